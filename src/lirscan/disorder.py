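"""Intrinsic-disorder tracks and the anchored-LIR filter.

A motif hit is only considered a credible Atg8-binding candidate when it
overlaps an intrinsically disordered ("anchor") segment — a region able to
transit from a disordered to an ordered state upon binding.  A protein is
called a LIRCP (LIR-containing protein) when at least one xLIR hit overlaps
such a segment.

Disorder calls come from external per-residue predictor output (IUPred /
ANCHOR style two-column files), from interval lists, or from a simple
built-in hydropathy/charge heuristic that is *not* equivalent to a real
disorder predictor and is labeled as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .motif_core import MotifHit

DEFAULT_DISORDER_THRESHOLD = 0.5  # conventional IUPred/ANCHOR cutoff


class DisorderFormatError(ValueError):
    """Malformed disorder input (index gaps, duplicates, bad intervals)."""


class CoordinateError(ValueError):
    """A hit lies outside the protein covered by a track."""


def segments_from_scores(
    scores: Sequence[float], threshold: float = DEFAULT_DISORDER_THRESHOLD
) -> list[tuple[int, int]]:
    """Run-length encode per-residue scores into 1-based disordered segments.

    A residue is disordered when its score is >= ``threshold``; maximal runs
    of disordered residues become (start, end) inclusive intervals.
    """
    segments = []
    start = None
    for i, s in enumerate(scores, start=1):
        if s >= threshold:
            if start is None:
                start = i
        elif start is not None:
            segments.append((start, i - 1))
            start = None
    if start is not None:
        segments.append((start, len(scores)))
    return segments


@dataclass
class DisorderTrack:
    """Disordered segments of one protein, 1-based inclusive coordinates."""

    protein_id: str
    length: int
    segments: list[tuple[int, int]] = field(default_factory=list)
    source: str = "external"
    scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.segments:
            if start < 1 or end > self.length or start > end:
                raise DisorderFormatError(
                    f"interval ({start},{end}) out of bounds for "
                    f"{self.protein_id!r} of length {self.length}"
                )
            if start <= prev_end:
                raise DisorderFormatError(
                    "segments must be sorted and non-overlapping"
                )
            prev_end = end
        if self.scores is not None and len(self.scores) != self.length:
            raise DisorderFormatError("score vector length != protein length")

    @classmethod
    def from_scores(
        cls,
        protein_id: str,
        scores: Sequence[float],
        threshold: float = DEFAULT_DISORDER_THRESHOLD,
        source: str = "external",
    ) -> "DisorderTrack":
        arr = np.asarray(scores, dtype=float)
        return cls(
            protein_id,
            len(arr),
            segments_from_scores(arr, threshold),
            source=source,
            scores=arr,
        )

    def is_disordered(self, residue: int) -> bool:
        return any(s <= residue <= e for s, e in self.segments)


def parse_disorder(
    path: str | Path,
    protein_id: str | None = None,
    threshold: float = DEFAULT_DISORDER_THRESHOLD,
) -> DisorderTrack:
    """Parse a per-residue two-column (index, score) disorder file.

    Rows must cover residues 1..L contiguously; comment lines starting with
    ``#`` are ignored.  Scores are thresholded (>= ``threshold``) and merged
    into segments.
    """
    path = Path(path)
    if protein_id is None:
        protein_id = path.stem
    indices, scores = [], []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise DisorderFormatError(
                    f"{path}:{line_no}: expected 'index score'"
                )
            try:
                indices.append(int(fields[0]))
                scores.append(float(fields[1]))
            except ValueError as exc:
                raise DisorderFormatError(f"{path}:{line_no}: {exc}") from exc
    if not indices:
        raise DisorderFormatError(f"{path}: no data rows")
    expected = list(range(1, len(indices) + 1))
    if indices != expected:
        raise DisorderFormatError(
            f"{path}: residue indices must run 1..{len(indices)} without "
            "gaps or duplicates"
        )
    return DisorderTrack.from_scores(protein_id, scores, threshold)


def parse_disorder_intervals(path: str | Path) -> dict[str, DisorderTrack]:
    """Parse a BED-like interval TSV: protein_id, start, end[, length].

    Coordinates are 1-based inclusive.  When a fourth column gives the
    protein length it is used; otherwise the track length is the largest
    end seen for that protein.
    """
    raw: dict[str, list[tuple[int, int]]] = {}
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DisorderFormatError(
                    f"{path}:{line_no}: expected 'protein_id\\tstart\\tend'"
                )
            pid, start, end = fields[0], int(fields[1]), int(fields[2])
            if start < 1 or end < start:
                raise DisorderFormatError(
                    f"{path}:{line_no}: bad interval ({start},{end})"
                )
            raw.setdefault(pid, []).append((start, end))
            if len(fields) >= 4 and fields[3]:
                lengths[pid] = int(fields[3])
    tracks = {}
    for pid, segs in raw.items():
        segs.sort()
        merged: list[tuple[int, int]] = []
        for s, e in segs:
            if merged and s <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        length = lengths.get(pid, merged[-1][1])
        tracks[pid] = DisorderTrack(pid, length, merged, source="external")
    return tracks


def overlaps_disorder(
    hit: MotifHit, track: DisorderTrack, min_overlap: int = 1
) -> bool:
    """True iff >= ``min_overlap`` residues of the hit lie in a disordered
    segment of ``track``.  ``min_overlap`` equal to the motif length demands
    full containment."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if hit.end > track.length or hit.start < 1:
        raise CoordinateError(
            f"hit {hit.start}-{hit.end} outside track of length {track.length}"
        )
    overlap = 0
    for s, e in track.segments:
        overlap += max(0, min(hit.end, e) - max(hit.start, s) + 1)
        if overlap >= min_overlap:
            return True
    return False


@dataclass
class FilteredHitSet:
    """All hits of one protein and the subset overlapping disorder."""

    protein_id: str
    hits_all: list[MotifHit]
    hits_anchored: list[MotifHit]
    lircp: bool
    note: str = ""


def classify_lircp(
    hits: Iterable[MotifHit],
    track: DisorderTrack | None,
    min_overlap: int = 1,
    policy: str = "strict",
) -> FilteredHitSet:
    """Apply the LIRCP criterion: >= 1 xLIR hit inside a disordered region.

    ``policy`` governs proteins without a disorder track: ``strict`` never
    calls them LIRCPs; ``permissive`` treats all their hits as anchored and
    flags the set ``no-disorder-data``.
    """
    hits = list(hits)
    ids = {h.protein_id for h in hits}
    if len(ids) > 1:
        raise ValueError(f"hits from multiple proteins: {sorted(ids)}")
    protein_id = ids.pop() if ids else (track.protein_id if track else "")
    if track is None:
        if policy == "permissive":
            return FilteredHitSet(
                protein_id, hits, list(hits), bool(hits), "no-disorder-data"
            )
        if policy == "strict":
            return FilteredHitSet(protein_id, hits, [], False, "no-disorder-data")
        raise ValueError(f"unknown no-track policy {policy!r}")
    anchored = [h for h in hits if overlaps_disorder(h, track, min_overlap)]
    return FilteredHitSet(protein_id, hits, anchored, bool(anchored))


# ---------------------------------------------------------------------------
# Built-in heuristic predictor
# ---------------------------------------------------------------------------

# Kyte-Doolittle hydropathy, rescaled to [0, 1] over the window mean.
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}
_CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.0}


def builtin_disorder(
    protein_id: str,
    sequence: str,
    window: int = 21,
    threshold: float = DEFAULT_DISORDER_THRESHOLD,
) -> DisorderTrack:
    """Windowed hydropathy/charge disorder heuristic.

    A residue's score combines low mean hydropathy and high mean net charge
    over a sliding window (the folding-index idea: hydrophobic, weakly
    charged stretches fold; hydrophilic, charged stretches tend to stay
    disordered).  This is a coarse stand-in usable when no predictor output
    is available; it is **not equivalent** to IUPred/ANCHOR and tracks it
    produces carry ``source='builtin'``.
    """
    n = len(sequence)
    if n == 0:
        raise ValueError("empty sequence")
    half = window // 2
    kd = np.array([_KD.get(aa, 0.0) for aa in sequence])
    charge = np.array([_CHARGE.get(aa, 0.0) for aa in sequence])
    scores = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        mean_h = (kd[lo:hi].mean() + 4.5) / 9.0  # rescale to [0, 1]
        mean_q = abs(charge[lo:hi].mean())
        # folding index sign flipped to a disorder propensity in [0, 1]
        fold = 2.785 * mean_h - mean_q - 1.151
        scores[i] = 1.0 / (1.0 + np.exp(10.0 * fold))
    return DisorderTrack.from_scores(
        protein_id, scores, threshold, source="builtin"
    )
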