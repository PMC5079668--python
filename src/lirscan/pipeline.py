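"""Proteome-wide LIRCP prediction: batch scan, filter, summarize, export.

Runs the whole prediction over a proteome FASTA: scan every protein for
LIR motifs, keep proteins with at least one xLIR inside an intrinsically
disordered region (the LIRCP criterion), score hits with a PSSM, annotate
similarity to known LIR motifs, attach GO terms, and produce the
database-style per-hit table plus summary statistics (counts, % LIRCPs and
the LIR-per-LIRCP ratio).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Callable, Iterable, Mapping

import pandas as pd

from .disorder import DisorderTrack, builtin_disorder, classify_lircp, parse_disorder
from .motif_core import (
    PATTERNS,
    XLIR,
    KnownLirCatalog,
    MotifHit,
    PSSMModel,
    annotate_similar_known,
    read_fasta,
    score_hits,
    scan_pattern,
)

logger = logging.getLogger(__name__)

TrackSource = Callable[[str, str], DisorderTrack | None]


@dataclass
class BatchConfig:
    """Knobs of a batch run.

    patterns: which motif patterns to scan; the LIRCP call itself always
    rests on xLIR hits (WxxL hits are reported but never qualify a protein).
    disorder_policy: 'strict' (no track -> not a LIRCP) or 'permissive'.
    min_overlap: residues of a hit that must lie in a disordered segment;
    set to 6 to demand full containment of the 6-mer.
    strict: fail on unreadable/duplicate records instead of logging.
    """

    patterns: tuple[str, ...] = ("xlir",)
    disorder_policy: str = "strict"
    min_overlap: int = 1
    max_mismatches: int = 2
    strict: bool = False


@dataclass
class LircpEntry:
    """One predicted LIRCP: the database-row analogue.

    ``hits`` holds the anchored hits only (those inside disorder); each may
    carry a PSSM score and similar-known-LIR labels.
    """

    accession: str
    protein_name: str
    hits: list[MotifHit]
    similar_known: dict[int, list[str]] = field(default_factory=dict)
    go_mf: list[str] = field(default_factory=list)
    go_bp: list[str] = field(default_factory=list)
    go_cc: list[str] = field(default_factory=list)


@dataclass
class SummaryStats:
    """Per-organism batch summary mirroring the database's overview table."""

    n_orfs: int
    n_lircps: int
    n_lir_motifs: int
    pct_lircps: float  # 100 * n_lircps / n_orfs, 2 d.p. half-up
    ratio_lirs_per_lircp: float | None  # n_lir_motifs / n_lircps, 2 d.p.


def _round2(value: float) -> float:
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), ROUND_HALF_UP))


def summarize(n_orfs: int, n_lircps: int, n_lir_motifs: int) -> SummaryStats:
    """Compute % LIRCPs and the #LIRs:LIRCP ratio, rounded half-up to 2 d.p.

    The ratio is undefined (None) when there are no LIRCPs.
    """
    if n_orfs <= 0:
        raise ValueError("n_orfs must be positive")
    if min(n_lircps, n_lir_motifs) < 0 or n_lircps > n_orfs:
        raise ValueError("inconsistent counts")
    pct = _round2(100.0 * n_lircps / n_orfs)
    ratio = _round2(n_lir_motifs / n_lircps) if n_lircps > 0 else None
    return SummaryStats(n_orfs, n_lircps, n_lir_motifs, pct, ratio)


def directory_track_source(
    directory: str | Path, threshold: float = 0.5
) -> TrackSource:
    """Track source reading ``<accession>.txt|.tsv|.dis`` two-column files."""
    directory = Path(directory)

    def source(accession: str, sequence: str) -> DisorderTrack | None:
        for suffix in (".txt", ".tsv", ".dis"):
            path = directory / f"{accession}{suffix}"
            if path.exists():
                return parse_disorder(path, accession, threshold)
        return None

    return source


def builtin_track_source(accession: str, sequence: str) -> DisorderTrack:
    """Track source running the built-in hydropathy/charge heuristic."""
    return builtin_disorder(accession, sequence)


def run_batch(
    proteome: str | Path | Iterable[tuple[str, str, str]],
    disorder: TrackSource | Mapping[str, DisorderTrack] | None,
    pssm: PSSMModel | None = None,
    catalog: KnownLirCatalog | None = None,
    annotations: Mapping[str, Mapping[str, list[str]]] | None = None,
    config: BatchConfig | None = None,
) -> tuple[list[LircpEntry], SummaryStats]:
    """Predict LIRCPs across a proteome.

    Parameters
    ----------
    proteome
        FASTA path, or an iterable of (accession, description, sequence).
    disorder
        per-protein track source: a callable ``(accession, sequence) ->
        DisorderTrack | None``, a mapping, or None (policy decides).
    pssm, catalog, annotations
        optional scoring matrix, known-LIR catalog for similarity labels,
        and ``accession -> {'MF': [...], 'BP': [...], 'CC': [...]}`` GO map.

    Returns the LIRCP entries (proteins with >= 1 anchored xLIR) and the
    summary statistics.  Streaming: memory use is independent of proteome
    size apart from the entries themselves.
    """
    config = config or BatchConfig()
    records = read_fasta(proteome) if isinstance(proteome, (str, Path)) else proteome
    if isinstance(disorder, Mapping):
        tracks = disorder
        track_source: TrackSource = lambda acc, seq: tracks.get(acc)
    elif disorder is None:
        track_source = lambda acc, seq: None
    else:
        track_source = disorder

    patterns = [PATTERNS[p] for p in config.patterns]
    seen: dict[str, int] = {}
    entries: list[LircpEntry] = []
    n_orfs = 0
    n_lir_motifs = 0
    for accession, description, sequence in records:
        if accession in seen:
            seen[accession] += 1
            new = f"{accession}.{seen[accession]}"
            msg = f"duplicate accession {accession}; renamed to {new}"
            if config.strict:
                raise ValueError(msg)
            logger.warning(msg)
            accession = new
        else:
            seen[accession] = 0
        n_orfs += 1
        try:
            xlir_hits = scan_pattern(sequence, XLIR, accession)
        except ValueError as exc:
            if config.strict:
                raise
            logger.warning("skipping unreadable record %s: %s", accession, exc)
            continue
        track = track_source(accession, sequence)
        filtered = classify_lircp(
            xlir_hits, track, config.min_overlap, config.disorder_policy
        )
        if not filtered.lircp:
            continue
        anchored = filtered.hits_anchored
        extra: list[MotifHit] = []
        for pat in patterns:
            if pat is XLIR:
                continue
            raw = scan_pattern(sequence, pat, accession)
            sub = classify_lircp(raw, track, config.min_overlap, config.disorder_policy)
            extra.extend(sub.hits_anchored)
        hits = sorted(anchored + extra, key=lambda h: (h.start, h.pattern))
        if pssm is not None:
            score_hits(hits, pssm)
        similar: dict[int, list[str]] = {}
        if catalog is not None:
            for i, hit in enumerate(hits):
                if len(hit.window) == 6:
                    labels = annotate_similar_known(
                        hit, catalog, config.max_mismatches
                    )
                    if labels:
                        similar[i] = labels
        go = (annotations or {}).get(accession, {})
        entries.append(
            LircpEntry(
                accession,
                description,
                hits,
                similar,
                list(go.get("MF", [])),
                list(go.get("BP", [])),
                list(go.get("CC", [])),
            )
        )
        n_lir_motifs += sum(1 for h in hits if h.pattern == "xLIR")
        if n_orfs % 5000 == 0:
            logger.info("processed %d records, %d LIRCPs", n_orfs, len(entries))
    if n_orfs == 0:
        raise ValueError("proteome contains no sequences")
    stats = summarize(n_orfs, len(entries), n_lir_motifs)
    return entries, stats


# ---------------------------------------------------------------------------
# Export / import / search
# ---------------------------------------------------------------------------

EXPORT_COLUMNS = [
    "accession",
    "start",
    "end",
    "motif",
    "pattern",
    "pssm_score",
    "similar_known",
    "protein_name",
    "go_mf",
    "go_bp",
    "go_cc",
]


def entries_to_frame(entries: Iterable[LircpEntry]) -> pd.DataFrame:
    rows = []
    for entry in entries:
        for i, hit in enumerate(entry.hits):
            rows.append(
                {
                    "accession": entry.accession,
                    "start": hit.start,
                    "end": hit.end,
                    "motif": hit.window,
                    "pattern": hit.pattern,
                    "pssm_score": (
                        round(hit.pssm_score, 4)
                        if hit.pssm_score is not None
                        else ""
                    ),
                    "similar_known": ";".join(entry.similar_known.get(i, [])),
                    "protein_name": entry.protein_name,
                    "go_mf": "|".join(entry.go_mf),
                    "go_bp": "|".join(entry.go_bp),
                    "go_cc": "|".join(entry.go_cc),
                }
            )
    return pd.DataFrame(rows, columns=EXPORT_COLUMNS)


def export_entries(
    entries: Iterable[LircpEntry], path: str | Path, format: str = "tsv"
) -> None:
    """Write one row per (entry, hit) in a stable column order."""
    if format not in {"tsv", "csv"}:
        raise ValueError(f"unknown format {format!r}")
    sep = "\t" if format == "tsv" else ","
    entries_to_frame(entries).to_csv(path, sep=sep, index=False)


def load_entries(path: str | Path, format: str = "tsv") -> list[LircpEntry]:
    """Round-trip reader for :func:`export_entries` output."""
    sep = "\t" if format == "tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    entries: dict[str, LircpEntry] = {}
    for _, row in df.iterrows():
        acc = row["accession"]
        entry = entries.get(acc)
        if entry is None:
            entry = LircpEntry(
                acc,
                row["protein_name"],
                [],
                {},
                [t for t in row["go_mf"].split("|") if t],
                [t for t in row["go_bp"].split("|") if t],
                [t for t in row["go_cc"].split("|") if t],
            )
            entries[acc] = entry
        hit = MotifHit(
            acc,
            int(row["start"]),
            int(row["end"]),
            row["motif"],
            row["pattern"],
            float(row["pssm_score"]) if row["pssm_score"] else None,
        )
        idx = len(entry.hits)
        entry.hits.append(hit)
        if row["similar_known"]:
            entry.similar_known[idx] = row["similar_known"].split(";")
    return list(entries.values())


def keyword_search(
    entries: Iterable[LircpEntry], query: str, field_name: str = "description"
) -> list[LircpEntry]:
    """Case-insensitive substring search over a single entry field
    (``gene``/``description`` search the protein name, ``accession`` the
    UniProt-style ID).  An empty query matches everything, with a warning."""
    getters = {
        "gene": lambda e: e.protein_name,
        "description": lambda e: e.protein_name,
        "accession": lambda e: e.accession,
    }
    if field_name not in getters:
        raise ValueError(
            f"unknown search field {field_name!r}; use gene, description or accession"
        )
    if not query:
        logger.warning("empty query matches every entry")
        return list(entries)
    q = query.lower()
    getter = getters[field_name]
    return [e for e in entries if q in getter(e).lower()]
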