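"""Seeded synthetic proteomes, disorder tracks and GO annotations.

Every stage of the predictor is testable without downloads: the generator
emits FASTA proteomes with xLIR motifs planted at recorded positions
(inside or outside disordered segments), matching per-residue disorder
tracks, and a miniature GO ontology plus annotation table with one term
enriched among the pseudo-LIRCPs by a known multiplier.  All output parses
through the production readers — there are no fixture-only dialects — and
a single integer seed fixes every random draw.

In *strict* mode the background sequence is rejection-resampled so that no
xLIR occurs outside a planted site, which supports exact-count assertions;
*loose* mode leaves the natural background rate (about 9 x 10^-4 per
window under uniform residue frequencies).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .disorder import DisorderTrack
from .enrichment import AnnotationSet, GODag, parse_obo
from .motif_core import AMINO_ACIDS, XLIR, scan_pattern

_DESCRIPTION_POOL = (
    "hypothetical protein",
    "putative kinase",
    "transport protein",
    "zinc finger protein",
    "membrane receptor",
    "ribosomal protein",
    "heat shock protein",
    "ubiquitin ligase",
)

_NAMESPACE_ROOTS = {
    "molecular_function": "GO:0003674",
    "biological_process": "GO:0008150",
    "cellular_component": "GO:0005575",
}


@dataclass
class FixtureSpec:
    """Parameters of a synthetic study.

    Defaults emulate the observed scale of LIR prediction: roughly 6 % of
    proteins carry a planted xLIR (the per-organism LIRCP fraction ranges
    from 4 to 7 %), half of the plants fall inside disordered segments
    (the rest are decoys the disorder filter must reject), residues are
    drawn uniformly, and the enriched GO term is assigned to
    pseudo-LIRCPs at 10 x the 8 % background annotation rate.
    """

    n_proteins: int = 100
    length_range: tuple[int, int] = (80, 300)
    plant_rate: float = 0.06
    anchored_fraction: float = 0.5
    background_freqs: np.ndarray | None = None  # AMINO_ACIDS order; uniform
    n_go_terms: int = 20
    enriched_term: str | None = None  # default: first BP slim term
    enriched_multiplier: float = 10.0
    background_annotation_rate: float = 0.08
    strict: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo > hi:
            raise ValueError("length_range min exceeds max")
        if lo < len(XLIR):
            raise ValueError(
                f"proteins of length {lo} cannot hold a {len(XLIR)}-mer motif"
            )
        for name in ("plant_rate", "anchored_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.background_freqs is not None:
            bg = np.asarray(self.background_freqs, dtype=float)
            if bg.shape != (20,) or abs(bg.sum() - 1) > 1e-9:
                raise ValueError("background_freqs must be 20 values summing to 1")


@dataclass
class PlantedMotif:
    start: int  # 1-based inclusive
    end: int
    motif: str
    anchored: bool


@dataclass
class GroundTruth:
    """Generator bookkeeping: what was planted where."""

    planted: dict[str, PlantedMotif] = field(default_factory=dict)
    term_counts: dict[str, tuple[int, int]] = field(default_factory=dict)  # term -> (x, n)
    enriched_term: str | None = None
    lircps: set[str] = field(default_factory=set)

    @property
    def anchored_accessions(self) -> set[str]:
        return {a for a, p in self.planted.items() if p.anchored}


@dataclass
class ProteomeFixture:
    """A synthetic proteome with disorder tracks and recorded ground truth."""

    records: list[tuple[str, str, str]]  # (accession, description, sequence)
    tracks: dict[str, DisorderTrack]
    truth: GroundTruth

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for acc, desc, seq in self.records:
                fh.write(f">sp|{acc}|{acc}_SYN {desc}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")

    def write_tracks(self, directory: str | Path) -> None:
        """One two-column (index, score) file per protein."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for acc, track in self.tracks.items():
            with open(directory / f"{acc}.txt", "w") as fh:
                fh.write(f"# disorder track {acc}\n")
                for i in range(1, track.length + 1):
                    score = 0.9 if track.is_disordered(i) else 0.1
                    fh.write(f"{i}\t{score:.2f}\n")


def _draw_xlir(rng: np.random.Generator) -> str:
    return "".join(
        sorted(cls)[rng.integers(len(cls))] for cls in XLIR.position_classes
    )


def _random_sequence(rng: np.random.Generator, length: int, bg: np.ndarray) -> list[str]:
    return list(rng.choice(list(AMINO_ACIDS), size=length, p=bg))


def _scrub_spurious(
    seq: list[str],
    protected: tuple[int, int] | None,
    rng: np.random.Generator,
    bg: np.ndarray,
    max_rounds: int = 200,
) -> list[str]:
    """Resample residues until no xLIR match survives outside ``protected``
    (0-based half-open span of the planted motif)."""
    for _ in range(max_rounds):
        hits = scan_pattern("".join(seq), XLIR)
        spurious = [
            h
            for h in hits
            if protected is None or (h.start - 1, h.end) != protected
        ]
        if not spurious:
            return seq
        for h in spurious:
            for i in range(h.start - 1, h.end):
                if protected and protected[0] <= i < protected[1]:
                    continue
                seq[i] = str(rng.choice(list(AMINO_ACIDS), p=bg))
    raise RuntimeError("could not scrub spurious motifs (pathological spec)")


def generate_proteome(spec: FixtureSpec) -> ProteomeFixture:
    """Generate a seeded proteome with planted motifs and disorder tracks.

    Plant counts are deterministic: ``round(n_proteins * plant_rate)``
    proteins receive exactly one xLIR drawn uniformly from the consensus
    position-class product, and ``round(n_plants * anchored_fraction)`` of
    those plants are covered by a disordered segment; the remaining plants
    are guaranteed to lie entirely in ordered sequence.  Unplanted
    proteins get a decoy disordered segment half the time.
    """
    rng = np.random.default_rng([spec.seed, 11])
    bg = (
        np.asarray(spec.background_freqs, dtype=float)
        if spec.background_freqs is not None
        else np.full(20, 0.05)
    )
    n_plants = round(spec.n_proteins * spec.plant_rate)
    n_anchored = round(n_plants * spec.anchored_fraction)
    planted_idx = (
        sorted(rng.choice(spec.n_proteins, size=n_plants, replace=False))
        if n_plants
        else []
    )
    anchored_idx = set(planted_idx[:n_anchored])

    records = []
    tracks = {}
    truth = GroundTruth()
    for i in range(spec.n_proteins):
        acc = f"SYN{i + 1:04d}"
        desc = _DESCRIPTION_POOL[i % len(_DESCRIPTION_POOL)]
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        seq = _random_sequence(rng, length, bg)
        plant_span = None
        segments: list[tuple[int, int]] = []
        if i in planted_idx:
            motif = _draw_xlir(rng)
            lo = min(5, length - 6)
            start0 = int(rng.integers(lo, length - 6 + 1))  # 0-based
            seq[start0 : start0 + 6] = list(motif)
            plant_span = (start0, start0 + 6)
            start1, end1 = start0 + 1, start0 + 6  # 1-based inclusive
            anchored = i in anchored_idx
            if anchored:
                segments.append((max(1, start1 - 3), min(length, end1 + 3)))
            else:
                # decoy segment guaranteed clear of the motif
                if start1 > length - end1:
                    region = (1, start1 - 2)
                else:
                    region = (end1 + 2, length)
                if region[1] - region[0] >= 5:
                    s = int(rng.integers(region[0], region[1] - 4))
                    segments.append((s, min(region[1], s + 14)))
            truth.planted[acc] = PlantedMotif(start1, end1, motif, anchored)
            if anchored:
                truth.lircps.add(acc)
        elif rng.random() < 0.5 and length >= 30:
            s = int(rng.integers(1, length - 19))
            segments.append((s, s + 19))
        if spec.strict:
            seq = _scrub_spurious(seq, plant_span, rng, bg)
        records.append((acc, desc, "".join(seq)))
        tracks[acc] = DisorderTrack(acc, length, segments, source="external")
    return ProteomeFixture(records, tracks, truth)


# ---------------------------------------------------------------------------
# Annotations + miniature ontology
# ---------------------------------------------------------------------------


@dataclass
class AnnotationFixture:
    """A miniature GO DAG, slim subset and protein annotation table."""

    obo_text: str
    slim_terms: list[str]
    annotations: AnnotationSet
    truth: GroundTruth

    @property
    def dag(self) -> GODag:
        return parse_obo(io.StringIO(self.obo_text))

    def write_obo(self, path: str | Path) -> None:
        Path(path).write_text(self.obo_text)

    def write_annotations(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("accession\tgo_ids\n")
            for acc in sorted(self.annotations.mapping):
                terms = "|".join(sorted(self.annotations.mapping[acc]))
                fh.write(f"{acc}\t{terms}\n")


def _build_obo(slim_terms: list[str], namespaces: dict[str, str], leaves: dict[str, str]) -> str:
    buf = ["format-version: 1.2", "ontology: go-synthetic", ""]
    for ns, root in _NAMESPACE_ROOTS.items():
        buf += [f"[Term]", f"id: {root}", f"name: {ns}", f"namespace: {ns}", ""]
    for term in slim_terms:
        ns = namespaces[term]
        buf += [
            "[Term]",
            f"id: {term}",
            f"name: synthetic {ns.split('_')[1]} {term[-2:]}",
            f"namespace: {ns}",
            f"is_a: {_NAMESPACE_ROOTS[ns]} ! {ns}",
            "",
        ]
    for leaf, parent in leaves.items():
        ns = namespaces[parent]
        buf += [
            "[Term]",
            f"id: {leaf}",
            f"name: synthetic leaf under {parent}",
            f"namespace: {ns}",
            f"is_a: {parent} ! parent slim",
            "",
        ]
    return "\n".join(buf)


def generate_annotations(
    spec: FixtureSpec,
    lircps: set[str] | None = None,
    proteins: list[str] | None = None,
) -> AnnotationFixture:
    """Generate a mini ontology and an annotation table with one planted
    enrichment.

    The DAG holds the three namespace roots, ``n_go_terms`` slim terms
    distributed round-robin over the namespaces, and one non-slim leaf
    child under each of the first three slim terms (annotations sometimes
    use the leaf, exercising upward slim mapping).  The enriched term is
    assigned to pseudo-LIRCPs at ``enriched_multiplier`` times the
    background rate (clipped at 1 with a warning); realized counts are
    recorded in the ground truth.
    """
    if spec.n_go_terms < 2:
        raise ValueError("need at least 2 GO terms")
    rng = np.random.default_rng([spec.seed, 23])
    if proteins is None:
        proteins = [f"SYN{i + 1:04d}" for i in range(spec.n_proteins)]
    if lircps is None:
        n_plants = round(spec.n_proteins * spec.plant_rate)
        n_anchored = round(n_plants * spec.anchored_fraction)
        lircps = set(proteins[:n_anchored])

    ns_order = list(_NAMESPACE_ROOTS)
    slim_terms = [f"GO:{7700001 + i:07d}" for i in range(spec.n_go_terms)]
    namespaces = {
        term: ns_order[i % 3] for i, term in enumerate(slim_terms)
    }
    leaves = {
        f"GO:{7800001 + i:07d}": slim_terms[i]
        for i in range(min(3, len(slim_terms)))
    }
    leaf_of = {parent: leaf for leaf, parent in leaves.items()}
    enriched = spec.enriched_term or next(
        t for t in slim_terms if namespaces[t] == "biological_process"
    )
    if enriched not in slim_terms:
        raise ValueError(f"enriched term {enriched} is not a slim term")

    base = spec.background_annotation_rate
    boosted = spec.enriched_multiplier * base
    if boosted > 1.0:
        warnings.warn(
            f"enriched assignment probability {boosted:.2f} clipped to 1.0",
            stacklevel=2,
        )
        boosted = 1.0

    mapping: dict[str, set[str]] = {p: set() for p in proteins}
    counts = {t: [0, 0] for t in slim_terms}  # term -> [x, n]
    for p in proteins:
        for t in slim_terms:
            rate = boosted if (t == enriched and p in lircps) else base
            if rng.random() < rate:
                # annotate via the leaf child half the time when one exists
                use_leaf = t in leaf_of and rng.random() < 0.5
                mapping[p].add(leaf_of[t] if use_leaf else t)
                counts[t][1] += 1
                if p in lircps:
                    counts[t][0] += 1
    mapping = {p: s for p, s in mapping.items() if s}
    annotations = AnnotationSet(
        mapping, organism="synthetic", universe_size=len(proteins)
    )
    truth = GroundTruth(
        term_counts={t: (x, n) for t, (x, n) in counts.items()},
        enriched_term=enriched,
        lircps=set(lircps),
    )
    obo = _build_obo(slim_terms, namespaces, leaves)
    return AnnotationFixture(obo, slim_terms, annotations, truth)
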