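"""Scanning amino-acid sequences for LIR (LC3-interacting region) motifs.

The LIR motif mediates binding of selective-autophagy receptors and other
proteins to Atg8-family proteins (LC3/GABARAP).  Two consensus patterns are
implemented:

* **xLIR** — the extended six-position consensus
  ``(ADEFGLPRSK)(DEGMSTV)(WFY)(DEILQTV)(ADEFHIKLMPSTV)(ILV)`` derived from
  experimentally verified LIR instances.  Positions 3 (aromatic) and 6
  (aliphatic) are the core residues that dock into the two hydrophobic
  pockets of the Atg8 fold.
* **WxxL** — the classical relaxed four-position pattern
  ``(WFY)xx(ILV)``, where ``x`` is any residue.

Hits can additionally be scored with a position-specific scoring matrix
(PSSM): an additive log-odds model built from a training set of validated
6-mer LIR instances, and annotated with similar experimentally
characterized LIR motifs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

# The 20 canonical residues, fixed column order for PSSMs and serialization.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: residues treated as valid input letters but never matching any position
#: class (ambiguity/rare codes: class membership is undefined for them)
AMBIGUOUS_RESIDUES = set("XBZUOJ")


class EmptySequenceError(ValueError):
    """Raised when an empty sequence is submitted for scanning."""


class SequenceFormatError(ValueError):
    """Raised when a sequence contains non-letter characters."""


class ScoringError(ValueError):
    """Raised when a window cannot be scored (non-canonical residue)."""


@dataclass(frozen=True)
class MotifPattern:
    """A short-linear-motif consensus: one allowed residue set per position."""

    name: str
    position_classes: tuple[frozenset[str], ...]

    def __len__(self) -> int:
        return len(self.position_classes)

    def matches(self, window: str) -> bool:
        """True iff ``window`` satisfies every position class.

        Windows containing any residue outside the 20-letter alphabet never
        match (ambiguity codes have undefined class membership).
        """
        if len(window) != len(self.position_classes):
            return False
        return all(
            aa in cls for aa, cls in zip(window, self.position_classes)
        )


def _classes(*specs: str) -> tuple[frozenset[str], ...]:
    return tuple(frozenset(s) for s in specs)


#: extended LIR consensus; positions 3 and 6 are the Atg8-binding core
XLIR = MotifPattern(
    "xLIR",
    _classes("ADEFGLPRSK", "DEGMSTV", "WFY", "DEILQTV", "ADEFHIKLMPSTV", "ILV"),
)

#: relaxed classical pattern, aromatic-x-x-aliphatic
WXXL = MotifPattern("WxxL", _classes("WFY", AMINO_ACIDS, AMINO_ACIDS, "ILV"))

PATTERNS = {"xlir": XLIR, "wxxl": WXXL}


@dataclass
class MotifHit:
    """One pattern match in a protein sequence.

    Coordinates are reported 1-based inclusive (database display
    convention); ``window`` is the matched subsequence.  ``pssm_score`` is
    defined for 6-mer (xLIR) hits once a PSSM has been applied.
    """

    protein_id: str
    start: int
    end: int
    window: str
    pattern: str
    pssm_score: float | None = None

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.window):
            raise ValueError("hit coordinates inconsistent with window length")


def scan_pattern(
    sequence: str, pattern: MotifPattern, protein_id: str = ""
) -> list[MotifHit]:
    """Report every window of ``sequence`` matching ``pattern``.

    All overlapping positions are considered and all matches are kept (a
    protein commonly carries more than one LIR candidate).  Returned hits
    are sorted by start coordinate (1-based inclusive).

    Raises
    ------
    EmptySequenceError
        if ``sequence`` is empty.
    SequenceFormatError
        if ``sequence`` contains non-letter characters.
    """
    if not sequence:
        raise EmptySequenceError("cannot scan an empty sequence")
    if not sequence.isalpha():
        bad = sorted({c for c in sequence if not c.isalpha()})
        raise SequenceFormatError(f"non-letter characters in sequence: {bad!r}")
    sequence = sequence.upper()
    w = len(pattern)
    hits = []
    for i in range(len(sequence) - w + 1):
        window = sequence[i : i + w]
        if pattern.matches(window):
            hits.append(
                MotifHit(protein_id, i + 1, i + w, window, pattern.name)
            )
    return hits


# ---------------------------------------------------------------------------
# PSSM construction and scoring
# ---------------------------------------------------------------------------

UNIFORM_BACKGROUND = {aa: 0.05 for aa in AMINO_ACIDS}


@dataclass
class PSSMModel:
    """Additive log-odds model over the 6 xLIR positions.

    ``matrix[p, a]`` is ``log2((count(p, aa) + c) / (n + 20 c)) −
    log2(background(aa))`` with pseudocount ``c > 0``, which keeps every
    weight finite.  Scoring a 6-mer sums the six positional lookups.
    """

    matrix: np.ndarray  # (6, 20) log-odds weights
    background: np.ndarray  # (20,) frequencies summing to 1
    pseudocount: float
    training_set_size: int

    def score(self, window: str) -> float:
        return score_window(window, self)

    def to_tsv(self, path: str | Path) -> None:
        """Serialize as TSV: 6 rows (positions) × 20 named residue columns."""
        df = pd.DataFrame(
            self.matrix,
            index=[f"pos{i + 1}" for i in range(self.matrix.shape[0])],
            columns=list(AMINO_ACIDS),
        )
        df.index.name = "position"
        df.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        background: Sequence[float] | None = None,
        pseudocount: float = 1.0,
        training_set_size: int = 0,
    ) -> "PSSMModel":
        """Load a serialized matrix (e.g. an externally obtained LIR PSSM)."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        matrix = df[list(AMINO_ACIDS)].to_numpy(dtype=float)
        bg = (
            np.asarray(background, dtype=float)
            if background is not None
            else np.full(20, 0.05)
        )
        return cls(matrix, bg, pseudocount, training_set_size)


def _as_background_array(background) -> np.ndarray:
    if background is None:
        return np.full(20, 0.05)
    if isinstance(background, dict):
        arr = np.array([background[aa] for aa in AMINO_ACIDS], dtype=float)
    else:
        arr = np.asarray(background, dtype=float)
    if arr.shape != (20,):
        raise ValueError("background must provide one frequency per residue")
    if abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError(f"background frequencies sum to {arr.sum()}, not 1")
    if (arr <= 0).any():
        raise ValueError("background frequencies must be positive")
    return arr


def build_pssm(
    instances: Sequence[str],
    background=None,
    pseudocount: float = 1.0,
) -> PSSMModel:
    """Build a log-odds PSSM from validated 6-mer LIR instances.

    Parameters
    ----------
    instances
        one or more 6-mer strings over the canonical alphabet.
    background
        residue frequencies (mapping or length-20 array in ``AMINO_ACIDS``
        order); default uniform 0.05, must sum to 1 within 1e-9.
    pseudocount
        additive smoothing, must be > 0 (default 1.0).
    """
    if not instances:
        raise ValueError("need at least one training instance")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    for inst in instances:
        if len(inst) != 6:
            raise ValueError(f"training instance {inst!r} is not a 6-mer")
        if any(aa not in AA_INDEX for aa in inst):
            raise ValueError(f"non-canonical residue in instance {inst!r}")
    bg = _as_background_array(background)
    n = len(instances)
    counts = np.zeros((6, 20))
    for inst in instances:
        for pos, aa in enumerate(inst):
            counts[pos, AA_INDEX[aa]] += 1
    freqs = (counts + pseudocount) / (n + 20 * pseudocount)
    matrix = np.log2(freqs) - np.log2(bg)[None, :]
    return PSSMModel(matrix, bg, pseudocount, n)


def score_window(window: str, model: PSSMModel) -> float:
    """Sum of the positional log-odds weights for a 6-mer window."""
    if len(window) != model.matrix.shape[0]:
        raise ScoringError(
            f"window {window!r} length does not match matrix "
            f"({model.matrix.shape[0]} positions)"
        )
    try:
        cols = [AA_INDEX[aa] for aa in window]
    except KeyError as exc:
        raise ScoringError(f"non-canonical residue {exc.args[0]!r}") from exc
    return float(sum(model.matrix[p, c] for p, c in enumerate(cols)))


def score_hits(hits: Iterable[MotifHit], model: PSSMModel) -> list[MotifHit]:
    """Attach PSSM scores to xLIR hits in place; WxxL hits are left unscored."""
    hits = list(hits)
    for hit in hits:
        if len(hit.window) == model.matrix.shape[0]:
            hit.pssm_score = score_window(hit.window, model)
    return hits


# ---------------------------------------------------------------------------
# Similarity to experimentally characterized LIR motifs
# ---------------------------------------------------------------------------


@dataclass
class KnownLirEntry:
    protein_name: str
    motif: str
    organism: str = ""

    def __post_init__(self) -> None:
        if len(self.motif) != 6 or any(a not in AA_INDEX for a in self.motif):
            raise ValueError(
                f"validated LIR {self.motif!r} must be a canonical 6-mer"
            )


@dataclass
class KnownLirCatalog:
    """Experimentally characterized LIR 6-mers, e.g. p62/SQSTM1 ``DDDWTHL``'s
    core ``DDWTHL``; used to annotate predicted hits with similar known
    motifs."""

    entries: list[KnownLirEntry] = field(default_factory=list)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KnownLirCatalog":
        """Read a TSV with columns name, motif, organism."""
        df = pd.read_csv(
            path, sep="\t", header=0, dtype=str, keep_default_na=False
        )
        cols = list(df.columns[:3])
        entries = [
            KnownLirEntry(*(row[c] for c in cols)) for _, row in df.iterrows()
        ]
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(e.protein_name, e.motif, e.organism) for e in self.entries],
            columns=["name", "motif", "organism"],
        ).to_csv(path, sep="\t", index=False)


def annotate_similar_known(
    hit: MotifHit, catalog: KnownLirCatalog, max_mismatches: int = 2
) -> list[str]:
    """Catalog entries similar to a hit's 6-mer window.

    A catalog motif is similar when it matches the window exactly at the
    core positions 3 and 6 (the residues critical for Atg8 binding) and
    differs at no more than ``max_mismatches`` of the remaining positions.
    """
    if len(hit.window) != 6:
        raise ValueError("similarity annotation is defined for 6-mer windows")
    labels = []
    for entry in catalog.entries:
        m, w = entry.motif, hit.window
        if m[2] != w[2] or m[5] != w[5]:
            continue
        mismatches = sum(m[i] != w[i] for i in (0, 1, 3, 4))
        if mismatches <= max_mismatches:
            labels.append(entry.protein_name)
    return labels


# ---------------------------------------------------------------------------
# FASTA input
# ---------------------------------------------------------------------------


def parse_fasta_header(header: str) -> tuple[str, str]:
    """Split a FASTA description line into (accession, description).

    UniProt ``db|ACC|NAME description`` headers yield the accession; plain
    headers use the first whitespace-separated token.
    """
    first, _, rest = header.partition(" ")
    parts = first.split("|")
    if len(parts) >= 3 and parts[0] in {"sp", "tr", "db"}:
        return parts[1], rest or parts[2]
    return first, rest


def read_fasta(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Stream (accession, description, sequence) triples from a FASTA file."""
    for record in SeqIO.parse(str(path), "fasta"):
        accession, description = parse_fasta_header(record.description)
        yield accession, description, str(record.seq).upper()
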