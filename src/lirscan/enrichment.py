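"""GO-slim functional enrichment of predicted LIR-containing proteins.

Workflow: protein GO annotations are projected onto a GO-slim (a reduced,
high-level subset of the ontology) with the classic map2slim min-ancestor
rule; each slim category is then tested for over-representation among the
predicted LIRCPs with an exact hypergeometric test,

    h(x; N, n, k) = C(k, x) C(N-k, n-x) / C(N, n)

where N is the universe size, n the number of proteins in the category,
k the number of LIRCPs and x the number of LIRCPs in the category.  The
reported p-value is the upper tail P(X >= x).  Benjamini-Hochberg FDR
control is applied within each GO namespace (molecular function,
biological process, cellular component analyzed as separate families) and
each category is placed in one of four significance tiers.

Candidate triage screens significant LIRCPs for association with a
reference set of GO terms derived from experimentally validated LIRCPs and
partitions them into curation groups A-D.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

NAMESPACES = {
    "molecular_function": "MF",
    "biological_process": "BP",
    "cellular_component": "CC",
}

TIER_HIGH = "highly_significant"
TIER_SIG = "significant"
TIER_LOW = "low_significance"
TIER_NOT = "not_significant"

#: GO terms associated with the experimentally validated LIRCPs whose LIR
#: lies in a disordered region; used as the reference set for candidate
#: triage.  User-extensible — pass your own set to ``triage_candidates``.
REFERENCE_GO_TERMS = frozenset(
    {
        "GO:0006914",  # autophagy
        "GO:0005739",  # mitochondrion
        "GO:0030904",  # retromer complex
        "GO:0006810",  # transport
        "GO:0005515",  # protein binding
        "GO:0042277",  # peptide binding
        "GO:0005634",  # nucleus
        "GO:0005576",  # extracellular region
        "GO:0009986",  # cell surface
        "GO:0006457",  # protein folding
        "GO:0007049",  # cell cycle
        "GO:0004871",  # signal transducer activity
        "GO:0042562",  # hormone binding
        "GO:0016032",  # viral process
    }
)


class OntologyError(ValueError):
    """Structural problem in the ontology (cycles, missing parents)."""


class ComparabilityError(ValueError):
    """Two result sets do not share the same slim and cannot be compared."""


# ---------------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------------


@dataclass
class GODag:
    """A GO ontology restricted to ``is_a`` edges (child -> parent DAG)."""

    graph: nx.DiGraph
    names: dict[str, str]
    namespaces: dict[str, str]
    obsolete: set[str]
    alt_ids: dict[str, str]

    def __contains__(self, term: str) -> bool:
        return self.resolve(term) is not None

    def resolve(self, term: str) -> str | None:
        """Canonical ID for ``term`` (following alt_id), or None."""
        if term in self.graph:
            return term
        return self.alt_ids.get(term)

    def ancestors(self, term: str, include_self: bool = True) -> set[str]:
        """All ``is_a`` ancestors of ``term`` (transitive closure)."""
        term = self.resolve(term) or term
        if term not in self.graph:
            raise OntologyError(f"unknown term {term!r}")
        anc = nx.descendants(self.graph, term)  # edges point child -> parent
        if include_self:
            anc = anc | {term}
        return anc


def parse_obo(path, include_part_of: bool = False) -> GODag:
    """Parse an OBO ontology file into a :class:`GODag`.

    Only ``is_a`` edges are kept by default; ``include_part_of`` adds
    ``part_of`` relationships as edges too.  Obsolete terms are retained
    (flagged) but excluded from slim mapping.  Raises
    :class:`OntologyError` on cyclic ``is_a`` structure or unknown parents.
    """
    multi = obonet.read_obo(path, ignore_obsolete=False)
    graph = nx.DiGraph()
    names: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    obsolete: set[str] = set()
    alt_ids: dict[str, str] = {}
    for term, data in multi.nodes(data=True):
        graph.add_node(term)
        names[term] = data.get("name", term)
        namespaces[term] = data.get("namespace", "")
        if data.get("is_obsolete") == "true":
            obsolete.add(term)
        for alt in data.get("alt_id", []):
            alt_ids[alt] = term
    keep = {"is_a"} | ({"part_of"} if include_part_of else set())
    for child, parent, key in multi.edges(keys=True):
        if key not in keep:
            continue
        if parent not in multi:
            raise OntologyError(
                f"term {child} references unknown parent {parent}"
            )
        graph.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise OntologyError(f"cyclic is_a structure: {cycle}")
    return GODag(graph, names, namespaces, obsolete, alt_ids)


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


@dataclass
class AnnotationSet:
    """Protein -> GO-term multimap for one organism.

    ``universe_size`` (N) defaults to the number of annotated proteins; it
    may be overridden with the full proteome size.
    """

    mapping: dict[str, set[str]]
    organism: str = ""
    universe_size: int | None = None

    @property
    def N(self) -> int:
        n_annotated = len(self.mapping)
        if self.universe_size is not None:
            if self.universe_size < n_annotated:
                raise ValueError(
                    "universe size smaller than number of annotated proteins"
                )
            return self.universe_size
        return n_annotated

    @property
    def proteins(self) -> set[str]:
        return set(self.mapping)


def read_annotation_tsv(path: str | Path, organism: str = "") -> AnnotationSet:
    """Read ``accession<TAB>GO:x|GO:y|...`` mapping rows (header optional)."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            acc, _, terms = line.partition("\t")
            if acc.lower() in {"accession", "protein", "uniprot"}:
                continue
            ids = {t for t in terms.strip().split("|") if t}
            mapping.setdefault(acc, set()).update(ids)
    return AnnotationSet(mapping, organism=organism)


def read_gaf(path: str | Path, organism: str = "") -> AnnotationSet:
    """Read a GAF 2.x association file (columns 2 and 5: object ID, GO ID)."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                continue
            mapping.setdefault(fields[1], set()).add(fields[4])
    return AnnotationSet(mapping, organism=organism)


def map_to_slim(
    annotations: AnnotationSet,
    dag: GODag,
    slim_terms: Iterable[str],
    rule: str = "min",
    strict: bool = False,
) -> dict[str, set[str]]:
    """Project each protein's GO annotations onto slim terms.

    ``rule='min'`` is the map2slim convention: an annotation term maps to
    the *closest* slim ancestors — slim terms reachable by an upward
    ``is_a`` path that passes through no other slim term.  ``rule='closure'``
    maps to every slim ancestor instead.  Terms absent from the DAG are
    skipped with a log message (or raise when ``strict``); obsolete terms
    never map.
    """
    slim = {dag.resolve(t) or t for t in slim_terms}
    unknown_slim = slim - set(dag.graph)
    if unknown_slim:
        raise OntologyError(f"slim terms not in ontology: {sorted(unknown_slim)}")
    if rule not in {"min", "closure"}:
        raise ValueError(f"unknown mapping rule {rule!r}")

    cache: dict[str, frozenset[str]] = {}

    def slim_of(term: str) -> frozenset[str]:
        if term in cache:
            return cache[term]
        if rule == "closure":
            result = frozenset(dag.ancestors(term) & slim)
        else:
            # upward BFS that stops at the first slim term on each path
            result_set: set[str] = set()
            if term in slim:
                result_set.add(term)
            else:
                seen = {term}
                frontier = [term]
                while frontier:
                    nxt = []
                    for u in frontier:
                        for parent in dag.graph.successors(u):
                            if parent in seen:
                                continue
                            seen.add(parent)
                            if parent in slim:
                                result_set.add(parent)
                            else:
                                nxt.append(parent)
                    frontier = nxt
            result = frozenset(result_set)
        cache[term] = result
        return result

    out: dict[str, set[str]] = {}
    for protein, terms in annotations.mapping.items():
        mapped: set[str] = set()
        for term in terms:
            resolved = dag.resolve(term)
            if resolved is None:
                msg = f"annotation term {term} absent from ontology ({protein})"
                if strict:
                    raise OntologyError(msg)
                logger.warning(msg)
                continue
            if resolved in dag.obsolete:
                continue
            mapped |= slim_of(resolved)
        out[protein] = mapped
    return out


# ---------------------------------------------------------------------------
# Hypergeometric test and FDR
# ---------------------------------------------------------------------------


def _check_hypergeom_args(x: int, N: int, n: int, k: int) -> None:
    if not (0 <= n <= N and 0 <= k <= N):
        raise ValueError(f"need 0 <= n,k <= N; got N={N}, n={n}, k={k}")
    if not 0 <= x <= min(n, k):
        raise ValueError(f"need 0 <= x <= min(n,k); got x={x}, n={n}, k={k}")


def hypergeom_pmf(x: int, N: int, n: int, k: int) -> float:
    """Probability of exactly ``x`` LIRCPs in a category:
    ``C(k,x) C(N-k,n-x) / C(N,n)`` — drawing the ``n`` category members
    from a universe of ``N`` containing ``k`` LIRCPs.  Evaluated in
    log-space, so it stays finite for proteome-scale N."""
    _check_hypergeom_args(x, N, n, k)
    return float(hypergeom.pmf(x, N, k, n))


def hypergeom_upper_tail(x: int, N: int, n: int, k: int) -> float:
    """Over-representation p-value P(X >= x) for the same draw."""
    _check_hypergeom_args(x, N, n, k)
    if x == 0:
        return 1.0
    return float(hypergeom.sf(x - 1, N, k, n))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_i = min_{j >= i, sorted order} (m * p_(j) / j), capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_tier(p_adj: float) -> str:
    """Place an adjusted p-value into one of four significance tiers:
    <= 0.01 highly significant; (0.01, 0.05] significant; (0.05, 0.1] low
    significance; > 0.1 not significant."""
    if not 0 <= p_adj <= 1:
        raise ValueError(f"adjusted p-value {p_adj} outside [0, 1]")
    if p_adj <= 0.01:
        return TIER_HIGH
    if p_adj <= 0.05:
        return TIER_SIG
    if p_adj <= 0.1:
        return TIER_LOW
    return TIER_NOT


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    """One GO-slim category with its counts and test outcome."""

    go_id: str
    namespace: str  # MF | BP | CC
    name: str
    x: int  # LIRCPs in category
    n: int  # proteins in category
    k: int  # total LIRCPs
    N: int  # universe size
    p: float
    p_adj: float = float("nan")
    tier: str = ""


def enrich(
    lircps: Iterable[str],
    annotations: AnnotationSet,
    dag: GODag,
    slim_terms: Iterable[str],
    rule: str = "min",
) -> list[EnrichmentResult]:
    """Test every slim category for LIRCP over-representation.

    BH adjustment and tier assignment are performed within each GO
    namespace separately (one family per top-level hierarchy).  Results
    cover every slim term with n > 0 or x > 0 and are sorted by namespace
    then adjusted p-value.
    """
    lircp_set = set(lircps)
    missing = lircp_set - annotations.proteins
    if missing:
        logger.warning(
            "%d LIRCPs have no annotation record and count toward k only",
            len(missing),
        )
    slim = [dag.resolve(t) or t for t in slim_terms]
    per_protein = map_to_slim(annotations, dag, slim, rule=rule)

    N = annotations.N
    k = len(lircp_set)
    results: list[EnrichmentResult] = []
    for term in sorted(set(slim)):
        members = {p for p, s in per_protein.items() if term in s}
        n = len(members)
        x = len(members & lircp_set)
        if n == 0 and x == 0:
            continue
        ns = NAMESPACES.get(dag.namespaces.get(term, ""), "")
        p = hypergeom_upper_tail(x, N, n, min(k, N))
        results.append(
            EnrichmentResult(term, ns, dag.names.get(term, term), x, n, k, N, p)
        )
    # BH within each namespace family
    for ns in sorted({r.namespace for r in results}):
        group = [r for r in results if r.namespace == ns]
        adjusted = bh_adjust([r.p for r in group])
        for r, adj in zip(group, adjusted):
            r.p_adj = float(adj)
            r.tier = classify_tier(r.p_adj)
    results.sort(key=lambda r: (r.namespace, r.p_adj, -r.x, r.go_id))
    return results


def results_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    cols = ["go_id", "namespace", "name", "x", "n", "k", "N", "p", "p_adj", "tier"]
    return pd.DataFrame(
        [[getattr(r, c) for c in cols] for r in results], columns=cols
    )


def write_results(results: Iterable[EnrichmentResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)


def compare_species(
    results_a: Sequence[EnrichmentResult],
    results_b: Sequence[EnrichmentResult],
) -> dict[str, tuple[float, float]]:
    """Per-term LIRCP proportions (x/k) for two species on the same slim.

    Terms present in only one species get proportion 0 in the other; a
    species with k = 0 yields all-zero proportions (with a warning).
    Raises :class:`ComparabilityError` when the shared terms disagree on
    namespace, i.e. the two runs used different slim versions.
    """
    a = {r.go_id: r for r in results_a}
    b = {r.go_id: r for r in results_b}
    for term in a.keys() & b.keys():
        if a[term].namespace != b[term].namespace:
            raise ComparabilityError(
                f"term {term} has namespace {a[term].namespace} vs "
                f"{b[term].namespace}: slim versions differ"
            )

    def proportion(r: EnrichmentResult | None, label: str) -> float:
        if r is None:
            return 0.0
        if r.k == 0:
            warnings.warn(
                f"species {label} has no LIRCPs (k=0); proportions are 0",
                stacklevel=3,
            )
            return 0.0
        return r.x / r.k

    return {
        term: (proportion(a.get(term), "A"), proportion(b.get(term), "B"))
        for term in sorted(a.keys() | b.keys())
    }


# ---------------------------------------------------------------------------
# Candidate triage
# ---------------------------------------------------------------------------

#: curation labels -> triage group; anything unlabeled falls in group D
GROUP_OF_LABEL = {
    "validated": "A",  # experimentally verified LIR motif
    "atg8_interactor": "B",  # known Atg8-family interactor, LIR unverified
    "autophagy_linked": "C",  # linked to autophagy, no known interaction
}


def triage_candidates(
    entries: Mapping[str, tuple[str, Iterable[str]]],
    reference_terms: Iterable[str] = REFERENCE_GO_TERMS,
    labels: Mapping[str, str] | None = None,
) -> dict[str, list[str]]:
    """Screen significant LIRCPs against a reference GO-term set.

    ``entries`` maps an accession to ``(tier, go_terms)``.  Entries in the
    not-significant tier are dropped; the rest are retained when they share
    at least one reference GO term, then partitioned by the supplied
    curation label map into groups A (validated LIR), B (known Atg8
    interactor), C (autophagy-linked) and D (candidates with no known
    autophagy link).
    """
    reference = set(reference_terms)
    if not reference:
        raise ValueError("reference term set must be non-empty")
    labels = labels or {}
    groups: dict[str, list[str]] = {"A": [], "B": [], "C": [], "D": []}
    for accession in sorted(entries):
        tier, terms = entries[accession]
        if tier == TIER_NOT:
            continue
        if not reference & set(terms):
            continue
        group = GROUP_OF_LABEL.get(labels.get(accession, ""), "D")
        groups[group].append(accession)
    return groups
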