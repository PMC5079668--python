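"""Ontology handling, hypergeometric testing, FDR, tiers and triage."""

import io
import math
from fractions import Fraction

import numpy as np
import pytest

from lirscan import (
    AnnotationSet,
    FixtureSpec,
    bh_adjust,
    classify_tier,
    compare_species,
    enrich,
    generate_annotations,
    hypergeom_pmf,
    hypergeom_upper_tail,
    map_to_slim,
    parse_obo,
    read_annotation_tsv,
    read_gaf,
    triage_candidates,
)
from lirscan.enrichment import (
    ComparabilityError,
    EnrichmentResult,
    OntologyError,
    TIER_HIGH,
    TIER_LOW,
    TIER_NOT,
    TIER_SIG,
)

MINI_OBO = """format-version: 1.2
ontology: test

[Term]
id: GO:0000003
name: grandparent
namespace: biological_process

[Term]
id: GO:0000002
name: parent
namespace: biological_process
is_a: GO:0000003 ! grandparent

[Term]
id: GO:0000001
name: leaf
namespace: biological_process
alt_id: GO:0099999
is_a: GO:0000002 ! parent

[Term]
id: GO:0000004
name: second parent
namespace: biological_process

[Term]
id: GO:0000005
name: diamond child
namespace: biological_process
is_a: GO:0000002 ! parent
is_a: GO:0000004 ! second parent

[Term]
id: GO:0000006
name: retired
namespace: biological_process
is_obsolete: true
"""


def mini_dag():
    return parse_obo(io.StringIO(MINI_OBO))


def enumeration_upper_tail(x, N, n, k):
    """Exact-fraction enumeration oracle for P(X >= x)."""
    total = Fraction(0)
    for i in range(x, min(n, k) + 1):
        total += Fraction(math.comb(k, i) * math.comb(N - k, n - i), math.comb(N, n))
    return float(total)


class TestParseObo:
    def test_single_term_ontology(self):
        dag = parse_obo(io.StringIO(
            "format-version: 1.2\n\n[Term]\nid: GO:1\nname: only\n"
            "namespace: biological_process\n"
        ))
        assert len(dag.graph) == 1 and dag.graph.number_of_edges() == 0

    def test_transitive_ancestors(self):
        dag = mini_dag()
        assert dag.ancestors("GO:0000001", include_self=False) == {
            "GO:0000002",
            "GO:0000003",
        }

    def test_multiple_parents_both_in_ancestors(self):
        anc = mini_dag().ancestors("GO:0000005", include_self=False)
        assert {"GO:0000002", "GO:0000004"} <= anc

    def test_obsolete_flag_and_alt_id(self):
        dag = mini_dag()
        assert "GO:0000006" in dag.obsolete
        assert dag.resolve("GO:0099999") == "GO:0000001"

    def test_cyclic_is_a_rejected(self):
        text = (
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:1\nname: a\nis_a: GO:2\n\n"
            "[Term]\nid: GO:2\nname: b\nis_a: GO:1\n"
        )
        with pytest.raises(OntologyError, match="cyclic"):
            parse_obo(io.StringIO(text))


class TestMapToSlim:
    def annotations(self, mapping):
        return AnnotationSet({k: set(v) for k, v in mapping.items()})

    def test_direct_slim_annotation_maps_to_itself(self):
        out = map_to_slim(
            self.annotations({"P1": ["GO:0000002"]}), mini_dag(), {"GO:0000002"}
        )
        assert out["P1"] == {"GO:0000002"}

    def test_no_slim_ancestor_maps_to_nothing(self):
        out = map_to_slim(
            self.annotations({"P1": ["GO:0000004"]}), mini_dag(), {"GO:0000002"}
        )
        assert out["P1"] == set()

    def test_min_ancestor_rule_stops_at_nearest_slim(self):
        # leaf is_a parent is_a grandparent, both parents slim -> parent only
        slim = {"GO:0000002", "GO:0000003"}
        out = map_to_slim(
            self.annotations({"P1": ["GO:0000001"]}), mini_dag(), slim, rule="min"
        )
        assert out["P1"] == {"GO:0000002"}
        closure = map_to_slim(
            self.annotations({"P1": ["GO:0000001"]}), mini_dag(), slim, rule="closure"
        )
        assert closure["P1"] == slim

    def test_obsolete_terms_never_map(self):
        out = map_to_slim(
            self.annotations({"P1": ["GO:0000006"]}), mini_dag(), {"GO:0000003"}
        )
        assert out["P1"] == set()

    def test_unknown_annotation_skipped_or_strict_raises(self):
        annotations = self.annotations({"P1": ["GO:7777777"]})
        out = map_to_slim(annotations, mini_dag(), {"GO:0000002"})
        assert out["P1"] == set()
        with pytest.raises(OntologyError):
            map_to_slim(annotations, mini_dag(), {"GO:0000002"}, strict=True)

    def test_distinct_protein_counts_match_independent_recount(
        self, annotation_fixture
    ):
        """Sum of per-protein slim indicators equals distribution counts."""
        af = annotation_fixture
        per_protein = map_to_slim(af.annotations, af.dag, af.slim_terms)
        for term, (_, n_true) in af.truth.term_counts.items():
            n = sum(1 for s in per_protein.values() if term in s)
            assert n == n_true


class TestHypergeometric:
    def test_pmf_printed_formula_example(self):
        assert hypergeom_pmf(3, 6, 3, 3) == pytest.approx(0.05, abs=1e-12)

    def test_pmf_degenerate_empty_draw(self):
        assert hypergeom_pmf(0, 50, 10, 0) == pytest.approx(1.0)

    def test_pmf_sums_to_one(self):
        total = sum(hypergeom_pmf(x, 12, 5, 4) for x in range(0, 5))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_upper_tail_at_zero_is_one(self):
        assert hypergeom_upper_tail(0, 100, 10, 5) == 1.0

    def test_upper_tail_single_term(self):
        assert hypergeom_upper_tail(5, 10, 5, 5) == pytest.approx(
            1 / 252, abs=1e-12
        )

    def test_upper_tail_matches_enumeration_small_universe(self):
        for N in (5, 9, 12):
            for n in range(N + 1):
                for k in range(N + 1):
                    for x in range(min(n, k) + 1):
                        assert hypergeom_upper_tail(x, N, n, k) == pytest.approx(
                            enumeration_upper_tail(x, N, n, k), abs=1e-12
                        )

    @pytest.mark.parametrize("args", [(4, 6, 3, 3), (1, 5, 6, 2), (-1, 5, 2, 2)])
    def test_bounds_violations_raise(self, args):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(*args)


class TestBH:
    def test_single_value_unchanged(self):
        assert bh_adjust([0.07]) == pytest.approx([0.07])

    def test_hand_computed_stepup(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_equal_values_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2, 0.2]) == pytest.approx([0.2] * 4)

    def test_never_below_raw_and_monotone(self):
        rng = np.random.default_rng(17)
        p = rng.random(25)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_domain_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestTiers:
    @pytest.mark.parametrize(
        "p_adj,tier",
        [
            (0.0, TIER_HIGH),
            (0.005, TIER_HIGH),
            (0.01, TIER_HIGH),
            (0.02, TIER_SIG),
            (0.05, TIER_SIG),
            (0.07, TIER_LOW),
            (0.1, TIER_LOW),
            (0.2, TIER_NOT),
            (1.0, TIER_NOT),
        ],
    )
    def test_four_intervals_with_inclusive_boundaries(self, p_adj, tier):
        assert classify_tier(p_adj) == tier

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_tier(1.5)


class TestEnrich:
    def test_empty_lircp_set_gives_unit_pvalues(self, annotation_fixture):
        af = annotation_fixture
        results = enrich(set(), af.annotations, af.dag, af.slim_terms)
        assert results
        assert all(r.x == 0 and r.p == 1.0 for r in results)

    def test_lircps_equal_universe_gives_unit_pvalues(self, annotation_fixture):
        af = annotation_fixture
        universe = {f"SYN{i + 1:04d}" for i in range(af.annotations.N)}
        results = enrich(universe, af.annotations, af.dag, af.slim_terms)
        assert all(r.x == r.n and r.p == pytest.approx(1.0) for r in results)

    def test_planted_term_ranks_first(self, annotation_fixture):
        af = annotation_fixture
        results = enrich(af.truth.lircps, af.annotations, af.dag, af.slim_terms)
        best = min(results, key=lambda r: r.p_adj)
        assert best.go_id == af.truth.enriched_term
        assert best.tier in {TIER_HIGH, TIER_SIG}

    def test_bh_applied_within_each_namespace(self, annotation_fixture):
        af = annotation_fixture
        results = enrich(af.truth.lircps, af.annotations, af.dag, af.slim_terms)
        for ns in {r.namespace for r in results}:
            group = [r for r in results if r.namespace == ns]
            recomputed = bh_adjust([r.p for r in group])
            assert [r.p_adj for r in group] == pytest.approx(list(recomputed))
            for r in group:
                assert r.tier == classify_tier(r.p_adj)
                assert 0 <= r.x <= min(r.n, r.k) and r.n <= r.N

    def test_counts_match_fixture_ground_truth(self, annotation_fixture):
        af = annotation_fixture
        results = {
            r.go_id: r
            for r in enrich(af.truth.lircps, af.annotations, af.dag, af.slim_terms)
        }
        for term, (x, n) in af.truth.term_counts.items():
            if n == 0:
                assert term not in results
            else:
                assert (results[term].x, results[term].n) == (x, n)


class TestCompareSpecies:
    def result(self, go_id, x, k, ns="BP"):
        return EnrichmentResult(go_id, ns, go_id, x, x, k, 100, 0.5, 0.5, TIER_SIG)

    def test_identical_inputs_give_zero_differences(self):
        res = [self.result("GO:1", 3, 10), self.result("GO:2", 5, 10)]
        pairs = compare_species(res, res)
        assert all(a == b for a, b in pairs.values())

    def test_degenerate_species_without_lircps(self):
        a = [self.result("GO:1", 3, 10)]
        b = [self.result("GO:1", 0, 0)]
        with pytest.warns(UserWarning, match="k=0"):
            pairs = compare_species(a, b)
        assert pairs["GO:1"] == (0.3, 0.0)

    def test_hand_computed_proportions_and_missing_terms(self):
        a = [self.result("GO:1", 2, 8), self.result("GO:2", 4, 8)]
        b = [self.result("GO:1", 1, 4), self.result("GO:3", 3, 4)]
        pairs = compare_species(a, b)
        assert pairs["GO:1"] == (0.25, 0.25)
        assert pairs["GO:2"] == (0.5, 0.0)
        assert pairs["GO:3"] == (0.0, 0.75)

    def test_mismatched_slim_versions_rejected(self):
        a = [self.result("GO:1", 2, 8, ns="BP")]
        b = [self.result("GO:1", 2, 8, ns="MF")]
        with pytest.raises(ComparabilityError):
            compare_species(a, b)


class TestTriage:
    ENTRIES = {
        "VAL1": (TIER_HIGH, {"GO:0006914"}),
        "INT1": (TIER_SIG, {"GO:0005515"}),
        "AUT1": (TIER_LOW, {"GO:0005739"}),
        "NEW1": (TIER_SIG, {"GO:0005634"}),
        "NOSIG": (TIER_NOT, {"GO:0006914"}),
        "NOREF": (TIER_HIGH, {"GO:1234567"}),
    }
    LABELS = {
        "VAL1": "validated",
        "INT1": "atg8_interactor",
        "AUT1": "autophagy_linked",
    }

    def test_partition_matches_label_map(self):
        groups = triage_candidates(self.ENTRIES, labels=self.LABELS)
        assert groups == {
            "A": ["VAL1"],
            "B": ["INT1"],
            "C": ["AUT1"],
            "D": ["NEW1"],
        }

    def test_not_significant_and_no_reference_term_excluded(self):
        groups = triage_candidates(self.ENTRIES, labels=self.LABELS)
        flat = [a for g in groups.values() for a in g]
        assert "NOSIG" not in flat and "NOREF" not in flat

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            triage_candidates(self.ENTRIES, reference_terms=set())


class TestReaders:
    def test_annotation_tsv(self, tmp_path):
        path = tmp_path / "annot.tsv"
        path.write_text(
            "accession\tgo_ids\nP1\tGO:1|GO:2\nP2\tGO:2\nP1\tGO:3\n"
        )
        ann = read_annotation_tsv(path)
        assert ann.mapping == {"P1": {"GO:1", "GO:2", "GO:3"}, "P2": {"GO:2"}}
        assert ann.N == 2

    def test_universe_override(self):
        ann = AnnotationSet({"P1": {"GO:1"}}, universe_size=50)
        assert ann.N == 50
        with pytest.raises(ValueError):
            AnnotationSet({"P1": {"GO:1"}, "P2": {"GO:1"}}, universe_size=1).N

    def test_gaf_reader(self, tmp_path):
        path = tmp_path / "test.gaf"
        path.write_text(
            "!gaf-version: 2.2\n"
            "UniProtKB\tP1\tGENE1\t\tGO:0005634\tPMID:1\tIDA\t\tC\t\t\t"
            "protein\ttaxon:9606\t20140101\tUniProt\n"
            "UniProtKB\tP1\tGENE1\t\tGO:0006914\tPMID:1\tIDA\t\tP\t\t\t"
            "protein\ttaxon:9606\t20140101\tUniProt\n"
        )
        ann = read_gaf(path)
        assert ann.mapping == {"P1": {"GO:0005634", "GO:0006914"}}
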