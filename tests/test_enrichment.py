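import io
import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netpharm.enrichment import (
    GeneSetCollection,
    GMTParseError,
    bh_fdr,
    hypergeom_enrich,
    pathway_impact,
    read_gmt,
    write_gmt,
)
from netpharm.network import Network
from oracles import bh_step_up, hypergeom_tail_by_enumeration


def make_coll(sets: dict, universe=None) -> GeneSetCollection:
    uni = frozenset(universe) if universe else frozenset().union(*map(frozenset, sets.values()))
    return GeneSetCollection(
        sets={k: frozenset(v) for k, v in sets.items()}, universe=uni
    )


class TestGMT:
    def test_two_line_gmt_universe_is_union(self):
        coll = read_gmt(io.StringIO("s1\tna\tA\tB\tC\ns2\tna\tC\tD\tE\n"))
        assert len(coll.universe) == 5
        assert coll.sets["s1"] == {"A", "B", "C"}

    def test_duplicate_gene_stored_once(self):
        coll = read_gmt(io.StringIO("s1\tna\tA\tA\tB\n"))
        assert coll.sets["s1"] == {"A", "B"}

    def test_short_line_raises(self):
        with pytest.raises(GMTParseError, match="line 1"):
            read_gmt(io.StringIO("s1\tonlydesc\n"))

    def test_round_trip_on_random_collections(self):
        rng = np.random.default_rng(8)
        genes = [f"G{i}" for i in range(30)]
        sets = {
            f"set{j}": set(rng.choice(genes, size=rng.integers(2, 10), replace=False))
            for j in range(6)
        }
        coll = make_coll(sets)
        buf = io.StringIO()
        write_gmt(coll, buf)
        again = read_gmt(io.StringIO(buf.getvalue()))
        assert again.sets == coll.sets and again.universe == coll.universe

    def test_sets_restricted_to_explicit_universe(self):
        coll = read_gmt(io.StringIO("s1\tna\tA\tB\tZ\n"), universe={"A", "B", "C"})
        assert coll.sets["s1"] == {"A", "B"}


class TestHypergeomEnrich:
    def test_full_overlap_closed_form(self):
        # universe 10, set 5, query 5, overlap 5: p = 1 / C(10, 5)
        genes = [f"G{i}" for i in range(10)]
        coll = make_coll({"s": genes[:5]}, universe=genes)
        res = hypergeom_enrich(genes[:5], coll, p_cutoff=1.0)
        assert res[0].p == pytest.approx(1 / comb(10, 5), rel=1e-12)
        assert res[0].k == 5

    def test_degenerate_set_equals_universe(self):
        genes = [f"G{i}" for i in range(6)]
        coll = make_coll({"all": genes}, universe=genes)
        res = hypergeom_enrich(["G0"], coll, p_cutoff=1.0)
        assert res[0].p == 1.0

    def test_universe_query_gives_p_one(self):
        genes = [f"G{i}" for i in range(8)]
        coll = make_coll({"s": genes[:3]}, universe=genes)
        res = hypergeom_enrich(genes, coll, p_cutoff=1.0)
        assert res[0].p == 1.0

    def test_small_instances_match_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(15):
            m = int(rng.integers(6, 16))
            genes = [f"G{i}" for i in range(m)]
            set_genes = frozenset(rng.choice(genes, size=rng.integers(2, m), replace=False))
            n_query = int(rng.integers(1, m))
            query = list(rng.choice(genes, size=n_query, replace=False))
            coll = make_coll({"s": set_genes}, universe=genes)
            res = hypergeom_enrich(query, coll, p_cutoff=1.0)
            k = len(set(query) & set_genes)
            oracle = hypergeom_tail_by_enumeration(
                frozenset(genes), set_genes, n_query, k
            )
            assert res[0].p == pytest.approx(oracle, abs=1e-12)

    def test_pvalues_invariant_under_relabeling(self):
        genes = [f"G{i}" for i in range(12)]
        coll = make_coll({"s": genes[:4]}, universe=genes)
        p1 = hypergeom_enrich(genes[2:7], coll, p_cutoff=1.0)[0].p
        relabel = {g: f"X{g}" for g in genes}
        coll2 = make_coll(
            {"s": [relabel[g] for g in genes[:4]]},
            universe=[relabel[g] for g in genes],
        )
        p2 = hypergeom_enrich([relabel[g] for g in genes[2:7]], coll2, p_cutoff=1.0)[0].p
        assert p1 == p2

    def test_planted_enriched_set_attains_min_p(self):
        """A query drawn 80% from one planted set should rank that set
        first in at least 95 of 100 seeded replicates."""
        genes = [f"G{i}" for i in range(200)]
        sets = {f"s{j}": genes[20 * j: 20 * (j + 1)] for j in range(10)}
        coll = make_coll(sets, universe=genes)
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            inside = rng.choice(sets["s3"], size=16, replace=False)
            outside = rng.choice(
                [g for g in genes if g not in set(sets["s3"])], size=4, replace=False
            )
            res = hypergeom_enrich([*inside, *outside], coll, p_cutoff=1.0)
            if res[0].pathway == "s3":
                wins += 1
        assert wins >= 95

    def test_empty_restricted_query_raises(self):
        coll = make_coll({"s": ["A", "B"]})
        with pytest.raises(ValueError, match="empty"):
            hypergeom_enrich(["Z1", "Z2"], coll)

    def test_fdr_at_least_p(self):
        genes = [f"G{i}" for i in range(30)]
        coll = make_coll({f"s{j}": genes[j: j + 8] for j in range(5)}, universe=genes)
        for r in hypergeom_enrich(genes[:6], coll, p_cutoff=1.0):
            assert r.fdr >= r.p - 1e-15


class TestBHFDR:
    def test_closed_form_triplet(self):
        assert bh_fdr([0.001, 0.01, 0.03]) == pytest.approx([0.003, 0.015, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]) == [pytest.approx(0.2)]

    def test_random_vectors_match_step_up_definition(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = list(rng.uniform(1e-6, 1, size=rng.integers(1, 40)))
            np.testing.assert_allclose(bh_fdr(p), bh_step_up(p), atol=1e-12)

    def test_output_dominates_input_and_is_monotone(self):
        rng = np.random.default_rng(3)
        p = list(rng.uniform(0.001, 1, 25))
        adj = bh_fdr(p)
        assert all(a >= x - 1e-15 for a, x in zip(adj, p))
        order = np.argsort(p)
        assert (np.diff(np.asarray(adj)[order]) >= -1e-15).all()
        # a constant vector is a fixed point of the adjustment
        np.testing.assert_allclose(bh_fdr([0.2] * 5), [0.2] * 5, atol=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=50))
    def test_step_up_definition_holds_for_any_vector(self, p):
        got = bh_fdr(p)
        np.testing.assert_allclose(got, bh_step_up(p), atol=1e-12)
        assert all(x <= 1.0 + 1e-15 for x in got)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_fdr([1.2])


class TestPathwayImpact:
    def test_no_matches_scores_zero(self, path_graph):
        assert pathway_impact(path_graph, set()) == 0.0

    def test_all_nodes_matched_scores_one(self, path_graph):
        assert pathway_impact(path_graph, {"A", "B", "C"}) == pytest.approx(1.0)

    def test_p3_center_carries_all_impact(self, path_graph):
        assert pathway_impact(path_graph, {"B"}) == pytest.approx(1.0)
        assert pathway_impact(path_graph, {"A"}) == 0.0

    def test_single_edge_graph_falls_back_to_node_fraction(self):
        net = Network.from_edges([("A", "B")])
        assert pathway_impact(net, {"A", "B"}) == pytest.approx(1.0)
        assert pathway_impact(net, {"A"}) == pytest.approx(0.5)

    def test_unknown_matched_node_rejected(self, path_graph):
        with pytest.raises(ValueError, match="absent"):
            pathway_impact(path_graph, {"Q"})
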