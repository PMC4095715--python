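import numpy as np
import pytest
from scipy import stats

from mpinet import (
    bh_fdr,
    compute_gcs,
    overlap_pvalue,
    pathway_crosstalk,
    pathway_gn_bias_test,
    pathway_relative_weight,
    wallenius_pvalue,
)
from mpinet.enrichment import EnrichmentContext, _wallenius_pmf_terms
from mpinet.pathways import Pathway, PathwayCollection

from conftest import make_network
from oracles import urn_exact_pmf, urn_monte_carlo, urn_upper_tail


class TestWalleniusPvalue:
    def test_g_zero_is_one(self):
        assert wallenius_pvalue(0, 5, 5, 20, 0.3) == 1.0

    def test_central_hand_case(self):
        # N=8, m1=4, n=3: P(X >= 2) = 28/56
        assert wallenius_pvalue(2, 3, 4, 8, 1.0, 1.0) == pytest.approx(0.5, abs=1e-10)

    def test_weighted_urn_hand_case(self):
        # sequential urn: (6/9) * (4/7) = 8/21
        assert wallenius_pvalue(2, 2, 3, 6, 2.0, 1.0) == pytest.approx(8 / 21, abs=1e-8)

    def test_degenerate_full_draw(self):
        assert wallenius_pvalue(3, 10, 3, 10, 0.5) == 1.0

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(g=5, n=4, m1=10, N=20, w1=1.0), "g"),
            (dict(g=1, n=4, m1=30, N=20, w1=1.0), "m1"),
            (dict(g=1, n=25, m1=10, N=20, w1=1.0), "n"),
            (dict(g=1, n=4, m1=10, N=20, w1=0.0), "w"),
            (dict(g=1, n=4, m1=10, N=20, w1=1.0, w2=-1.0), "w"),
        ],
    )
    def test_precondition_errors_name_offender(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            wallenius_pvalue(**kwargs)

    def test_reduces_to_central_hypergeometric(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            N = int(rng.integers(2, 31))
            m1 = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            g = int(rng.integers(0, min(n, m1) + 1))
            p = wallenius_pvalue(g, n, m1, N, 1.0, 1.0)
            ref = float(stats.hypergeom.sf(g - 1, N, m1, n))
            assert p == pytest.approx(ref, abs=1e-6)

    @pytest.mark.parametrize("w1", [0.1, 0.5, 2.0, 7.0])
    def test_matches_exact_urn_dynamic_program(self, w1):
        for n, m1, N in [(3, 4, 10), (5, 6, 14), (8, 5, 20), (12, 10, 25)]:
            pmf = _wallenius_pmf_terms(n, m1, N, w1, 1.0)
            ref = urn_exact_pmf(n, m1, N, w1, 1.0)
            assert np.abs(pmf - ref).max() < 1e-8

    def test_matches_monte_carlo_urn(self):
        n, m1, N, w1 = 8, 10, 30, 0.4
        draws = 100_000
        mc = urn_monte_carlo(n, m1, N, w1, 1.0, draws, seed=42)
        for g in range(1, min(n, m1) + 1):
            p = wallenius_pvalue(g, n, m1, N, w1)
            phat = mc[g:].sum()
            se = np.sqrt(max(p * (1 - p), 1e-12) / draws)
            assert abs(p - phat) <= 4 * se + 1e-9

    def test_monotone_nondecreasing_in_w1(self):
        grid = np.linspace(0.05, 10, 200)
        ps = [wallenius_pvalue(3, 8, 6, 30, w) for w in grid]
        assert (np.diff(ps) >= -1e-12).all()


def make_ctx(member_cgnb: dict[str, dict[str, float]], interesting=None):
    """Context from {pathway_id: {member: cgnb}} with full-coverage background."""
    cgnb = {}
    paths = []
    for pid, members in member_cgnb.items():
        cgnb.update(members)
        paths.append(Pathway(id=pid, name=pid, members=set(members)))
    background = set(cgnb)
    return EnrichmentContext(
        background=background,
        interesting=interesting or {next(iter(background))},
        cgnb=cgnb,
        collection=PathwayCollection(paths),
    )


class TestPathwayRelativeWeight:
    def test_equal_cgnb_gives_unit_weights(self):
        ctx = make_ctx(
            {"a": {"1": 0.4, "2": 0.4}, "b": {"3": 0.4, "4": 0.4, "5": 0.4}}
        )
        w = pathway_relative_weight(ctx)
        assert all(v == pytest.approx(1.0) for v in w.values())

    def test_two_pathway_hand_case(self):
        # (1 - C) member values {0.2, 0.4} and {0.6, 0.8} -> W = (0.6, 1.4)
        ctx = make_ctx(
            {"lo": {"1": 0.8, "2": 0.6}, "hi": {"3": 0.4, "4": 0.2}}
        )
        w = pathway_relative_weight(ctx)
        assert w["lo"] == pytest.approx(0.6)
        assert w["hi"] == pytest.approx(1.4)
        assert w["lo"] ** 6 == pytest.approx(0.046656)

    def test_mean_weight_is_one_on_random_contexts(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            member_cgnb = {}
            node = 1
            for k in range(int(rng.integers(2, 10))):
                size = int(rng.integers(2, 12))
                member_cgnb[f"p{k}"] = {
                    str(node + i): float(rng.uniform(0, 1)) for i in range(size)
                }
                node += size
            w = pathway_relative_weight(make_ctx(member_cgnb))
            assert np.mean(list(w.values())) == pytest.approx(1.0, abs=1e-9)

    def test_all_cgnb_one_errors(self):
        ctx = make_ctx({"a": {"1": 1.0, "2": 1.0}, "b": {"3": 1.0}})
        with pytest.raises(ValueError):
            pathway_relative_weight(ctx)

    def test_missing_cgnb_imputed_with_background_mean(self):
        cgnb = {"1": 0.4, "2": 0.4, "3": 0.4, "4": 0.4}
        coll = PathwayCollection(
            [
                Pathway(id="a", name="a", members={"1", "2", "5"}),  # 5 unscored
                Pathway(id="b", name="b", members={"3", "4"}),
            ]
        )
        ctx = EnrichmentContext(
            background={"1", "2", "3", "4", "5"},
            interesting={"1"},
            cgnb=cgnb,
            collection=coll,
        )
        w = pathway_relative_weight(ctx)
        # imputed value = mean of (1 - C) = 0.6, so both pathway means equal
        assert w["a"] == pytest.approx(1.0)
        assert w["b"] == pytest.approx(1.0)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        assert bh_fdr([0.005, 0.04, 0.03]) == pytest.approx([0.015, 0.04, 0.04])

    def test_all_equal_after_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_invalid_p_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.5])

    def test_matches_statsmodels_and_dominates_input(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, 200)
        adj = bh_fdr(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(adj, ref, atol=1e-12)
        assert (adj >= p - 1e-15).all()
        # significance order preserved: smaller p never gets larger adjusted p
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestPathwayGnBiasTest:
    def test_whole_network_pathway_p_is_one(self):
        rng = np.random.default_rng(1)
        gn = {str(i): float(rng.uniform(0, 1)) for i in range(1, 31)}
        coll = PathwayCollection([Pathway(id="all", name="all", members=set(gn))])
        p = pathway_gn_bias_test(coll, gn, sides="two")
        assert p["all"] == pytest.approx(1.0)

    def test_top_scoring_members_exact_one_sided(self):
        gn = {str(i): i / 20 for i in range(1, 21)}
        top3 = {"20", "19", "18"}
        coll = PathwayCollection([Pathway(id="top", name="top", members=top3)])
        p = pathway_gn_bias_test(coll, gn, sides="one")["top"]
        ref = stats.mannwhitneyu(
            [gn[m] for m in top3],
            list(gn.values()),
            alternative="greater",
            method="exact",
        ).pvalue
        assert p == pytest.approx(float(ref))
        assert p < 0.05

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(8)
        gn = {str(i): float(rng.normal()) for i in range(1, 101)}
        nodes = list(gn)
        ps = []
        for rep in range(300):
            members = set(rng.choice(nodes, size=12, replace=False))
            coll = PathwayCollection([Pathway(id="r", name="r", members=members)])
            ps.append(pathway_gn_bias_test(coll, gn, sides="two")["r"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_unknown_sides_errors(self):
        with pytest.raises(ValueError):
            pathway_gn_bias_test(
                PathwayCollection([Pathway(id="a", name="a", members={"1"})]),
                {"1": 0.5, "2": 0.6},
                sides="three",
            )


class TestPathwayCrosstalk:
    def test_disconnected_components_no_edge(self):
        net = make_network([(1, 2, 0.9), (2, 3, 0.9), (4, 5, 0.9), (5, 6, 0.9)])
        gcs = compute_gcs(net, 0.5, 4)
        coll = PathwayCollection(
            [
                Pathway(id="a", name="a", members={"1", "2", "3"}),
                Pathway(id="b", name="b", members={"4", "5", "6"}),
            ]
        )
        assert pathway_crosstalk(coll, gcs) == []

    def test_duplicated_pathway_mean_is_internal_mean(self):
        net = make_network(
            [(1, 2, 0.9), (2, 3, 0.8), (3, 4, 0.7), (4, 5, 0.6), (1, 5, 0.5)]
        )
        gcs = compute_gcs(net, 0.5, 4)
        members = {"1", "2", "3"}
        coll = PathwayCollection(
            [
                Pathway(id="a", name="a", members=members),
                Pathway(id="b", name="b", members=members),
            ]
        )
        edges = pathway_crosstalk(coll, gcs)
        idx = [gcs.index_of(m) for m in members]
        sub = gcs.values[np.ix_(idx, idx)]
        internal_mean = sub[~np.eye(3, dtype=bool)].mean()
        iu = np.triu_indices(5, k=1)
        median = np.median(gcs.values[iu])
        if internal_mean > median:
            assert edges == [("a", "b", pytest.approx(internal_mean))]
        else:
            assert edges == []

    def test_fewer_than_two_pathways_errors(self):
        net = make_network([(1, 2, 0.5)])
        gcs = compute_gcs(net, 0.5, 2)
        with pytest.raises(ValueError):
            pathway_crosstalk(
                PathwayCollection([Pathway(id="a", name="a", members={"1"})]), gcs
            )


class TestOverlapPvalue:
    def test_disjoint_lists_p_is_one(self):
        assert overlap_pvalue({"a", "b"}, {"c", "d"}, universe=20) == pytest.approx(1.0)

    def test_identical_full_lists(self):
        u = {str(i) for i in range(20)}
        assert overlap_pvalue(u, u, universe=20) == pytest.approx(1.0)

    def test_full_overlap_closed_form(self):
        a = {str(i) for i in range(5)}
        from math import comb

        assert overlap_pvalue(a, a, universe=20) == pytest.approx(1 / comb(20, 5))

    def test_list_exceeding_universe_errors(self):
        with pytest.raises(ValueError):
            overlap_pvalue({str(i) for i in range(30)}, {"1"}, universe=20)
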