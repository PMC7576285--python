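import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from immrisk.differential_coexpression import (
    NEG_TO_POS,
    POS_TO_NEG,
    STRENGTHENED,
    WEAKENED,
    CoexPair,
    build_network,
    classify_pattern,
    delta_histogram,
    fit_power_law,
    hub_report,
    pcc,
    screen_pairs,
)
from immrisk.expression_io import ExpressionMatrix, PipelineConfig

from oracles import pearson_r


def make_pair(gene, lnc, delta, population="pop", pcc_tumor=None, pcc_normal=None):
    if pcc_tumor is None:
        pcc_tumor = min(delta / 2, 1.0)
        pcc_normal = pcc_tumor - delta
    return CoexPair(
        population=population, gene_id=gene, lnc_id=lnc,
        pcc_tumor=pcc_tumor, pcc_normal=pcc_normal, p_tumor=0.01, p_normal=0.01,
        delta=delta, pattern=classify_pattern(pcc_normal, pcc_tumor),
    )


class TestPcc:
    def test_identity_and_antisymmetry(self):
        u = [1.0, 2.0, 4.0, 3.0]
        assert pcc(u, u)[0] == pytest.approx(1.0)
        assert pcc(u, [-x for x in u])[0] == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        u = [1.0, 2.0, 3.0, 4.0, 5.0]
        v = [2.0, 1.0, 4.0, 3.0, 6.0]
        r, p = pcc(u, v)
        assert r == pytest.approx(pearson_r(u, v), abs=1e-12)
        assert 0.0 < p < 1.0

    def test_agrees_with_oracle_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(3, 30)
            u = rng.normal(size=n)
            v = rng.normal(size=n)
            assert pcc(u, v)[0] == pytest.approx(pearson_r(list(u), list(v)), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pcc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pcc([1.0, 2.0], [2.0, 1.0])


class TestClassifyPattern:
    @pytest.mark.parametrize(
        "normal,tumor,expected",
        [
            (-0.58, 0.58, NEG_TO_POS),
            (0.70, -0.28, POS_TO_NEG),
            (0.4, 0.9, STRENGTHENED),
            (0.9, 0.4, WEAKENED),
            (-0.9, -0.4, WEAKENED),
            (-0.4, -0.9, STRENGTHENED),
            (0.3, 0.0, POS_TO_NEG),
            (-0.3, 0.0, NEG_TO_POS),
        ],
    )
    def test_pattern_table(self, normal, tumor, expected):
        assert classify_pattern(normal, tumor) == expected

    @given(
        st.floats(-1, 1, allow_nan=False),
        st.floats(-1, 1, allow_nan=False),
    )
    def test_pattern_consistent_with_signs(self, rn, rt):
        p = classify_pattern(rn, rt)
        if p == NEG_TO_POS:
            assert rn < 0 <= rt
        elif p == POS_TO_NEG:
            assert rn > 0 >= rt
        elif p == STRENGTHENED:
            assert abs(rt) > abs(rn)
        else:
            assert abs(rt) <= abs(rn)


def correlated_matrix(r_tumor, r_normal, n_t=50, n_n=50, seed=0):
    """One gene-lncRNA pair with given group correlations, plus a null pair."""
    rng = np.random.default_rng(seed)
    g_t, g_n = rng.normal(size=n_t), rng.normal(size=n_n)
    l_t = r_tumor * g_t + np.sqrt(1 - r_tumor**2) * rng.normal(size=n_t)
    l_n = r_normal * g_n + np.sqrt(1 - r_normal**2) * rng.normal(size=n_n)
    g2 = rng.normal(size=n_t + n_n)
    l2 = rng.normal(size=n_t + n_n)
    vals = pd.DataFrame(
        [np.r_[g_t, g_n], np.r_[l_t, l_n], g2, l2],
        index=["GA", "LA", "GB", "LB"],
        columns=[f"T{i}" for i in range(n_t)] + [f"N{i}" for i in range(n_n)],
    )
    return ExpressionMatrix(
        values=vals,
        feature_class=pd.Series(
            {"GA": "gene", "GB": "gene", "LA": "lncRNA", "LB": "lncRNA"}
        ),
        sample_group=pd.Series(["tumor"] * n_t + ["normal"] * n_n, index=vals.columns),
        log_scale=True,
    )


class TestScreenPairs:
    def test_sign_flip_pair_retained_null_pair_not(self):
        x = correlated_matrix(0.9, -0.9, seed=1)
        pairs = screen_pairs(x, {"pop": ["GA", "GB"]}, ["LA", "LB"])
        keys = {(p.gene_id, p.lnc_id) for p in pairs}
        assert ("GA", "LA") in keys
        planted = next(p for p in pairs if (p.gene_id, p.lnc_id) == ("GA", "LA"))
        assert planted.delta > 1.5
        assert planted.pattern == NEG_TO_POS
        assert planted.delta == pytest.approx(abs(planted.pcc_tumor - planted.pcc_normal))

    def test_identical_structure_in_both_groups_yields_nothing(self):
        x = correlated_matrix(0.8, 0.8, n_t=100, n_n=100, seed=2)
        assert screen_pairs(x, {"pop": ["GA", "GB"]}, ["LA", "LB"]) == []

    def test_invariant_to_sample_and_feature_order(self):
        x = correlated_matrix(0.9, -0.5, seed=3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(x.values.columns)
        x2 = ExpressionMatrix(
            values=x.values.loc[["LB", "GB", "LA", "GA"], perm],
            feature_class=x.feature_class,
            sample_group=x.sample_group[perm],
            log_scale=True,
        )
        p1 = screen_pairs(x, {"pop": ["GA", "GB"]}, ["LA", "LB"])
        p2 = screen_pairs(x2, {"pop": ["GA", "GB"]}, ["LA", "LB"])
        k1 = sorted((p.gene_id, p.lnc_id, round(p.delta, 12)) for p in p1)
        k2 = sorted((p.gene_id, p.lnc_id, round(p.delta, 12)) for p in p2)
        assert k1 == k2

    def test_population_without_genes_is_empty(self):
        x = correlated_matrix(0.9, -0.9)
        assert screen_pairs(x, {"pop": []}, ["LA"]) == []

    def test_histogram_bins_from_threshold(self):
        pairs = [make_pair("G", f"L{i}", d) for i, d in enumerate([0.35, 0.45, 0.42, 1.16])]
        h = delta_histogram(pairs)
        assert h["0.3-0.4"] == 1
        assert h["0.4-0.5"] == 2
        assert h.sum() == 4


class TestBuildNetwork:
    def test_strict_threshold_filters_edges(self):
        pairs = [make_pair("G1", "L1", 0.75), make_pair("G1", "L2", 0.72),
                 make_pair("G2", "L1", 0.40), make_pair("G2", "L3", 0.70)]
        net = build_network(pairs, PipelineConfig(), scope="pop")
        assert len(net) == 2
        assert all(p.delta > 0.7 for p in net.edges)

    def test_star_degrees(self):
        pairs = [make_pair("G1", f"L{i}", 0.9) for i in range(5)]
        net = build_network(pairs, scope="pop")
        assert net.degree["G1"] == 5
        assert all(net.degree[f"L{i}"] == 1 for i in range(5))
        assert sum(net.degree.values()) == 2 * len(net)

    def test_integrated_dedup_keeps_max_delta(self):
        pairs = [make_pair("G1", "L1", 0.8, population="a"),
                 make_pair("G1", "L1", 0.9, population="b")]
        net = build_network(pairs, scope="integrated")
        assert len(net) == 1
        assert net.edges[0].delta == 0.9

    def test_bipartite(self):
        pairs = [make_pair(f"G{i}", f"L{j}", 0.9) for i in range(3) for j in range(4)]
        net = build_network(pairs, scope="pop")
        kinds = {n: d["kind"] for n, d in net.graph.nodes(data=True)}
        for u, v in net.graph.edges:
            assert {kinds[u], kinds[v]} == {"gene", "lncRNA"}

    def test_empty_network_is_valid(self):
        net = build_network([make_pair("G1", "L1", 0.5)], scope="pop")
        assert len(net) == 0
        assert net.degree == {}


class TestFitPowerLaw:
    def test_exact_inverse_square_law(self):
        c = 705600  # divisible by d^2 for d = 1..8
        freq = {d: c // d**2 for d in range(1, 9)}
        fit = fit_power_law(freq)
        assert fit.slope == pytest.approx(-2.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.n_points == 8

    def test_regular_graph_rejected(self):
        pairs = [make_pair("G1", "L1", 0.9), make_pair("G2", "L2", 0.9)]
        net = build_network(pairs, scope="integrated")
        with pytest.raises(ValueError, match="degree diversity"):
            fit_power_law(net)

    def test_preferential_attachment_like_network_has_negative_slope(self):
        rng = np.random.default_rng(0)
        pairs, genes = [], ["G0"]
        for i in range(300):
            # new lncRNA attaches to a gene chosen proportional to occurrences
            g = genes[rng.integers(len(genes))]
            pairs.append(make_pair(g, f"L{i}", 0.9))
            genes.append(g)
            if rng.random() < 0.15:
                genes.append(f"G{i}")
        fit = fit_power_law(build_network(pairs, scope="integrated"))
        assert fit.slope < 0


class TestHubReport:
    def test_top_hub_and_tie_break(self):
        pairs = [make_pair("G1", f"L{i:02d}", 0.9) for i in range(6)]
        pairs += [make_pair("G2", "L00", 0.9), make_pair("G2", "L01", 0.9)]
        pairs += [make_pair("G0", "L00", 0.9), make_pair("G3", "L07", 0.9)]
        report = hub_report(build_network(pairs, scope="integrated"), top_k=3)
        genes = report[report["kind"] == "gene"]
        assert list(genes["node"]) == ["G1", "G2", "G0"]  # 6, 2, then tie 1/1 lexicographic
        lncs = report[report["kind"] == "lncRNA"]
        assert list(lncs["node"])[:2] == ["L00", "L01"]

    def test_empty_network_empty_report(self):
        report = hub_report(build_network([], scope="integrated"))
        assert report.empty
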