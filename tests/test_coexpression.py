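"""Pearson/partial correlation, significance classification, network building."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coexprofiler.coexpression import (
    CorrelationEdge,
    Thresholds,
    UndefinedCorrelationError,
    build_network,
    classify_edge,
    correlation_matrix,
    edges_to_frame,
    null_strong_probability,
    partial_with_p,
    pearson_with_p,
)


class TestPearsonWithP:
    def test_exact_linear_relation(self):
        r, p, n = pearson_with_p([1, 2, 3], [2, 4, 6])
        assert r == 1.0 and p == 0.0 and n == 3

    def test_exact_inverse_relation(self):
        r, p, _ = pearson_with_p([1, 2, 3, 4], [4, 3, 2, 1])
        assert r == -1.0 and p == 0.0

    def test_moderate_correlation_matches_t_transform(self):
        # frozen from the product-moment formula + t tail (verified vs scipy)
        r, p, n = pearson_with_p([1, 2, 3, 4, 5], [2, 1, 4, 3, 6])
        assert r == pytest.approx(0.8219949365, abs=1e-9)
        assert p == pytest.approx(0.0877066470, abs=1e-9)
        assert n == 5

    def test_zero_variance_is_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3"):
            pearson_with_p([1.0, 2.0], [1.0, 2.0])

    def test_matches_scipy_oracle_on_random_pairs(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=10), rng.normal(size=10)
            r, p, _ = pearson_with_p(x, y)
            expected = stats.pearsonr(x, y)
            assert r == pytest.approx(expected.statistic, abs=1e-12)
            assert p == pytest.approx(expected.pvalue, abs=1e-12)


class TestPartialWithP:
    def test_single_group_equals_plain_pearson(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=8)
        rp, pp, n, k = partial_with_p(x, y, ["all"] * 8)
        r0, p0, _ = pearson_with_p(x, y)
        assert k == 1
        assert rp == pytest.approx(r0, abs=1e-12)
        assert pp == pytest.approx(p0, abs=1e-12)

    def test_hand_residualized_two_group_example(self):
        # residuals: x -> [-0.5, 0.5, -0.5, 0.5], y -> [-1, 1, -1, 1]; r = 1
        r, p, n, k = partial_with_p([1, 2, 5, 6], [1, 3, 5, 7], ["A", "A", "B", "B"])
        assert r == pytest.approx(1.0)
        assert n == 4 and k == 2  # df = 4 - 2 - 1 = 1

    def test_group_means_only_is_undefined(self):
        # x and y constant within groups: residuals are identically zero
        with pytest.raises(UndefinedCorrelationError):
            partial_with_p([1, 1, 5, 5], [2, 2, 7, 7], ["A", "A", "B", "B"])

    def test_df_exhaustion_rejected(self):
        with pytest.raises(ValueError, match="df"):
            partial_with_p([1, 2, 3, 4], [1, 2, 3, 4], ["A", "B", "C", "D"])

    def test_matches_pingouin_oracle(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x, y = rng.normal(size=12), rng.normal(size=12)
        groups = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        r, p, _, _ = partial_with_p(x, y, groups)
        frame = pd.DataFrame({
            "x": x, "y": y,
            "gB": [1.0 if g == "B" else 0.0 for g in groups],
            "gC": [1.0 if g == "C" else 0.0 for g in groups],
        })
        expected = pingouin.partial_corr(frame, x="x", y="y", covar=["gB", "gC"])
        assert r == pytest.approx(float(expected["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(expected["p_val"].iloc[0]), abs=1e-10)


class TestClassifyEdge:
    @pytest.mark.parametrize(
        "r,p,expected",
        [
            (0.94, 0.06, "approaching"),
            (0.95, 0.05, "approaching"),  # p < 0.05 is strict
            (-0.84, 0.075, "approaching"),
            (0.80, 0.01, "strong"),
            (0.50, 0.001, "absent"),
            (0.75, 0.049, "strong"),  # |r| >= 0.75 is inclusive
            (-0.75, 0.0999, "approaching"),
            (0.9, 0.10, "absent"),
        ],
    )
    def test_study_threshold_calls(self, r, p, expected):
        assert classify_edge(r, p) == expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_edge(1.5, 0.01)
        with pytest.raises(ValueError):
            classify_edge(0.5, -0.1)

    def test_custom_thresholds(self):
        lax = Thresholds(r_min=0.5, alpha=0.1, approach_max=0.2)
        assert classify_edge(0.6, 0.05, lax) == "strong"

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            Thresholds(r_min=1.5)
        with pytest.raises(ValueError):
            Thresholds(approach_max=0.01)


class TestBuildNetwork:
    def test_combinatorial_edge_bound(self, rng):
        matrix = pd.DataFrame(
            rng.normal(size=(5, 10)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{j}" for j in range(10)],
        )
        edges = build_network(matrix, setting_id="x")
        assert len(edges) == 10  # C(5,2)

    def test_identical_genes_give_perfect_strong_edge(self, rng):
        base = rng.normal(size=8)
        matrix = pd.DataFrame([base, base.copy(), rng.normal(size=8)],
                              index=["A", "B", "C"], columns=[f"s{j}" for j in range(8)])
        edges = {e.pair: e for e in build_network(matrix)}
        edge = edges[("A", "B")]
        assert edge.r == pytest.approx(1.0) and edge.sig_class == "strong"

    def test_zero_variance_pairs_are_omitted(self, rng):
        matrix = pd.DataFrame(
            [np.ones(6), rng.normal(size=6), rng.normal(size=6)],
            index=["flat", "A", "B"], columns=[f"s{j}" for j in range(6)],
        )
        edges = build_network(matrix)
        pairs = {e.pair for e in edges}
        assert pairs == {("A", "B")}

    def test_too_few_samples_rejected(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(4, 2)), index=list("abcd"),
                              columns=["s1", "s2"])
        with pytest.raises(ValueError, match="samples"):
            build_network(matrix)

    def test_pair_restriction(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(4, 8)), index=list("ABCD"),
                              columns=[f"s{j}" for j in range(8)])
        edges = build_network(matrix, gene_pairs=[("B", "A"), ("C", "D")])
        assert {e.pair for e in edges} == {("A", "B"), ("C", "D")}

    def test_canonical_pair_order(self):
        edge = CorrelationEdge("Zfp", "Ar", r=0.5, p=0.5, n=5)
        assert edge.pair == ("Ar", "Zfp")

    def test_brute_force_equivalence_all_pairs(self, rng):
        """All-pairs vectorized path matches the scalar per-pair oracle to 1e-10."""
        matrix = pd.DataFrame(
            rng.normal(size=(8, 10)),
            index=[f"g{i}" for i in range(8)],
            columns=[f"s{j}" for j in range(10)],
        )
        edges = {e.pair: e for e in build_network(matrix)}
        assert len(edges) == 28
        for (a, b), edge in edges.items():
            r, p, _ = pearson_with_p(matrix.loc[a], matrix.loc[b])
            assert edge.r == pytest.approx(r, abs=1e-10)
            assert edge.p == pytest.approx(p, abs=1e-10)

    def test_partial_network_uses_metadata_subgroups(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(3, 8)), index=list("ABC"),
                              columns=[f"s{j}" for j in range(8)])
        metadata = pd.DataFrame({
            "sample_id": matrix.columns,
            "setting_id": "e", "condition": "control",
            "subgroup": ["F1"] * 4 + ["F2"] * 4,
            "species": "rat", "compound": "",
        })
        edges = build_network(matrix, metadata, method="partial")
        assert all(e.k_groups == 2 and e.method == "partial" for e in edges)
        r, p, _, _ = partial_with_p(matrix.loc["A"], matrix.loc["B"],
                                    ["F1"] * 4 + ["F2"] * 4)
        by_pair = {e.pair: e for e in edges}
        assert by_pair[("A", "B")].r == pytest.approx(r, abs=1e-12)


class TestCorrelationMatrix:
    def test_agrees_with_numpy_corrcoef(self, rng):
        values = rng.normal(size=(6, 9))
        R, P, df = correlation_matrix(values)
        assert df == 7
        np.testing.assert_allclose(R, np.corrcoef(values), atol=1e-12)

    def test_partial_reduces_df(self, rng):
        values = rng.normal(size=(4, 9))
        _, _, df = correlation_matrix(values, groups=["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert df == 9 - 2 - 2


class TestNullStrongProbability:
    def test_r_threshold_binds_at_n_12(self):
        # at n=12 the p<0.05 bound corresponds to |r|~0.576 < 0.75
        p0 = null_strong_probability(12)
        t = 0.75 * np.sqrt(10) / np.sqrt(1 - 0.75**2)
        assert p0 == pytest.approx(2 * stats.t.sf(t, 10), rel=1e-12)

    def test_null_rate_shrinks_with_sample_size(self):
        # the null distribution of r concentrates near 0 as n grows, so the
        # chance of clearing a fixed |r| >= 0.75 bar falls
        assert null_strong_probability(30) < null_strong_probability(12)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            null_strong_probability(2)


def test_edges_to_frame_round_trip_columns(rng):
    matrix = pd.DataFrame(rng.normal(size=(3, 6)), index=list("ABC"),
                          columns=[f"s{j}" for j in range(6)])
    frame = edges_to_frame(build_network(matrix, setting_id="t"))
    assert list(frame.columns) == [
        "gene_a", "gene_b", "r", "p", "n", "k_groups", "method", "setting_id", "sig_class"
    ]
    assert len(frame) == 3
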