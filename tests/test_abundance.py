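"""Abundance roll-up, contrasts, partial correlation, enrichment, clustering."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from turnoverkit.abundance import (
    AbundanceMatrix,
    cluster_order,
    contrast_ratios,
    fisher_enrichment,
    group_difference_tests,
    partial_correlation,
    pathway_correlations,
    protein_abundance,
)


def tidy_areas():
    rows = [
        # protein, peptide, sample, group, total_area
        ("P1", "a", "s1", "G1", 3.0),
        ("P1", "b", "s1", "G1", 7.0),
        ("P1", "a", "s2", "G2", 4.0),  # peptide b missing in s2
        ("P2", "c", "s1", "G1", 5.0),
        ("P2", "c", "s2", "G2", 10.0),
    ]
    return pd.DataFrame(rows, columns=["protein", "peptide", "sample", "group", "total_area"])


class TestProteinAbundance:
    def test_sum_rule_and_missing_peptides(self):
        mat = protein_abundance(tidy_areas())
        assert mat.values.loc["P1", "s1"] == 10.0  # 3 + 7
        assert mat.values.loc["P1", "s2"] == 4.0  # missing peptide absent, not zero
        assert mat.sample_groups["s2"] == "G2"

    def test_permutation_invariance(self):
        a = protein_abundance(tidy_areas())
        b = protein_abundance(tidy_areas().sample(frac=1.0, random_state=1))
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_negative_areas_rejected(self):
        df = tidy_areas()
        df.loc[0, "total_area"] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            protein_abundance(df)


class TestContrastRatios:
    @staticmethod
    def matrix():
        values = pd.DataFrame(
            {
                "s1": [8.0, 2.0, 0.0],
                "s2": [8.0, 2.0, 0.0],
                "s3": [2.0, 2.0, 5.0],
                "s4": [2.0, 2.0, 5.0],
            },
            index=["P1", "P2", "P3"],
        )
        groups = pd.Series(["A", "A", "B", "B"], index=values.columns)
        return AbundanceMatrix(values=values, sample_groups=groups)

    def test_log2_of_mean_ratio(self):
        (r,) = contrast_ratios(self.matrix(), [("A", "B")])
        assert r.log2_ratio["P1"] == pytest.approx(2.0)  # 8 vs 2
        assert r.log2_ratio["P2"] == pytest.approx(0.0)

    def test_zero_mean_protein_dropped(self):
        (r,) = contrast_ratios(self.matrix(), [("A", "B")])
        assert "P3" not in r.log2_ratio.index
        assert r.n_dropped == 1

    def test_antisymmetry(self):
        ab, ba = contrast_ratios(self.matrix(), [("A", "B"), ("B", "A")])
        pd.testing.assert_series_equal(ab.log2_ratio, -ba.log2_ratio)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="no samples"):
            contrast_ratios(self.matrix(), [("A", "C")])


class TestPartialCorrelation:
    def test_closed_form_example(self, rng):
        # r_xy = r_xz = r_yz = 0.5 -> r_xy.z = (0.5 - 0.25) / 0.75 = 1/3.
        # Construct x, y, z with those exact Pearson correlations via Cholesky
        # on ranks disabled (rank_based=False keeps the algebra exact).
        n = 400
        R = np.array([[1, 0.5, 0.5], [0.5, 1, 0.5], [0.5, 0.5, 1]])
        L = np.linalg.cholesky(R)
        raw = rng.standard_normal((3, n))
        raw -= raw.mean(axis=1, keepdims=True)
        # orthonormalize so empirical correlations are exactly R
        q, _ = np.linalg.qr(raw.T)
        x, y, z = (L @ q.T[:3]) if False else (L @ q.T)
        res = partial_correlation(x, y, z, rank_based=False)
        assert res.r_partial == pytest.approx(1.0 / 3.0, abs=1e-10)

    def test_self_correlation_tends_to_one(self, rng):
        x = rng.standard_normal(500)
        z = rng.standard_normal(500)
        res = partial_correlation(x, x + 1e-9 * z, z)
        assert res.r_partial > 0.999

    def test_matches_pingouin_oracle(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x, y, z = rng.standard_normal((3, 60))
        y = 0.5 * x + y
        for rank in (False, True):
            mine = partial_correlation(x, y, z, rank_based=rank)
            ref = pingouin.partial_corr(
                data=pd.DataFrame({"x": x, "y": y, "z": z}),
                x="x", y="y", covar="z",
                method="spearman" if rank else "pearson",
            )
            assert mine.r_partial == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
            assert mine.p_value == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_spurious_ratio_correlation_removed(self, rng):
        n = 2000
        logA, logB, logC = rng.normal(0, 1, (3, n))
        u = np.exp(logA - logC)
        v = np.exp(logB - logC)
        from scipy.stats import spearmanr

        raw = spearmanr(u, v).statistic
        res = partial_correlation(u, v, logC)
        assert raw > 0.3
        assert abs(res.r_partial) < 0.05

    def test_symmetry_and_rank_invariance(self, rng):
        x, y, z = rng.standard_normal((3, 50))
        a = partial_correlation(x, y, z)
        b = partial_correlation(y, x, z)
        assert a.r_partial == pytest.approx(b.r_partial, abs=1e-12)
        c = partial_correlation(3.0 * x + 7.0, y, z)  # positive affine on ranks
        assert c.r_partial == pytest.approx(a.r_partial, abs=1e-12)

    def test_degenerate_inputs_rejected(self, rng):
        x = rng.standard_normal(20)
        with pytest.raises(ValueError, match="degenerate"):
            partial_correlation(x, np.ones(20), x, rank_based=False)
        with pytest.raises(ValueError, match="collinear"):
            partial_correlation(x, rng.standard_normal(20), x, rank_based=False)
        with pytest.raises(ValueError, match="n >= 4"):
            partial_correlation(x[:3], x[:3], x[:3])


class TestPathwayCorrelations:
    def test_perfect_agreement(self):
        idx = [f"P{i}" for i in range(10)]
        a = pd.Series(np.arange(10.0), index=idx)
        table, pooled = pathway_correlations(a, a, {"path1": set(idx)})
        assert table["spearman_r"].iloc[0] == pytest.approx(1.0)
        assert pooled["ols_slope"] == pytest.approx(1.0)
        table, _ = pathway_correlations(a, -a, {"path1": set(idx)})
        assert table["spearman_r"].iloc[0] == pytest.approx(-1.0)

    def test_known_permutation_rank_correlation(self):
        # swapping two of ten ranks: rho = 1 - 6*sum(d^2)/(n(n^2-1)) with
        # d^2 = 2 for adjacent swap of ranks 1 and 2 -> 1 - 12/990
        idx = [f"P{i}" for i in range(10)]
        a = pd.Series(np.arange(10.0), index=idx)
        b = a.copy()
        b.iloc[0], b.iloc[1] = a.iloc[1], a.iloc[0]
        table, _ = pathway_correlations(a, b, {"path1": set(idx)})
        assert table["spearman_r"].iloc[0] == pytest.approx(1 - 12 / 990, abs=1e-12)

    def test_small_pathways_skipped(self):
        idx = [f"P{i}" for i in range(10)]
        a = pd.Series(np.arange(10.0), index=idx)
        table, _ = pathway_correlations(a, a, {"tiny": {"P0", "P1"}})
        assert table.empty


def exact_hypergeom_upper_tail(M, n, N, k):
    """Brute-force oracle: P(X >= k) as an exact rational tail sum."""
    total = Fraction(0)
    for j in range(k, min(n, N) + 1):
        total += Fraction(math.comb(n, j) * math.comb(M - n, N - j), math.comb(M, N))
    return float(total)


class TestFisherEnrichment:
    def test_worked_four_gene_example(self):
        universe = {"g1", "g2", "g3", "g4"}
        table = fisher_enrichment({"g1", "g2"}, {"path": {"g1", "g2"}}, universe)
        assert table["p_value"].iloc[0] == pytest.approx(1 / 6, abs=1e-12)

    def test_pathway_equal_to_universe_is_unenriched(self):
        universe = {"g1", "g2", "g3", "g4"}
        table = fisher_enrichment({"g1"}, {"all": set(universe)}, universe)
        assert table["p_value"].iloc[0] == pytest.approx(1.0)

    def test_empty_overlap_large_p(self):
        universe = {f"g{i}" for i in range(10)}
        table = fisher_enrichment({"g0", "g1"}, {"path": {"g8", "g9"}}, universe)
        oracle = exact_hypergeom_upper_tail(10, 2, 2, 0)
        assert table["p_value"].iloc[0] == pytest.approx(oracle, abs=1e-12)
        assert table["p_value"].iloc[0] >= 0.5

    def test_matches_exact_tail_sums(self):
        """Sweep of tables across universe sizes against the exact oracle
        (the exhaustive sweep to M = 50 runs in the acceptance suite)."""
        for M in (4, 7, 12):
            universe = [f"g{i}" for i in range(M)]
            for N in range(0, M + 1):
                sig = set(universe[:N])
                pathways = {}
                expected = {}
                for n in range(0, M + 1):
                    for k in range(max(0, n + N - M), min(n, N) + 1):
                        members = set(universe[:k]) | set(universe[N : N + n - k])
                        name = f"n{n}k{k}"
                        pathways[name] = members
                        expected[name] = exact_hypergeom_upper_tail(M, n, N, k)
                if not pathways:
                    continue
                table = fisher_enrichment(sig, pathways, set(universe))
                for name, p in zip(table["pathway"], table["p_value"]):
                    assert p == pytest.approx(expected[name], abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="empty universe"):
            fisher_enrichment(set(), {}, set())
        with pytest.raises(ValueError, match="subset"):
            fisher_enrichment({"x"}, {}, {"y"})


class TestClusterOrder:
    def test_nearest_pair_merges_first(self):
        mat = pd.DataFrame({"v": [0.0, 0.1, 10.0]}, index=["a", "b", "c"])
        order = cluster_order(mat)
        assert {order[0], order[1]} == {"a", "b"} or {order[1], order[2]} == {"a", "b"}
        # the close pair is adjacent
        ia, ib = order.index("a"), order.index("b")
        assert abs(ia - ib) == 1

    def test_single_row_identity(self):
        mat = pd.DataFrame({"v": [1.0]}, index=["only"])
        assert cluster_order(mat) == ["only"]

    def test_duplicate_rows_adjacent(self):
        mat = pd.DataFrame(
            [[0.0, 0.0], [5.0, 5.0], [0.0, 0.0], [9.0, 1.0]],
            index=["a", "b", "a2", "c"],
        )
        order = cluster_order(mat)
        assert abs(order.index("a") - order.index("a2")) == 1

    def test_missing_values_imputed_by_row_mean(self):
        mat = pd.DataFrame(
            [[1.0, np.nan], [1.0, 1.0], [50.0, 50.0]], index=["a", "b", "c"]
        )
        order = cluster_order(mat)
        assert abs(order.index("a") - order.index("b")) == 1

    def test_all_missing_row_rejected(self):
        mat = pd.DataFrame([[np.nan, np.nan], [1.0, 2.0]], index=["a", "b"])
        with pytest.raises(ValueError, match="missing"):
            cluster_order(mat)

    def test_column_axis_and_ward(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.normal(size=(5, 4)), columns=list("wxyz"))
        order = cluster_order(mat, axis="columns", method="ward")
        assert sorted(order) == list("wxyz")


class TestGroupDifferenceTests:
    def test_detects_planted_shift(self, rng):
        n = 50
        base = rng.normal(20, 1, n)
        vals = {}
        for i in range(6):
            vals[f"a{i}"] = np.exp2(base + rng.normal(0, 0.1, n))
            shift = np.r_[np.full(10, 2.0), np.zeros(n - 10)]
            vals[f"b{i}"] = np.exp2(base + shift + rng.normal(0, 0.1, n))
        values = pd.DataFrame(vals, index=[f"P{i}" for i in range(n)])
        groups = pd.Series(
            {k: "A" if k.startswith("a") else "B" for k in vals}
        )
        mat = AbundanceMatrix(values=values, sample_groups=groups)
        res = group_difference_tests(mat, "A", "B").set_index("protein")
        assert (res.loc[[f"P{i}" for i in range(10)], "q_value"] < 0.05).all()
        assert res.iloc[10:]["p_value"].median() > 0.2


@given(st.integers(0, 2**31 - 1))
@settings(deadline=None, max_examples=20)
def test_contrast_antisymmetry_property(seed):
    rng = np.random.default_rng(seed)
    values = pd.DataFrame(
        rng.lognormal(3, 1, size=(8, 6)),
        index=[f"P{i}" for i in range(8)],
        columns=[f"s{i}" for i in range(6)],
    )
    groups = pd.Series(["A"] * 3 + ["B"] * 3, index=values.columns)
    mat = AbundanceMatrix(values=values, sample_groups=groups)
    ab, ba = contrast_ratios(mat, [("A", "B"), ("B", "A")])
    np.testing.assert_allclose(ab.log2_ratio, -ba.log2_ratio, atol=1e-12)
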