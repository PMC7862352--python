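import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chrombarcode import (
    classify_quadrants,
    genes_in_windows,
    intensity_difference,
    quadrant_expression_summary,
    select_tails,
    track_quadrants,
)
from chrombarcode.differential import QUADRANTS
from chrombarcode.io import IntervalSet

from conftest import make_genes


class TestIntensityDifference:
    def test_null_with_tiny_jitter_controls_fdr(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 2000)
        y = x + rng.normal(0, 1e-3, 2000)
        res = intensity_difference(x, y)
        assert (res.df["q"] < 0.05).mean() < 0.01  # BH keeps false positives in check

    def test_antisymmetric_under_condition_swap(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 500)
        y = x + rng.normal(0, 0.3, 500)
        fwd = intensity_difference(x, y)
        rev = intensity_difference(y, x)
        np.testing.assert_allclose(rev.df["d"], -fwd.df["d"], atol=1e-12)
        np.testing.assert_allclose(rev.df["p"], fwd.df["p"], atol=1e-12)

    def test_neighbourhood_size_floor_applies(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 200)
        res = intensity_difference(x, x + rng.normal(0, 0.1, 200), frac=0.01, min_k=50)
        assert res.k == 50  # ceil(0.01*200)=2 < min_k

    def test_too_few_features_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            intensity_difference(np.arange(10.0), np.arange(10.0), min_k=50)

    def test_degenerate_local_sigma_flagged_untestable(self):
        x = np.arange(60.0)
        y = x.copy()  # all d identical (0) -> sigma 0 everywhere
        with pytest.warns(UserWarning, match="untestable"):
            res = intensity_difference(x, y)
        assert res.df["p"].isna().all()

    def test_planted_shifts_recovered(self):
        rng = np.random.default_rng(3)
        n, sig = 4000, 0.5
        m = rng.uniform(0, 10, n)
        d = rng.normal(0, sig, n)
        x, y = m - d / 2, m + d / 2
        idx = rng.choice(n, 40, replace=False)
        y[idx] += 4 * sig
        res = intensity_difference(x, y)
        assert (res.df["p"].to_numpy()[idx] < 0.05).mean() >= 0.9
        assert (res.df["p"].to_numpy()[idx] < 0.5).mean() >= 0.99


class TestSelectTails:
    def test_three_percent_of_hundred_is_three_per_tail(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=100), rng.normal(size=100)
        sel = select_tails(x, y, fraction=0.03)
        assert len(sel.lower) == len(sel.upper) == 3

    def test_swap_exchanges_tails(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=200), rng.normal(size=200)
        fwd = select_tails(x, y)
        rev = select_tails(y, x)
        assert set(fwd.upper["feature_id"]) == set(rev.lower["feature_id"])
        assert set(fwd.lower["feature_id"]) == set(rev.upper["feature_id"])

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(40, 400))
            x, y = rng.normal(size=n), rng.normal(size=n)
            frac = float(rng.uniform(0.02, 0.2))
            nsel = int(round(frac * n))
            if nsel < 1:
                continue
            sel = select_tails(x, y, fraction=frac)
            order = np.argsort(y - x, kind="stable")
            assert list(sel.lower_idx) == list(order[:nsel])
            assert list(sel.upper_idx) == list(order[-nsel:])

    def test_fraction_too_small_rejected(self):
        with pytest.raises(ValueError, match="nothing to select"):
            select_tails(np.zeros(10), np.ones(10), fraction=0.04)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    st.lists(
        st.floats(-1e3, 1e3, allow_nan=False),
        min_size=60,
        max_size=120,
        unique=True,
    )
)
def test_tail_swap_antisymmetry_property(xs):
    """Swapping conditions exchanges the upper and lower tails exactly
    (distinct differences guaranteed by unique inputs against a zero
    baseline)."""
    x = np.asarray(xs)
    zero = np.zeros_like(x)
    fwd = select_tails(x, zero, fraction=0.1)
    rev = select_tails(zero, x, fraction=0.1)
    assert set(fwd.upper["feature_id"]) == set(rev.lower["feature_id"])
    assert set(fwd.lower["feature_id"]) == set(rev.upper["feature_id"])


class TestGenesInWindows:
    def _selection(self):
        # windows engineered so the upper tail is [1000,2000) on chr1
        x = np.array([0.0, 0.0, 0.0])
        y = np.array([0.0, 5.0, -5.0])
        iv = IntervalSet(
            pd.DataFrame(
                [("chr1", 0, 1000, "w0"), ("chr1", 1000, 2000, "w1"), ("chr1", 2000, 3000, "w2")],
                columns=["chrom", "start", "end", "name"],
            )
        )
        return select_tails(x, y, fraction=0.34, intervals=iv)

    def test_tss_inside_window_collected(self):
        genes = make_genes(
            [("a", "chr1", 1100, 1500, "+"), ("b", "chr1", 1700, 1900, "+"), ("c", "chr1", 100, 400, "+")]
        )
        out = genes_in_windows(self._selection(), genes)
        assert sorted(out["upper"]["genes"]) == ["a", "b"]
        assert out["upper"]["density_per_mb"] == pytest.approx(2 / 0.001)

    def test_gene_spanning_window_with_tss_outside_excluded(self):
        genes = make_genes([("span", "chr1", 500, 2500, "-")])  # TSS at 2499
        out = genes_in_windows(self._selection(), genes)
        assert out["upper"]["genes"] == []

    def test_selection_without_coordinates_rejected(self):
        sel = select_tails(np.zeros(4), np.array([1.0, 2, -1, -2]), fraction=0.25)
        with pytest.raises(ValueError, match="no window coordinates"):
            genes_in_windows(sel, make_genes([("g", "chr1", 0, 10, "+")]))


class TestClassifyQuadrants:
    def test_explicit_threshold_rules(self):
        k4 = [5.0, 1.0, 5.0, 1.0]
        k27 = [1.0, 5.0, 5.0, 1.0]
        a = classify_quadrants(k4, k27, ["a", "b", "c", "d"], thresholds=(3.0, 3.0))
        assert list(a.df["quadrant"]) == ["K4_only", "K27_only", "bivalent", "neither"]

    def test_value_at_threshold_counts_as_low(self):
        a = classify_quadrants([3.0], [3.0], ["g"], thresholds=(3.0, 3.0))
        assert a.df["quadrant"][0] == "neither"

    def test_counts_partition_gene_universe(self):
        rng = np.random.default_rng(4)
        k4 = rng.normal(size=500)
        k27 = rng.normal(size=500)
        a = classify_quadrants(k4, k27, [f"g{i}" for i in range(500)], thresholds=(0.0, 0.0))
        assert a.counts().sum() == 500

    def test_planted_four_mode_recovery(self):
        # well-separated bimodal marginals: >=95% assigned the planted quadrant
        rng = np.random.default_rng(5)
        n = 2000
        hi4 = rng.random(n) < 0.5
        hi27 = rng.random(n) < 0.5
        k4 = np.where(hi4, rng.normal(8, 0.7, n), rng.normal(1, 0.7, n))
        k27 = np.where(hi27, rng.normal(7, 0.7, n), rng.normal(0.5, 0.7, n))
        planted = np.select(
            [hi4 & hi27, hi4 & ~hi27, ~hi4 & hi27],
            ["bivalent", "K4_only", "K27_only"],
            "neither",
        )
        a = classify_quadrants(k4, k27, [f"g{i}" for i in range(n)])  # estimated thresholds
        assert (a.df["quadrant"].to_numpy() == planted).mean() >= 0.95

    def test_unimodal_marginal_requires_explicit_thresholds(self):
        rng = np.random.default_rng(6)
        v = rng.normal(0, 1, 1000)
        with pytest.raises(ValueError, match="unimodal"):
            classify_quadrants(v, v, [f"g{i}" for i in range(1000)])


class TestTrackQuadrants:
    def _assign(self, quadrants):
        n = len(quadrants)
        df = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(n)], "k4": 0.0, "k27": 0.0, "quadrant": quadrants}
        )
        from chrombarcode import QuadrantAssignment

        return QuadrantAssignment(df, (0.0, 0.0))

    def test_identical_assignments_are_fully_stable(self):
        a = self._assign(["K4_only"] * 3 + ["neither"] * 2)
        mat, stability = track_quadrants(a, a)
        assert stability == 1.0
        assert np.trace(mat.to_numpy()) == 5

    def test_one_moved_gene_reduces_trace_by_one(self):
        a = self._assign(["K4_only"] * 4)
        b = self._assign(["K4_only"] * 3 + ["bivalent"])
        mat, stability = track_quadrants(a, b)
        assert np.trace(mat.to_numpy()) == 3
        assert stability == 0.75

    def test_mismatched_gene_sets_rejected(self):
        a = self._assign(["neither"] * 3)
        b = self._assign(["neither"] * 4)
        with pytest.raises(ValueError, match="different gene sets"):
            track_quadrants(a, b)


class TestQuadrantExpression:
    def _assign(self):
        df = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c", "d"],
                "k4": 0.0,
                "k27": 0.0,
                "quadrant": ["K4_only", "K4_only", "K4_only", "K27_only"],
            }
        )
        from chrombarcode import QuadrantAssignment

        return QuadrantAssignment(df, (0.0, 0.0))

    def test_five_number_summary(self):
        expr = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 9.0})
        out = quadrant_expression_summary(self._assign(), expr).set_index("quadrant")
        row = out.loc["K4_only"]
        assert (row["min"], row["median"], row["max"]) == (1.0, 2.0, 3.0)
        assert row["n"] == 3
        assert out.loc["neither", "n"] == 0

    def test_missing_expression_dropped_and_counted(self):
        expr = pd.Series({"a": 1.0})
        out = quadrant_expression_summary(self._assign(), expr).set_index("quadrant")
        assert out.loc["K4_only", "n"] == 1
        assert out.loc["K4_only", "n_missing_expression"] == 2

    def test_all_missing_warns(self):
        expr = pd.Series(dtype=float)
        with pytest.warns(UserWarning, match="no quadrant"):
            out = quadrant_expression_summary(self._assign(), expr)
        assert (out["n"] == 0).all()

    def test_planted_expression_ordering(self):
        rng = np.random.default_rng(7)
        n = 300
        quads = np.array(QUADRANTS)[rng.integers(0, 4, n)]
        df = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(n)], "k4": 0.0, "k27": 0.0, "quadrant": quads}
        )
        from chrombarcode import QuadrantAssignment

        a = QuadrantAssignment(df, (0.0, 0.0))
        base = {"K4_only": 10.0, "bivalent": 5.0, "neither": 5.0, "K27_only": 1.0}
        expr = pd.Series(
            {f"g{i}": rng.lognormal(np.log(base[quads[i]]), 0.3) for i in range(n)}
        )
        out = quadrant_expression_summary(a, expr).set_index("quadrant")
        assert out.loc["K4_only", "median"] > out.loc["K27_only", "median"]
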