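"""Rank-abundance curves, log-model fitting, breakpoint threshold
detection and rare/abundant/undetected calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from rarebio.config import RunConfig
from rarebio.containers import CoverageMatrix
from rarebio.rarity import (
    MIN_SEGMENT,
    RarityClassifier,
    detect_threshold,
    fit_sad,
    rank_abundance_curve,
)


def make_curve(abundances):
    return rank_abundance_curve(pd.Series(abundances))


def two_segment_curve(n, knee_rank, slope1, slope2, intercept=-3.0, noise=0.0, seed=0):
    """ln(abund) piecewise-linear in ln(rank), continuous at the knee."""
    rng = np.random.default_rng(seed)
    x = np.log(np.arange(1, n + 1))
    xk = np.log(knee_rank)
    y = intercept + slope1 * x + (slope2 - slope1) * np.maximum(0.0, x - xk)
    y = y + rng.normal(0, noise, n)
    return pd.DataFrame(
        {"rank": np.arange(1, n + 1), "mag_id": [f"m{i}" for i in range(n)],
         "rel_abund": np.exp(y)}
    )


class TestRankAbundanceCurve:
    def test_sorts_descending_and_drops_zeros(self):
        curve = make_curve({"A": 0.03, "B": 0.01, "C": 0.0})
        assert curve["mag_id"].tolist() == ["A", "B"]
        assert curve["rank"].tolist() == [1, 2]

    def test_ties_broken_by_mag_id(self):
        curve = make_curve({"B": 0.02, "A": 0.02})
        assert curve["mag_id"].tolist() == ["A", "B"]

    def test_input_order_invariance(self):
        a = make_curve({"A": 0.02, "B": 0.05, "C": 0.01})
        b = make_curve({"C": 0.01, "A": 0.02, "B": 0.05})
        pd.testing.assert_frame_equal(a, b)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="no detected populations"):
            make_curve({"A": 0.0})


class TestFitSad:
    def test_exact_recovery_of_planted_line(self):
        ranks = np.arange(1, 21)
        abund = np.exp(-1.0 - 0.8 * np.log(ranks))
        fit = fit_sad(
            pd.DataFrame({"rank": ranks, "mag_id": ranks.astype(str), "rel_abund": abund})
        )
        assert fit.slope == pytest.approx(-0.8)
        assert fit.intercept == pytest.approx(-1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_independent_ols(self, default_dataset):
        import statsmodels.api as sm

        matrix = default_dataset["matrix"]
        sid = matrix.sample_ids[0]
        curve = rank_abundance_curve(matrix.rel_abund[sid])
        fit = fit_sad(curve)
        X = sm.add_constant(np.log(curve["rank"].to_numpy(float)))
        res = sm.OLS(np.log(curve["rel_abund"].to_numpy(float)), X).fit()
        assert fit.intercept == pytest.approx(res.params[0])
        assert fit.slope == pytest.approx(res.params[1])
        assert fit.r_squared == pytest.approx(res.rsquared)

    def test_semilog_model(self):
        ranks = np.arange(1, 11)
        abund = 0.05 - 0.01 * np.log(ranks)
        fit = fit_sad(
            pd.DataFrame({"rank": ranks, "mag_id": ranks.astype(str), "rel_abund": abund}),
            model="semilog",
        )
        assert fit.slope == pytest.approx(-0.01)
        assert fit.r_squared == pytest.approx(1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_sad(make_curve({"A": 0.02, "B": 0.01}))

    def test_constant_curve_rejected(self):
        curve = pd.DataFrame(
            {"rank": [1, 2, 3], "mag_id": list("abc"), "rel_abund": [0.01] * 3}
        )
        with pytest.raises(ValueError, match="zero variance"):
            fit_sad(curve)


class TestDetectThreshold:
    def test_pure_line_uses_default(self):
        curve = two_segment_curve(50, knee_rank=10, slope1=-0.8, slope2=-0.8)
        threshold, fit = detect_threshold(curve)
        assert fit.used_default
        assert threshold == pytest.approx(0.001)

    def test_planted_knee_recovered(self):
        curve = two_segment_curve(120, knee_rank=40, slope1=-0.5, slope2=-3.0)
        threshold, fit = detect_threshold(curve)
        assert not fit.used_default
        assert abs(fit.breakpoint_rank - 40) <= 1

    def test_knee_abundance_clamped_to_field_range(self):
        # knee planted at abundance exp(-3-0.5*ln 40) ~ 0.0078: above 0.2%
        curve = two_segment_curve(120, knee_rank=40, slope1=-0.5, slope2=-3.0)
        threshold, fit = detect_threshold(curve)
        assert fit.breakpoint_abund > 0.002
        assert threshold == pytest.approx(0.002)

    def test_breakpoint_abund_is_fitted_value_at_knee(self):
        curve = two_segment_curve(80, knee_rank=30, slope1=-0.4, slope2=-2.5, noise=0.05)
        _, fit = detect_threshold(curve)
        assert fit.breakpoint_rank is not None
        # noise-free replant at the detected knee: fitted value stays close
        assert fit.breakpoint_abund == pytest.approx(
            np.exp(-3.0 - 0.4 * np.log(fit.breakpoint_rank)), rel=0.1
        )

    def test_short_curve_falls_back_without_error(self):
        curve = make_curve({c: 0.01 / (i + 1) for i, c in enumerate("abcdefg")})
        threshold, fit = detect_threshold(curve)
        assert fit.used_default
        assert threshold == pytest.approx(0.001)

    def test_matches_brute_force_enumeration(self):
        """The chosen knee attains the global SSE minimum (independent OLS)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        for trial in range(10):
            n = int(rng.integers(20, 120))
            curve = two_segment_curve(
                n,
                knee_rank=int(rng.integers(6, n - 6)),
                slope1=-0.5,
                slope2=-3.0,
                noise=0.3,
                seed=trial,
            )
            _, fit = detect_threshold(curve)
            x = np.log(curve["rank"].to_numpy(float))
            y = np.log(curve["rel_abund"].to_numpy(float))
            best_sse = np.inf
            for k in range(MIN_SEGMENT - 1, n - MIN_SEGMENT):
                X = sm.add_constant(
                    np.column_stack([x, np.maximum(0, x - x[k])])
                )
                best_sse = min(best_sse, float(sm.OLS(y, X).fit().ssr))
            if fit.breakpoint_rank is not None:
                k = fit.breakpoint_rank - 1
                X = sm.add_constant(np.column_stack([x, np.maximum(0, x - x[k])]))
                assert float(sm.OLS(y, X).fit().ssr) == pytest.approx(best_sse, abs=1e-9)


class TestClassification:
    @pytest.mark.parametrize(
        "rel_abund, brd, expected",
        [
            (0.0015, 0.95, "abundant"),
            (0.0005, 0.60, "rare"),
            (0.0015, 0.80, "rare"),  # abundance alone is not enough
            (0.0005, 0.95, "rare"),  # breadth alone is not enough
            (0.0005, 0.05, "undetected"),
        ],
    )
    def test_label_rule(self, rel_abund, brd, expected):
        depth = pd.DataFrame({"s1": [rel_abund * 1000, 5.0]}, index=["m1", "m2"])
        breadth = pd.DataFrame({"s1": [brd, 0.99]}, index=["m1", "m2"])
        rel = pd.DataFrame({"s1": [rel_abund, 0.005]}, index=["m1", "m2"])
        matrix = CoverageMatrix(depth, breadth, rel)
        clf = RarityClassifier()
        clf.thresholds_ = pd.Series({"s1": 0.001})
        clf.sad_fits_ = {"s1": None}
        calls = clf.predict(matrix)
        assert calls.set_index("mag_id")["label"]["m1"] == expected

    def test_labels_partition_all_cells(self, default_dataset):
        calls = default_dataset["calls"]
        matrix = default_dataset["matrix"]
        counts = calls["label"].value_counts()
        assert counts.sum() == matrix.shape[0] * matrix.shape[1]
        assert set(counts.index) <= {"abundant", "rare", "undetected"}

    def test_abundant_calls_satisfy_both_cutoffs(self, default_dataset):
        calls = default_dataset["calls"]
        abundant = calls[calls["label"] == "abundant"]
        assert (abundant["rel_abund"] >= abundant["threshold_used"]).all()
        assert (abundant["breadth"] >= 0.90).all()
        undetected = calls[calls["label"] == "undetected"]
        assert (undetected["breadth"] < 0.10).all()

    def test_raising_threshold_never_adds_abundant_calls(self, default_dataset):
        matrix = default_dataset["matrix"]
        clf = default_dataset["clf"]
        base = (clf.predict(matrix)["label"] == "abundant").sum()
        higher = RarityClassifier()
        higher.thresholds_ = clf.thresholds_ * 2
        higher.sad_fits_ = clf.sad_fits_
        assert (higher.predict(matrix)["label"] == "abundant").sum() <= base

    def test_estimator_is_cloneable(self):
        clf = RarityClassifier(default_threshold=0.002, threshold_clamp=(0.001, 0.003))
        clone_ = clone(clf)
        assert clone_.get_params() == clf.get_params()
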