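"""Bin assignment, per-bin QTc-vs-HR regression and the slope trend."""

import math

import numpy as np
import pandas as pd
import pytest

import qtctbt as q
from qtctbt.evaluation import BinSlopeResult, bin_regression


def _frame(hr, qtc, t=0.5, subject=None):
    n = len(hr)
    return pd.DataFrame(
        {
            "subject_id": subject if subject is not None else [f"S{i}" for i in range(n)],
            "study": "C208",
            "arm": "active",
            "t_weeks": t,
            "ctime_h": 12.0,
            "occasion_id": [f"o{i}" for i in range(n)],
            "replicate": 1,
            "hr_bpm": hr,
            "qt_ms": 400.0,
            "conc_m2": 0.0,
            "assessment": "predose",
            "qtc": qtc,
        }
    )


class TestAssignBins:
    @pytest.mark.parametrize(
        "t,expected",
        [
            (-1 / 7, "pretreatment"),
            (0.0, "wk0-1"),
            (1.0, "wk0-1"),
            (1.5, None),
            (2.0, "wk2-3"),
            (3.0, "wk2-3"),
            (3.5, "wk3-4"),
            (4.5, None),
            (8.0, "wk5-8"),
            (12.0, "wk9-12"),
            (20.0, "wk13-20"),
            (24.0, "wk20-24"),
        ],
    )
    def test_boundary_rules(self, t, expected):
        scheme = q.TimeBinScheme.default()
        assert scheme.assign([t])[0] == expected

    def test_pretreatment_midpoint_is_zero(self):
        scheme = q.TimeBinScheme.default()
        assert scheme.midpoint("pretreatment") == 0.0
        assert scheme.midpoint("wk13-20") == 16.5

    def test_overlapping_bins_rejected(self):
        from qtctbt.evaluation import TimeBin

        with pytest.raises(ValueError):
            q.TimeBinScheme(bins=(TimeBin("a", 0, 5), TimeBin("b", 3, 8)))


class TestBinRegression:
    def test_constant_qtc_gives_zero_slope(self):
        df = _frame(hr=np.linspace(60, 100, 20), qtc=np.full(20, 410.0))
        (res,) = bin_regression(df)
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.r2 == 0.0

    def test_exact_line_recovered(self):
        hr = np.linspace(60, 100, 15)
        df = _frame(hr=hr, qtc=500.0 - 0.5 * hr)
        (res,) = bin_regression(df)
        assert res.slope == pytest.approx(-0.5, abs=1e-12)
        assert res.intercept == pytest.approx(500.0, abs=1e-9)
        assert res.r2 == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        hr = rng.uniform(60, 110, 40)
        qtc = 400.0 - 0.3 * hr + rng.normal(0, 5, 40)
        df = _frame(hr=hr, qtc=qtc)
        (res,) = bin_regression(df, se="ols")
        # Hand-rolled normal equations and classical slope SE.
        X = np.column_stack([np.ones_like(hr), hr])
        beta = np.linalg.solve(X.T @ X, X.T @ qtc)
        resid = qtc - X @ beta
        s2 = resid @ resid / (len(hr) - 2)
        se = math.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        assert res.slope == pytest.approx(beta[1], abs=1e-10)
        assert res.intercept == pytest.approx(beta[0], abs=1e-10)
        assert res.slope_se == pytest.approx(se, abs=1e-10)

    def test_undercorrection_detected_at_elevated_hr(self):
        # QT generated with exponent 0.4081 but corrected with 0.33 at t=0:
        # QTc falls with HR, so the slope is negative with CI excluding 0.
        rng = np.random.default_rng(2)
        n = 500
        hr = rng.normal(78, 10, n).clip(50, 120)
        qt = 400.0 * (60.0 / hr) ** 0.4081 * np.exp(rng.normal(0, 0.02, n))
        qtc = q.correct_qt(qt, hr, 0.0, "fridericia")
        df = _frame(hr=hr, qtc=np.asarray(qtc))
        (res,) = bin_regression(df)
        assert res.ci_high < 0.0

    def test_small_bins_skipped(self):
        df = _frame(hr=np.array([70.0, 80.0]), qtc=np.array([400.0, 401.0]))
        assert bin_regression(df) == []


class TestSlopeTrend:
    def _results(self, slopes, ses, mids=None):
        mids = mids if mids is not None else np.linspace(0, 22, len(slopes))
        return [
            BinSlopeResult(f"b{i}", 100, s, 400.0, se, s - 2 * se, s + 2 * se, 0.0, m)
            for i, (s, se, m) in enumerate(zip(slopes, ses, mids))
        ]

    def test_identical_slopes_give_flat_trend(self):
        res = self._results([0.2] * 5, [0.05] * 5)
        trend = q.slope_trend(res)
        assert trend.intercept == pytest.approx(0.2, abs=1e-12)
        assert trend.trend == pytest.approx(0.0, abs=1e-12)

    def test_equal_weights_match_unweighted_ols(self):
        slopes = [0.30, 0.25, 0.18, 0.12, 0.02, -0.01]
        res = self._results(slopes, [0.04] * 6)
        trend = q.slope_trend(res)
        t = np.array([b.midpoint_weeks for b in res])
        b1, b0 = np.polyfit(t, slopes, 1)
        assert trend.intercept == pytest.approx(b0, abs=1e-10)
        assert trend.trend == pytest.approx(b1, abs=1e-10)

    def test_invariant_to_weight_rescaling(self):
        slopes = [0.3, 0.2, 0.1, 0.05, -0.02]
        ses = [0.02, 0.05, 0.03, 0.08, 0.04]
        a = q.slope_trend(self._results(slopes, ses))
        b = q.slope_trend(self._results(slopes, [10 * s for s in ses]))
        assert a.intercept == pytest.approx(b.intercept, rel=1e-10)
        assert a.trend == pytest.approx(b.trend, rel=1e-10)

    def test_needs_three_bins(self):
        with pytest.raises(ValueError):
            q.slope_trend(self._results([0.1, 0.2], [0.05, 0.05]))


class TestEvaluateCorrections:
    def test_matched_cf_keeps_tbt_flat(self, matched_cf_dataset):
        df, _ = matched_cf_dataset
        report = q.evaluate_corrections(df, methods=("fridericia", "tbt"))
        tbt = report.trends["tbt"]
        assert tbt.trend_covers_zero
        assert report.bins_covering_zero["tbt"] >= 6
        frid = report.trends["fridericia"]
        assert frid.intercept < 0  # initial undercorrection

    def test_single_bin_single_method_report(self):
        rng = np.random.default_rng(3)
        hr = rng.uniform(60, 100, 30)
        qt = 400.0 * (60.0 / hr) ** 0.4081
        df = _frame(hr=hr, qtc=np.zeros(30))
        df["qt_ms"] = qt
        df = df.drop(columns="qtc")
        report = q.evaluate_corrections(df, methods=("fridericia",))
        assert len(report.per_bin) == 1
        assert report.trends["fridericia"] is None
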