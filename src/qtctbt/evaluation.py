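"""Two-step evaluation of QT correction quality.

Step 1: within each prespecified treatment-time bin, ordinary least squares
of QTc (ms) on HR (bpm).  A successful correction makes QTc independent of
HR, so the bin slope and r^2 should be close to 0.  Because triplicate
replicates from one subject share that subject's QTc level, the default
slope standard errors are clustered by subject (classical OLS SEs are
available via ``se="ols"``).

Step 2: weighted least squares of the bin slopes against bin midpoint time
(weights 1/SE^2).  The WLS intercept is the QTc-vs-HR slope at treatment
start and the WLS slope is the drift in correction quality over time; both
should be close to 0 for a successful correction.

The default eight bins are: pretreatment (t < 0), Week 0-1, 2-3, 3-4, 5-8,
9-12, 13-20 and 20-24, with the shared boundaries 3 and 20 belonging to the
earlier bin and the gaps between bins (e.g. week 1.5) left unassigned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .correction import CorrectionSpec, correct_qt, method_spec
from .data import as_frame

logger = logging.getLogger("qtctbt")


@dataclass(frozen=True)
class TimeBin:
    label: str
    start: float
    end: float
    closed_left: bool = True
    closed_right: bool = True

    def contains(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        left = t >= self.start if self.closed_left else t > self.start
        right = t <= self.end if self.closed_right else t < self.end
        return left & right

    @property
    def midpoint(self) -> float:
        # Pretreatment maps to 0: the trend intercept is the slope at
        # treatment start.
        if self.start == -math.inf:
            return 0.0
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class TimeBinScheme:
    """Ordered, non-overlapping treatment-time bins."""

    bins: tuple[TimeBin, ...]

    def __post_init__(self):
        prev_end = -math.inf
        for b in self.bins:
            if b.start < prev_end:
                raise ValueError("bins must be ordered and non-overlapping")
            prev_end = b.end

    @classmethod
    def default(cls) -> "TimeBinScheme":
        return cls(
            bins=(
                TimeBin("pretreatment", -math.inf, 0.0, False, False),
                TimeBin("wk0-1", 0.0, 1.0, True, True),
                TimeBin("wk2-3", 2.0, 3.0, True, True),
                TimeBin("wk3-4", 3.0, 4.0, False, True),
                TimeBin("wk5-8", 5.0, 8.0, True, True),
                TimeBin("wk9-12", 9.0, 12.0, True, True),
                TimeBin("wk13-20", 13.0, 20.0, True, True),
                TimeBin("wk20-24", 20.0, 24.0, False, True),
            )
        )

    def assign(self, t) -> np.ndarray:
        """Bin label per time, or None for times in gaps."""
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, None, dtype=object)
        for b in self.bins:
            sel = b.contains(t) & (out == None)  # noqa: E711
            out[sel] = b.label
        return out

    def midpoint(self, label: str) -> float:
        for b in self.bins:
            if b.label == label:
                return b.midpoint
        raise KeyError(label)


@dataclass
class BinSlopeResult:
    """QTc-vs-HR regression summary for one time bin."""

    label: str
    n: int
    slope: float  # ms per bpm
    intercept: float  # ms
    slope_se: float
    ci_low: float
    ci_high: float
    r2: float
    midpoint_weeks: float
    #: per-subject influence on the slope estimate (sums to ~0); carries the
    #: between-bin dependence into the slope-trend covariance.
    subject_influence: dict | None = None

    @property
    def covers_zero(self) -> bool:
        return self.ci_low <= 0.0 <= self.ci_high


@dataclass
class SlopeTrendResult:
    """Weighted regression of bin slopes over time."""

    intercept: float  # QTc/HR slope at treatment start
    intercept_ci: tuple[float, float]
    trend: float  # change in slope per week
    trend_ci: tuple[float, float]

    @property
    def intercept_covers_zero(self) -> bool:
        return self.intercept_ci[0] <= 0.0 <= self.intercept_ci[1]

    @property
    def trend_covers_zero(self) -> bool:
        return self.trend_ci[0] <= 0.0 <= self.trend_ci[1]


def assign_bins(data, scheme: TimeBinScheme | None = None) -> pd.DataFrame:
    """Annotate the ECG table with a ``bin`` column (None in gaps)."""
    scheme = scheme or TimeBinScheme.default()
    df = as_frame(data).copy()
    df["bin"] = scheme.assign(df["t_weeks"].to_numpy())
    n_gap = int(df["bin"].isna().sum())
    if n_gap:
        logger.info("assign_bins: %d record(s) fall outside the bin scheme", n_gap)
    return df


def bin_regression(
    data,
    qtc_col: str = "qtc",
    scheme: TimeBinScheme | None = None,
    min_n: int = 3,
    se: str = "cluster",
    center_hr: bool = False,
) -> list[BinSlopeResult]:
    """Per-bin OLS of QTc on HR with t-based 95% CIs.

    ``se="cluster"`` (default) clusters by subject to respect the
    triplicate structure; ``se="ols"`` gives classical standard errors.
    Bins with fewer than ``min_n`` records or no HR variance are skipped
    with a warning.
    """
    scheme = scheme or TimeBinScheme.default()
    df = data if "bin" in getattr(data, "columns", ()) else assign_bins(data, scheme)
    results = []
    for b in scheme.bins:
        sub = df[df["bin"] == b.label]
        if len(sub) < min_n:
            logger.warning("bin %s: only %d record(s); skipped", b.label, len(sub))
            continue
        hr = sub["hr_bpm"].to_numpy(dtype=float)
        if np.ptp(hr) == 0:
            logger.warning("bin %s: zero HR variance; skipped", b.label)
            continue
        if center_hr:
            hr = hr - hr.mean()
        X = sm.add_constant(hr)
        y = sub[qtc_col].to_numpy(dtype=float)
        groups = sub["subject_id"].to_numpy()
        if se == "cluster" and len(np.unique(groups)) > 1:
            res = sm.OLS(y, X).fit(
                cov_type="cluster", cov_kwds={"groups": groups}, use_t=True
            )
        else:
            res = sm.OLS(y, X).fit(use_t=True)
        ci = res.conf_int(alpha=0.05)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = float(res.rsquared)
        if not np.isfinite(r2):  # constant QTc: no variance to explain
            r2 = 0.0
        # Per-subject influence on the slope: g_s = sum_{i in s} a_i * u_i
        # with a the slope row of (X'X)^-1 X' and u the OLS residuals.
        a = np.linalg.solve(X.T @ X, X.T)[1]
        u = y - X @ res.params
        gu = pd.Series(a * u).groupby(pd.Series(groups)).sum()
        influence = {str(k): float(v) for k, v in gu.items()}
        results.append(
            BinSlopeResult(
                label=b.label,
                n=len(sub),
                slope=float(res.params[1]),
                intercept=float(res.params[0]),
                slope_se=float(res.bse[1]),
                ci_low=float(ci[1][0]),
                ci_high=float(ci[1][1]),
                r2=r2,
                midpoint_weeks=b.midpoint,
                subject_influence=influence,
            )
        )
    return results


def _slope_covariance(bin_results: list[BinSlopeResult]) -> np.ndarray | None:
    """Between-bin covariance of the slope estimates from subject influences.

    The same subjects contribute to every bin of a longitudinal design, so
    slope errors are correlated across bins; the cluster (subject-level)
    outer-product estimator S_bc = sum_s g_bs g_cs captures that.
    """
    if any(b.subject_influence is None for b in bin_results):
        return None
    subjects = sorted({s for b in bin_results for s in b.subject_influence})
    G = np.zeros((len(bin_results), len(subjects)))
    idx = {s: j for j, s in enumerate(subjects)}
    for i, b in enumerate(bin_results):
        for s, g in b.subject_influence.items():
            G[i, idx[s]] = g
    n = len(subjects)
    return (G @ G.T) * n / max(n - 1, 1)


def slope_trend(
    bin_results: list[BinSlopeResult],
    weighting: str = "inverse_variance",
    ci: str = "cluster",
) -> SlopeTrendResult:
    """SE-weighted regression of the bin slopes against bin midpoint time.

    Point estimates are weighted least squares with weights 1/SE^2
    (``weighting="inverse_se"`` uses 1/SE).  Confidence intervals default
    to a subject-level sandwich that propagates the between-bin dependence
    induced by the longitudinal design (``ci="wls"`` gives the plain WLS
    intervals, which ignore that dependence).  Requires >= 3 usable bins.
    """
    if len(bin_results) < 3:
        raise ValueError("slope_trend needs >= 3 bin slopes")
    t = np.array([b.midpoint_weeks for b in bin_results])
    s = np.array([b.slope for b in bin_results])
    se = np.array([b.slope_se for b in bin_results])
    if weighting == "inverse_variance":
        w = 1.0 / se**2
    elif weighting == "inverse_se":
        w = 1.0 / se
    else:
        raise ValueError("weighting must be 'inverse_variance' or 'inverse_se'")
    X = sm.add_constant(t)
    res = sm.WLS(s, X, weights=w).fit(use_t=True)
    S = _slope_covariance(bin_results) if ci == "cluster" else None
    if S is not None:
        # beta = A s with A = (X'WX)^-1 X'W  =>  Var(beta) = A S A'.
        A = np.linalg.solve(X.T @ (w[:, None] * X), (w[:, None] * X).T)
        V = A @ S @ A.T
        tq = stats.t.ppf(0.975, len(bin_results) - 2)
        half = tq * np.sqrt(np.diag(V))
        lo, hi = res.params - half, res.params + half
        bounds = np.column_stack([lo, hi])
    else:
        bounds = res.conf_int(alpha=0.05)
    return SlopeTrendResult(
        intercept=float(res.params[0]),
        intercept_ci=(float(bounds[0][0]), float(bounds[0][1])),
        trend=float(res.params[1]),
        trend_ci=(float(bounds[1][0]), float(bounds[1][1])),
    )


@dataclass
class CorrectionReport:
    """Comparative evaluation of several correction methods."""

    per_bin: pd.DataFrame  # one row per method x bin
    trends: dict  # method -> SlopeTrendResult
    bins_covering_zero: dict = field(default_factory=dict)  # method -> int


def add_qtc_columns(data, methods) -> tuple[pd.DataFrame, dict]:
    """Append one QTc column per requested method; returns (df, name->spec)."""
    df = as_frame(data).copy()
    specs = {}
    for m in methods:
        spec = m if isinstance(m, CorrectionSpec) else method_spec(m)
        col = f"qtc_{spec.method}"
        df[col] = correct_qt(
            df["qt_ms"].to_numpy(), df["hr_bpm"].to_numpy(), df["t_weeks"].to_numpy(), spec
        )
        specs[col] = spec
    return df, specs


def evaluate_corrections(
    data,
    methods=("bazett", "fridericia", "olliaro", "tbt"),
    scheme: TimeBinScheme | None = None,
    se: str = "cluster",
) -> CorrectionReport:
    """Per-method per-bin slopes plus the slope-over-time trend regression."""
    scheme = scheme or TimeBinScheme.default()
    df, specs = add_qtc_columns(data, methods)
    df = assign_bins(df, scheme)
    rows, trends, cover = [], {}, {}
    for col, spec in specs.items():
        res = bin_regression(df, qtc_col=col, scheme=scheme, se=se)
        for b in res:
            rows.append(
                {
                    "method": spec.method,
                    "bin": b.label,
                    "n": b.n,
                    "slope": b.slope,
                    "slope_se": b.slope_se,
                    "ci_low": b.ci_low,
                    "ci_high": b.ci_high,
                    "r2": b.r2,
                    "midpoint_weeks": b.midpoint_weeks,
                }
            )
        if len(res) >= 3:
            trends[spec.method] = slope_trend(res)
        else:
            logger.warning(
                "method %s: %d usable bin(s), slope trend not computed",
                spec.method, len(res),
            )
            trends[spec.method] = None
        cover[spec.method] = sum(b.covers_zero for b in res)
    return CorrectionReport(
        per_bin=pd.DataFrame(rows), trends=trends, bins_covering_zero=cover
    )


def plot_qtc_vs_hr(data, methods, scheme=None, path=None):
    """Panel grid of QTc vs HR per bin per method (one row per method).

    Requires matplotlib; returns the figure.  The dashed line marks the QTc
    level at HR = 60 bpm (mean QTc at RR = 1 s).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scheme = scheme or TimeBinScheme.default()
    df, specs = add_qtc_columns(data, methods)
    df = assign_bins(df, scheme)
    labels = [b.label for b in scheme.bins]
    fig, axes = plt.subplots(
        len(specs), len(labels), figsize=(2.2 * len(labels), 2.2 * len(specs)),
        sharex=True, sharey=True, squeeze=False,
    )
    for i, (col, spec) in enumerate(specs.items()):
        for j, lab in enumerate(labels):
            ax = axes[i][j]
            sub = df[df["bin"] == lab]
            if len(sub):
                ax.plot(sub["hr_bpm"], sub[col], ".", ms=2, alpha=0.4)
                b, a = np.polyfit(sub["hr_bpm"], sub[col], 1)
                xs = np.linspace(sub["hr_bpm"].min(), sub["hr_bpm"].max(), 20)
                ax.plot(xs, a + b * xs, "-", lw=1)
                ax.axhline(sub[col].mean(), ls="--", lw=0.8, color="r")
            if i == 0:
                ax.set_title(lab, fontsize=8)
            if j == 0:
                ax.set_ylabel(spec.label, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
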