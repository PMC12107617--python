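"""Standard QTc-prolongation endpoints: absolute QTc, change from baseline
(dQTc) and placebo-corrected change from baseline (ddQTc), summarised over
the prespecified treatment-time bins.

Baseline QTc is the mean of a subject's Day -1 triplicate, corrected with
the same method as the endpoint (for the time-varying method the
pretreatment correction exponent applies).  Summaries aggregate to one
value per subject per bin before computing t-based 95% confidence
intervals, so triplicates do not pseudo-replicate.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .correction import CorrectionSpec, correct_qt, method_spec
from .data import as_frame
from .evaluation import TimeBinScheme, assign_bins

logger = logging.getLogger("qtctbt")


def _spec(method) -> CorrectionSpec:
    return method if isinstance(method, CorrectionSpec) else method_spec(method)


def _with_qtc(df: pd.DataFrame, spec: CorrectionSpec) -> pd.DataFrame:
    df = df.copy()
    df["qtc"] = correct_qt(
        df["qt_ms"].to_numpy(), df["hr_bpm"].to_numpy(), df["t_weeks"].to_numpy(), spec
    )
    return df


def baseline_qtc(data, method="tbt", assessment: str = "predose") -> pd.Series:
    """Per-subject baseline QTc: mean of the Day -1 triplicate.

    ``assessment`` selects which Day -1 records form the baseline ("5h" for
    the 5-hour post-dose assessments, "predose" otherwise).  Subjects
    without Day -1 records are absent from the result (and logged).
    """
    spec = _spec(method)
    df = _with_qtc(as_frame(data), spec)
    pre = df[df["t_weeks"] < 0]
    if assessment in set(pre["assessment"]):
        pre = pre[pre["assessment"] == assessment]
    base = pre.groupby("subject_id")["qtc"].mean()
    missing = set(df["subject_id"]) - set(base.index)
    for sid in sorted(missing):
        logger.info("subject %s: no Day -1 record; excluded from delta endpoints", sid)
    return base


def delta_qtc(data, method="tbt", assessment: str = "predose") -> pd.DataFrame:
    """Per-record change from baseline, ``dqtc = qtc - baseline_subject``.

    Subjects without a baseline are dropped.  Returns the table with
    ``qtc`` and ``dqtc`` columns added.
    """
    spec = _spec(method)
    df = _with_qtc(as_frame(data), spec)
    base = baseline_qtc(df, spec, assessment=assessment)
    df = df[df["subject_id"].isin(base.index)].copy()
    df["dqtc"] = df["qtc"] - df["subject_id"].map(base)
    return df


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """(mean, lo, hi) t-based CI of the mean; degenerate for n < 2."""
    n = len(values)
    m = float(np.mean(values))
    if n < 2:
        return m, math.nan, math.nan
    sem = float(np.std(values, ddof=1) / math.sqrt(n))
    tq = stats.t.ppf(0.5 + level / 2.0, n - 1)
    return m, m - tq * sem, m + tq * sem


def _subject_bin_means(df: pd.DataFrame, value_col: str) -> pd.DataFrame:
    return (
        df.dropna(subset=["bin"])
        .groupby(["bin", "subject_id", "arm"], sort=False, observed=True)[value_col]
        .mean()
        .reset_index()
    )


def delta_delta_qtc(data, method="tbt", scheme: TimeBinScheme | None = None) -> pd.DataFrame:
    """Placebo-corrected change from baseline per bin.

    Per bin: mean dQTc(active) - mean dQTc(placebo), with a Welch
    two-sample t CI on subject-level means.  Bins missing an arm are
    omitted with a warning; an input with a single arm is an error.
    """
    scheme = scheme or TimeBinScheme.default()
    df = assign_bins(delta_qtc(data, method), scheme)
    arms = set(df["arm"])
    if not {"active", "placebo"} <= arms:
        raise ValueError(f"delta_delta_qtc needs both arms; got {sorted(arms)}")
    per_subj = _subject_bin_means(df[df["t_weeks"] >= 0], "dqtc")
    rows = []
    for b in scheme.bins:
        sub = per_subj[per_subj["bin"] == b.label]
        a = sub.loc[sub["arm"] == "active", "dqtc"].to_numpy()
        p = sub.loc[sub["arm"] == "placebo", "dqtc"].to_numpy()
        if len(sub) == 0:
            continue
        if len(a) < 2 or len(p) < 2:
            logger.warning("bin %s: an arm is missing/degenerate; omitted", b.label)
            continue
        diff = float(a.mean() - p.mean())
        v = a.var(ddof=1) / len(a) + p.var(ddof=1) / len(p)
        if v > 0:
            dof = v**2 / (
                (a.var(ddof=1) / len(a)) ** 2 / (len(a) - 1)
                + (p.var(ddof=1) / len(p)) ** 2 / (len(p) - 1)
            )
        else:  # degenerate (zero-variance) arms: CI collapses to the point
            dof = len(a) + len(p) - 2
        tq = stats.t.ppf(0.975, dof)
        rows.append(
            {
                "bin": b.label,
                "n_active": len(a),
                "n_placebo": len(p),
                "mean": diff,
                "ci_low": diff - tq * math.sqrt(v),
                "ci_high": diff + tq * math.sqrt(v),
            }
        )
    return pd.DataFrame(rows)


def summarize(
    data,
    methods=("fridericia", "tbt"),
    scheme: TimeBinScheme | None = None,
    arm: str | None = None,
) -> pd.DataFrame:
    """Endpoint summary table: mean and t-based 95% CI per endpoint kind,
    method and bin (subject-level aggregation).

    Endpoint kinds: ``absolute`` (QTc), ``delta`` (dQTc; on-treatment bins)
    and, when both arms are present, ``delta_delta``.
    """
    scheme = scheme or TimeBinScheme.default()
    df_all = as_frame(data)
    if arm is not None:
        df_all = df_all[df_all["arm"] == arm]
    rows = []
    for m in methods:
        spec = _spec(m)
        dfa = assign_bins(_with_qtc(df_all, spec), scheme)
        for b in scheme.bins:
            vals = _subject_bin_means(dfa[dfa["bin"] == b.label], "qtc")["qtc"]
            if len(vals):
                mean, lo, hi = _t_ci(vals.to_numpy())
                rows.append(
                    dict(method=spec.method, kind="absolute", bin=b.label,
                         n=len(vals), mean=mean, ci_low=lo, ci_high=hi)
                )
        dfd = assign_bins(delta_qtc(df_all, spec), scheme)
        for b in scheme.bins:
            if b.end <= 0:
                continue
            vals = _subject_bin_means(dfd[dfd["bin"] == b.label], "dqtc")["dqtc"]
            if len(vals):
                mean, lo, hi = _t_ci(vals.to_numpy())
                rows.append(
                    dict(method=spec.method, kind="delta", bin=b.label,
                         n=len(vals), mean=mean, ci_low=lo, ci_high=hi)
                )
        if {"active", "placebo"} <= set(df_all["arm"]):
            dd = delta_delta_qtc(df_all, spec, scheme)
            for _, r in dd.iterrows():
                rows.append(
                    dict(method=spec.method, kind="delta_delta", bin=r["bin"],
                         n=int(r["n_active"] + r["n_placebo"]), mean=r["mean"],
                         ci_low=r["ci_low"], ci_high=r["ci_high"])
                )
    return pd.DataFrame(rows)
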