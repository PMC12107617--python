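"""Marginal maximum-likelihood estimation for the heart-rate model.

The subject-level marginal likelihood integrates the conditional data
density over the random effects.  The integral is approximated by a
Laplace expansion at the per-subject posterior mode (found by a damped
Newton search with finite-difference derivatives):

    log L_j ~= log p(y_j | eta_hat) + log p(eta_hat)
               + k/2 log(2 pi) - 1/2 log|H|,

with H the negative Hessian of the joint log density at the mode.  The
objective function value is OFV = -2 sum_j log L_j.  When no random effect
is active the marginal likelihood is the closed-form product of Gaussian
densities (no integration).

The conditional density accounts for the two-level residual model: the
additive component is shared within a triplicate occasion, giving a
compound-symmetric covariance per occasion,
``Sigma = diag((pred * sigma_prop_i)^2) + sigma_add_i^2 * J``, evaluated
with the Sherman-Morrison identity.

Fixed effects are optimised on transformed scales (log for positive
parameters, logit for Emax) by quasi-Newton search; standard errors come
from the inverse finite-difference Hessian of OFV/2 at the optimum.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .data import EcgRecord, SubjectProfile, as_frame
from .hrmodel import (
    EFFECTS,
    LN2,
    HRModelSpec,
    boxcox_eta,
    subject_covariate_factors,
)

logger = logging.getLogger("qtctbt")

_LOG2PI = math.log(2.0 * math.pi)

# ---------------------------------------------------------------------------
# finite differences

def fd_gradient(f, x, rel_step=1e-5):
    """Central-difference gradient."""
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    for i in range(x.size):
        h = rel_step * (1.0 + abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (f(xp) - f(xm)) / (2.0 * h)
    return g


def fd_hessian(f, x, rel_step=1e-4):
    """Central-difference Hessian (symmetric)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    h = np.array([rel_step * (1.0 + abs(xi)) for xi in x])
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        xp, xm = x.copy(), x.copy()
        xp[i] += h[i]
        xm[i] -= h[i]
        H[i, i] = (f(xp) - 2.0 * f0 + f(xm)) / h[i] ** 2
        for j in range(i):
            xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
            xpp[[i, j]] += [h[i], h[j]]
            xpm[[i, j]] += [h[i], -h[j]]
            xmp[[i, j]] += [-h[i], h[j]]
            xmm[[i, j]] += [-h[i], -h[j]]
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (
                4.0 * h[i] * h[j]
            )
    return H


# ---------------------------------------------------------------------------
# Laplace approximation (generic)

def laplace_marginal(logjoint, k: int, eta0=None, tol=1e-6, max_iter=100):
    """Laplace approximation to ``log integral exp(logjoint(eta)) d eta``.

    ``logjoint`` must already include the random-effect prior.  Returns
    ``(log_marginal, eta_hat)``.  The mode search is a damped Newton
    iteration on finite-difference derivatives; failure raises
    :class:`RuntimeError`.
    """
    x = np.zeros(k) if eta0 is None else np.asarray(eta0, dtype=float).copy()
    if k == 0:
        return float(logjoint(x)), x

    def neg(e):
        return -logjoint(e)

    f0 = neg(x)
    converged = False
    for _ in range(max_iter):
        g = fd_gradient(neg, x)
        if np.max(np.abs(g)) < tol:
            converged = True
            break
        B = fd_hessian(neg, x)
        ridge = 0.0
        for _ in range(12):
            try:
                L = np.linalg.cholesky(B + ridge * np.eye(k))
                break
            except np.linalg.LinAlgError:
                ridge = max(2.0 * ridge, 1e-6)
        step = -np.linalg.solve(B + ridge * np.eye(k), g)
        alpha = 1.0
        while alpha > 1e-10:
            fn = neg(x + alpha * step)
            if fn <= f0:
                break
            alpha *= 0.5
        if alpha <= 1e-10:
            converged = True  # cannot improve: at (numerical) mode
            break
        x = x + alpha * step
        f0 = fn
        if np.max(np.abs(alpha * step)) < tol:
            converged = True
            break
    if not converged:
        res = optimize.minimize(neg, x, method="Nelder-Mead", options={"xatol": tol})
        if not res.success:
            raise RuntimeError("Laplace inner mode search failed")
        x, f0 = res.x, res.fun
    H = fd_hessian(neg, x)
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:  # ridge a non-PD curvature estimate
        H = H + (abs(np.min(np.linalg.eigvalsh(H))) + 1e-8) * np.eye(k)
        _, logdet = np.linalg.slogdet(H)
    return float(-f0 + 0.5 * k * _LOG2PI - 0.5 * logdet), x


# ---------------------------------------------------------------------------
# per-subject data and conditional density

@dataclass
class _SubjectData:
    subject: SubjectProfile
    y: np.ndarray  # observed HR
    t: np.ndarray
    ctime: np.ndarray
    conc: np.ndarray
    occ_starts: np.ndarray  # reduceat boundaries (occasion blocks)
    f_ttp: float = 1.0
    f_age: float = 1.0
    f_comp: np.ndarray = None  # type: ignore[assignment]
    eta_hat: np.ndarray | None = None  # warm start across OFV evaluations


def _prepare_subjects(records, cohort) -> list[_SubjectData]:
    df = as_frame(records)
    profiles = {s.subject_id: s for s in cohort}
    missing = set(df["subject_id"]) - set(profiles)
    if missing:
        raise ValueError(f"records reference unknown subject(s): {sorted(missing)[:5]}")
    out = []
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("occasion_id", kind="stable")
        occ = grp["occasion_id"].to_numpy()
        starts = np.flatnonzero(np.r_[True, occ[1:] != occ[:-1]])
        out.append(
            _SubjectData(
                subject=profiles[sid],
                y=grp["hr_bpm"].to_numpy(dtype=float),
                t=grp["t_weeks"].to_numpy(dtype=float),
                ctime=grp["ctime_h"].to_numpy(dtype=float),
                conc=grp["conc_m2"].to_numpy(dtype=float),
                occ_starts=starts,
            )
        )
    return out


def _update_covariate_factors(subjects: list[_SubjectData], spec: HRModelSpec):
    for sd in subjects:
        f_ttp, f_age, f_comp = subject_covariate_factors(sd.subject, spec, sd.t)
        sd.f_ttp, sd.f_age = f_ttp, f_age
        sd.f_comp = np.broadcast_to(np.asarray(f_comp, dtype=float), sd.t.shape)


def _conditional_loglik(sd: _SubjectData, spec: HRModelSpec, eta: dict) -> float:
    """log p(y | eta): Gaussian with occasion-level compound symmetry."""
    base = spec.hr_base * math.exp(eta.get("hr_base", 0.0)) * sd.f_ttp
    rec = spec.hr_rec * math.exp(eta.get("hr_rec", 0.0)) * sd.f_age
    tc = np.clip(sd.t, 0.0, None)
    if spec.time_effect_form == "linear":
        te = spec.alpha * tc
    else:
        te = (rec - base) * -np.expm1(-LN2 * tc / spec.t_prog)
    amp_scale = math.exp(boxcox_eta(eta.get("amp", 0.0), spec.boxcox_lambda))
    diur = amp_scale * (
        spec.amp24 * np.cos(2 * np.pi * (sd.ctime - spec.phi24) / 24.0)
        + spec.amp12 * np.cos(2 * np.pi * (sd.ctime - spec.phi12) / 12.0)
    )
    ec50 = spec.ec50_m2 * math.exp(eta.get("ec50", 0.0))
    pred = (base + te + diur) * (1.0 - spec.emax_m2 * sd.conc / (ec50 + sd.conc))
    pred = pred * sd.f_comp
    if np.any(pred <= 0):
        return -1e10  # pathological region: steer the optimiser away
    sp = spec.sigma_prop * math.exp(eta.get("ruv_prop", 0.0))
    sa = spec.sigma_add * math.exp(eta.get("ruv_add", 0.0))
    r = sd.y - pred
    d = (pred * sp) ** 2
    a = sa * sa
    st = sd.occ_starts
    s_inv = np.add.reduceat(1.0 / d, st)
    s_r = np.add.reduceat(r / d, st)
    s_r2 = np.add.reduceat(r * r / d, st)
    s_logd = np.add.reduceat(np.log(d), st)
    denom = 1.0 + a * s_inv
    quad = float(np.sum(s_r2 - a * s_r**2 / denom))
    logdet = float(np.sum(s_logd + np.log(denom)))
    return -0.5 * (sd.y.size * _LOG2PI + logdet + quad)


# ---------------------------------------------------------------------------
# marginal likelihood

class LikelihoodContext:
    """Caches per-subject data and posterior-mode warm starts across OFV calls."""

    def __init__(self, records, cohort, inner_tol=1e-6, on_inner_failure="raise"):
        self.subjects = _prepare_subjects(records, cohort)
        self.inner_tol = inner_tol
        self.on_inner_failure = on_inner_failure

    def ofv(self, spec: HRModelSpec) -> float:
        spec.validate()
        _update_covariate_factors(self.subjects, spec)
        names, cov = spec.omega_matrix()
        k = len(names)
        total = 0.0
        if k == 0:
            for sd in self.subjects:
                total += _conditional_loglik(sd, spec, {})
            return -2.0 * total
        cov_inv = np.linalg.inv(cov)
        _, logdet_cov = np.linalg.slogdet(cov)
        prior_const = -0.5 * (k * _LOG2PI + logdet_cov)

        for sd in self.subjects:

            def logjoint(evec, sd=sd):
                eta = dict(zip(names, evec))
                return (
                    _conditional_loglik(sd, spec, eta)
                    + prior_const
                    - 0.5 * float(evec @ cov_inv @ evec)
                )

            eta0 = sd.eta_hat if sd.eta_hat is not None and sd.eta_hat.size == k else None
            try:
                ll, eta_hat = laplace_marginal(
                    logjoint, k, eta0=eta0, tol=self.inner_tol
                )
                sd.eta_hat = eta_hat
            except RuntimeError:
                if self.on_inner_failure == "skip":
                    logger.warning(
                        "subject %s: inner mode search failed; skipped",
                        sd.subject.subject_id,
                    )
                    continue
                raise
            total += ll
        return -2.0 * total


def loglikelihood(records, cohort, spec: HRModelSpec, **kwargs) -> float:
    """OFV = -2 log marginal likelihood of the data under ``spec``."""
    return LikelihoodContext(records, cohort, **kwargs).ofv(spec)


# ---------------------------------------------------------------------------
# fixed-effect optimisation

_LOG_PARAMS = {
    "hr_base",
    "hr_rec",
    "t_prog",
    "amp24",
    "amp12",
    "ec50_m2",
    "sigma_prop",
    "sigma_add",
}
_LOGIT_PARAMS = {"emax_m2"}


def get_param(spec: HRModelSpec, name: str) -> float:
    if name.startswith("omega2_"):
        return spec.omega2.get(name[7:], 0.0)
    return getattr(spec, name)


def set_param(spec: HRModelSpec, name: str, value: float) -> HRModelSpec:
    if name.startswith("omega2_"):
        omega2 = dict(spec.omega2)
        omega2[name[7:]] = value
        return dataclasses.replace(spec, omega2=omega2)
    return dataclasses.replace(spec, **{name: value})


def _to_internal(name: str, value: float) -> float:
    if name in _LOG_PARAMS or name.startswith("omega2_"):
        if value <= 0:
            raise ValueError(f"{name} must be > 0 to be estimated")
        return math.log(value)
    if name in _LOGIT_PARAMS:
        return math.log(value / (1.0 - value))
    return value


def _from_internal(name: str, x: float) -> float:
    if name in _LOG_PARAMS or name.startswith("omega2_"):
        return math.exp(x)
    if name in _LOGIT_PARAMS:
        return 1.0 / (1.0 + math.exp(-x))
    return x


@dataclass
class FitResult:
    """Estimates, uncertainty and diagnostics from a marginal-ML fit."""

    estimates: HRModelSpec
    se: dict = field(default_factory=dict)
    ofv: float = math.nan
    converged: bool = False
    n_eval: int = 0
    trace: list = field(default_factory=list)
    cov: np.ndarray | None = None
    mask: list = field(default_factory=list)

    def summary(self) -> str:
        """Plain-text parameter table (estimate, SE, 95% CI)."""
        lines = [f"{'parameter':<18}{'estimate':>12}{'SE':>12}{'95% CI':>26}"]
        for name in self.mask:
            est = get_param(self.estimates, name)
            se = self.se.get(name, math.nan)
            lo, hi = est - 1.96 * se, est + 1.96 * se
            lines.append(f"{name:<18}{est:>12.4g}{se:>12.3g}   [{lo:>9.4g}, {hi:>9.4g}]")
        lines.append(f"OFV: {self.ofv:.4f}   converged: {self.converged}")
        return "\n".join(lines)


def fit(
    records,
    cohort,
    init: HRModelSpec,
    mask: list[str],
    inner_tol: float = 1e-6,
    outer_tol: float = 1e-4,
    max_iter: int = 200,
    compute_se: bool = True,
) -> FitResult:
    """Minimise OFV over the parameters named in ``mask``.

    Positivity-constrained parameters are optimised on the log scale and
    Emax on the logit scale; standard errors are reported on the natural
    scale from the inverse finite-difference Hessian of OFV/2.
    """
    if len(cohort) < 2:
        raise ValueError("fit requires at least 2 subjects")
    init.validate()
    ctx = LikelihoodContext(records, cohort, inner_tol=inner_tol)
    x0 = np.array([_to_internal(n, get_param(init, n)) for n in mask])
    trace: list[float] = []

    def apply(x) -> HRModelSpec:
        spec = init
        for n, xi in zip(mask, x):
            spec = set_param(spec, n, _from_internal(n, float(xi)))
        return spec

    def objective(x) -> float:
        try:
            val = ctx.ofv(apply(x))
        except Exception:  # pathological point during line search
            val = 1e12
        trace.append(val)
        return val

    res = optimize.minimize(
        objective,
        x0,
        method="L-BFGS-B",
        options={
            "maxiter": max_iter,
            "ftol": outer_tol * 1e-4,
            "gtol": 1e-5,
            "eps": 1e-5,
        },
    )
    best = apply(res.x)
    result = FitResult(
        estimates=best,
        ofv=float(res.fun),
        converged=bool(res.success),
        n_eval=int(res.nfev),
        trace=trace,
        mask=list(mask),
    )
    if compute_se:
        theta0 = np.array([get_param(best, n) for n in mask])

        def half_ofv(theta):
            spec = init
            for n, v in zip(mask, theta):
                spec = set_param(spec, n, float(v))
            try:
                return 0.5 * ctx.ofv(spec)
            except Exception:
                return 1e12

        H = fd_hessian(half_ofv, theta0, rel_step=1e-3)
        try:
            cov = np.linalg.pinv(H)
            diag = np.diag(cov)
            result.cov = cov
            result.se = {
                n: (math.sqrt(d) if d > 0 else math.nan)
                for n, d in zip(mask, diag)
            }
        except np.linalg.LinAlgError:
            logger.warning("SE computation failed: singular Hessian")
    return result


# ---------------------------------------------------------------------------
# stepwise covariate modelling

#: OFV drop thresholds (1 df): forward inclusion P<0.05, backward P<0.01.
SCM_FORWARD_DOFV = 3.84
SCM_BACKWARD_DOFV = 6.63


def scm_step(
    records,
    cohort,
    base_spec: HRModelSpec,
    candidates: list[str],
    direction: str = "forward",
    base_mask: list[str] | None = None,
    **fit_kwargs,
) -> tuple[HRModelSpec, list[dict]]:
    """One stepwise covariate-selection pass, iterated to a fixed point.

    ``candidates`` are covariate-effect parameter names (e.g.
    ``cov_albumin_exp``).  Forward: repeatedly add the candidate with the
    largest OFV drop while it exceeds 3.84; backward: repeatedly remove the
    weakest included effect while its OFV penalty is below 6.63.  Returns
    the selected spec and a step-by-step report.
    """
    fit_kwargs.setdefault("compute_se", False)
    base_mask = list(base_mask or [])
    spec = base_spec
    included = [c for c in candidates if get_param(spec, c) != 0.0]
    remaining = [c for c in candidates if c not in included]
    report: list[dict] = []

    def fitted_ofv(s, extra):
        m = base_mask + extra
        if not m:
            return loglikelihood(records, cohort, s), s
        r = fit(records, cohort, s, m, **fit_kwargs)
        return r.ofv, r.estimates

    if direction == "forward":
        while remaining:
            ofv0, _ = fitted_ofv(spec, included)
            best = None
            for cand in remaining:
                start = set_param(spec, cand, get_param(spec, cand) or 0.0)
                ofv1, est = fitted_ofv(start, included + [cand])
                dofv = ofv0 - ofv1
                report.append({"step": "forward", "candidate": cand, "dofv": dofv})
                if dofv > SCM_FORWARD_DOFV and (best is None or dofv > best[0]):
                    best = (dofv, cand, est)
            if best is None:
                break
            _, cand, est = best
            spec = est
            included.append(cand)
            remaining.remove(cand)
    elif direction == "backward":
        while included:
            ofv_full, _ = fitted_ofv(spec, included)
            weakest = None
            for cand in included:
                reduced = set_param(spec, cand, 0.0)
                ofv_red, _ = fitted_ofv(reduced, [c for c in included if c != cand])
                dofv = ofv_red - ofv_full
                report.append({"step": "backward", "candidate": cand, "dofv": dofv})
                if dofv < SCM_BACKWARD_DOFV and (weakest is None or dofv < weakest[0]):
                    weakest = (dofv, cand)
            if weakest is None:
                break
            _, cand = weakest
            spec = set_param(spec, cand, 0.0)
            included.remove(cand)
            if included:
                _, spec = fitted_ofv(spec, included)
    else:
        raise ValueError("direction must be 'forward' or 'backward'")
    return spec, report


# ---------------------------------------------------------------------------
# visual predictive check

def vpc(
    records,
    cohort,
    spec: HRModelSpec,
    n_sim: int = 200,
    scheme=None,
    seed=0,
    percentiles=(2.5, 50.0, 97.5),
):
    """Simulation-based percentile bands of HR per time bin.

    Re-simulates the observed design ``n_sim`` times under ``spec``, and for
    each time bin reports the 95% interval of each simulated percentile
    alongside the observed percentile.  Empty bins are dropped with a
    warning.  Returns a tidy DataFrame.
    """
    import pandas as pd

    from .evaluation import TimeBinScheme, assign_bins
    from .simulate import fill_hr

    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    scheme = scheme or TimeBinScheme.default()
    df = as_frame(records).copy()
    df = assign_bins(df, scheme)
    obs_mask = df["bin"].notna()
    if not obs_mask.all():
        logger.warning("vpc: %d record(s) outside the bin scheme dropped", (~obs_mask).sum())
    recs = df.to_dict("records")
    rec_objs = [
        EcgRecord(
            subject_id=r["subject_id"], study=r["study"], arm=r["arm"],
            t_weeks=r["t_weeks"], ctime_h=r["ctime_h"], occasion_id=r["occasion_id"],
            replicate=int(r["replicate"]), hr_bpm=r["hr_bpm"], conc_m2=r["conc_m2"],
        )
        for r in recs
    ]
    rng = np.random.default_rng(seed)
    bins = df["bin"].to_numpy()
    labels = [b.label for b in scheme.bins if (bins == b.label).any()]
    sim_pcts = {lab: [] for lab in labels}
    for _ in range(n_sim):
        sim = fill_hr(rec_objs, cohort, spec, rng)
        hr = np.array([r.hr_bpm for r in sim])
        for lab in labels:
            sel = bins == lab
            sim_pcts[lab].append(np.percentile(hr[sel], percentiles))
    rows = []
    hr_obs = df["hr_bpm"].to_numpy()
    for lab in labels:
        sel = bins == lab
        obs = np.percentile(hr_obs[sel], percentiles)
        arr = np.asarray(sim_pcts[lab])  # (n_sim, n_pct)
        for ip, p in enumerate(percentiles):
            lo, mid, hi = np.percentile(arr[:, ip], [2.5, 50.0, 97.5])
            rows.append(
                {
                    "bin": lab,
                    "percentile": p,
                    "observed": obs[ip],
                    "sim_lo": lo,
                    "sim_median": mid,
                    "sim_hi": hi,
                    "n_obs": int(sel.sum()),
                }
            )
    return pd.DataFrame(rows)
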