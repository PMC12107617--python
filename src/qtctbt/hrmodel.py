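"""Nonlinear mixed-effects model of heart-rate normalisation on TB treatment.

The composite heart-rate prediction for subject *i* at treatment time *t*
(weeks), clock time *CTIME* (h) and metabolite concentration *C* (ng/mL) is

    HR = [B_i + (R_i - B_i) * (1 - 2^(-t / Tprog)) + DIUR_i(CTIME)]
         * (1 - Emax * C / (EC50_i + C)) * F_study * F_weight(t) * F_albumin

where ``B_i = HRbaseline * e^eta_B * F_ttp`` and ``R_i = HRrecovered *
e^eta_R * F_age`` are the individual baseline and recovered heart rates
(covariates enter as power functions of covariate / reference), and

    DIUR_i(CTIME) = A24_i cos(2 pi (CTIME - phi24) / 24)
                  + A12_i cos(2 pi (CTIME - phi12) / 12)

is the circadian deviation with two harmonics.  Inter-individual
variability is log-normal, ``p_i = theta * e^eta``, except for the shared
amplitude random effect which is Box-Cox shaped:
``eta* = (e^(lambda eta) - 1) / lambda``.  Pretreatment observations
(t < 0) are evaluated at the t = 0 structural state.

The published typical values (the package's defaults) put baseline HR at
78.2 bpm, recovered HR at 73.1 bpm with a recovery half-life of 7.74 weeks,
circadian amplitudes of 6.2 / 1.65 bpm peaking at 15.7 h / 10.1 h, and a
mild negative chronotropic metabolite effect (Emax 17.9%, EC50 2600 ng/mL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .data import SubjectProfile

LN2 = math.log(2.0)

#: Random-effect names, in canonical order.  "amp" is the single shared
#: amplitude effect scaling both harmonics; "ruv_prop"/"ruv_add" scale the
#: residual-error magnitudes per subject.
EFFECTS = ("hr_base", "hr_rec", "amp", "ec50", "ruv_prop", "ruv_add")


def cv_to_omega2(cv: float) -> float:
    """Variance of a log-normal random effect from its CV: omega^2 = ln(1 + CV^2)."""
    return math.log1p(cv * cv)


def omega2_to_cv(omega2: float) -> float:
    """CV of a log-normal random effect: CV = sqrt(e^(omega^2) - 1)."""
    return math.sqrt(math.expm1(omega2))


class ParameterError(ValueError):
    """Model parameters violate an invariant."""


@dataclass
class HRModelSpec:
    """Fixed effects, random-effect (co)variances and residual error model.

    Defaults are the final published estimates; ``omega2``/``corr`` default
    to empty (no inter-individual variability) — use :func:`published_model_spec`
    for the full stochastic model.
    """

    hr_base: float = 78.2  # bpm, typical baseline HR (active, untreated TB)
    hr_rec: float = 73.1  # bpm, typical recovered HR
    t_prog: float = 7.74  # weeks, recovery half-life
    amp24: float = 6.2  # bpm, 24-h circadian amplitude
    phi24: float = 15.7  # clock h, 24-h acrophase
    amp12: float = 1.65  # bpm, 12-h circadian amplitude
    phi12: float = 10.1  # clock h, 12-h acrophase
    boxcox_lambda: float = -0.77  # shape of the shared amplitude IIV
    emax_m2: float = 0.179  # maximal fractional HR decrease from M2
    ec50_m2: float = 2600.0  # ng/mL
    # Covariate effects (power exponents; study effect is conditional).
    cov_study: float = 0.047  # C209 typically lower: factor (1 - cov_study)
    cov_weight_exp: float = -0.2  # on composite HR
    cov_albumin_exp: float = -0.22  # on composite HR
    cov_ttp_exp: float = -0.05  # on baseline HR
    cov_age_exp: float = 0.08  # on recovered HR
    # Reference covariate values.
    ref_weight_kg: float = 56.0
    ref_albumin_gL: float = 35.0
    ref_age_y: float = 33.0
    ref_ttp_h: float = 230.5
    # Stochastic model.
    omega2: dict = field(default_factory=dict)  # effect name -> variance
    corr: dict = field(default_factory=dict)  # (name, name) -> correlation
    sigma_prop: float = 0.084  # proportional RUV (fraction), per replicate
    sigma_add: float = 2.7  # additive RUV (bpm), shared per triplicate occasion
    # Structural options.
    time_effect_form: str = "asymptotic"  # or "linear"
    alpha: float = 0.0  # bpm/week, linear form only

    def validate(self) -> None:
        if self.t_prog <= 0:
            raise ParameterError("t_prog must be > 0")
        if not (0 <= self.emax_m2 < 1):
            raise ParameterError("emax_m2 must be in [0, 1)")
        if self.ec50_m2 <= 0:
            raise ParameterError("ec50_m2 must be > 0")
        if self.amp24 < 0 or self.amp12 < 0:
            raise ParameterError("amplitudes must be >= 0")
        for k, v in self.omega2.items():
            if k not in EFFECTS:
                raise ParameterError(f"unknown random effect {k!r}")
            if v < 0:
                raise ParameterError(f"omega2[{k}] must be >= 0")
        for pair, rho in self.corr.items():
            if not (-1 < rho < 1):
                raise ParameterError(f"corr{pair} must be in (-1, 1)")
        names, cov = self.omega_matrix()
        if names and np.min(np.linalg.eigvalsh(cov)) < -1e-10:
            raise ParameterError("implied random-effect covariance is not PSD")

    def active_effects(self) -> list[str]:
        """Random effects with non-zero variance, in canonical order."""
        return [e for e in EFFECTS if self.omega2.get(e, 0.0) > 0]

    def omega_matrix(self) -> tuple[list[str], np.ndarray]:
        """Covariance matrix of the active random effects."""
        names = self.active_effects()
        k = len(names)
        cov = np.zeros((k, k))
        for i, a in enumerate(names):
            cov[i, i] = self.omega2[a]
            for j, b in enumerate(names[:i]):
                rho = self.corr.get((a, b), self.corr.get((b, a), 0.0))
                cov[i, j] = cov[j, i] = rho * math.sqrt(
                    self.omega2[a] * self.omega2[b]
                )
        return names, cov

    def updated(self, **kwargs) -> "HRModelSpec":
        return replace(self, **kwargs)


#: Published inter-individual variability, as %CV.
PUBLISHED_IIV_CV = {
    "hr_base": 0.15,
    "hr_rec": 0.154,
    "amp": 0.953,
    "ec50": 8.834,
    "ruv_prop": 0.236,
    "ruv_add": 0.385,
}

#: Published random-effect correlations.
PUBLISHED_CORR = {
    ("hr_base", "hr_rec"): 0.41,
    ("hr_base", "amp"): -0.26,
    ("hr_rec", "amp"): -0.421,
    ("ruv_prop", "ruv_add"): 0.38,
}


def published_model_spec(effects: tuple[str, ...] = EFFECTS) -> HRModelSpec:
    """The full published model: typical values plus the stochastic model.

    ``effects`` restricts which random effects carry their published
    variance (the rest get none) — handy for reduced-IIV simulation and
    estimation designs.
    """
    omega2 = {e: cv_to_omega2(PUBLISHED_IIV_CV[e]) for e in effects}
    corr = {
        pair: rho
        for pair, rho in PUBLISHED_CORR.items()
        if pair[0] in effects and pair[1] in effects
    }
    return HRModelSpec(omega2=omega2, corr=corr)


def time_effect(spec: HRModelSpec, t_weeks) -> np.ndarray:
    """Time-on-treatment HR change (bpm) at the typical parameter values.

    Asymptotic form: ``(HRrec - HRbase) * (1 - 2^(-t/Tprog))``; linear form:
    ``alpha * t``.  Pretreatment times clamp to the t = 0 state (zero change).
    """
    if spec.t_prog <= 0:
        raise ParameterError("t_prog must be > 0")
    t = np.clip(np.asarray(t_weeks, dtype=float), 0.0, None)
    if spec.time_effect_form == "linear":
        return spec.alpha * t
    return (spec.hr_rec - spec.hr_base) * -np.expm1(-LN2 * t / spec.t_prog)


def circadian(spec: HRModelSpec, ctime_h, amp24=None, amp12=None) -> np.ndarray:
    """Circadian HR deviation (bpm): two cosine harmonics with 24 h / 12 h periods."""
    c = np.asarray(ctime_h, dtype=float)
    a24 = spec.amp24 if amp24 is None else amp24
    a12 = spec.amp12 if amp12 is None else amp12
    return a24 * np.cos(2 * np.pi * (c - spec.phi24) / 24.0) + a12 * np.cos(
        2 * np.pi * (c - spec.phi12) / 12.0
    )


def m2_effect(spec: HRModelSpec, conc_m2, ec50=None) -> np.ndarray:
    """Fractional HR decrease from the M2 metabolite: Emax * C / (EC50 + C)."""
    c = np.asarray(conc_m2, dtype=float)
    if np.any(c < 0):
        raise ValueError("conc_m2 must be >= 0")
    e50 = spec.ec50_m2 if ec50 is None else ec50
    return spec.emax_m2 * c / (e50 + c)


def covariate_factor(value, reference: float, exponent: float) -> np.ndarray:
    """Power covariate model: (value / reference) ** exponent."""
    v = np.asarray(value, dtype=float)
    if reference <= 0 or np.any(v <= 0):
        raise ValueError("covariate value and reference must be > 0")
    return (v / reference) ** exponent


def conditional_factor(flag, theta: float) -> np.ndarray:
    """Conditional covariate model: 1 + theta * indicator."""
    return 1.0 + theta * np.asarray(flag, dtype=float)


def boxcox_eta(eta, lam: float) -> np.ndarray:
    """Box-Cox-shaped random effect: eta* = (e^(lambda eta) - 1) / lambda.

    The lambda -> 0 limit is the identity (plain exponential IIV).
    """
    eta = np.asarray(eta, dtype=float)
    if abs(lam) < 1e-10:
        return eta
    return np.expm1(lam * eta) / lam


def individual_params(spec: HRModelSpec, eta: Mapping[str, float] | None = None) -> dict:
    """Per-subject parameter set from a random-effect draw.

    ``eta`` maps effect names (subset of :data:`EFFECTS`) to values;
    omitted effects default to 0.  All effects act as ``theta * e^eta``
    except the shared amplitude effect, which is Box-Cox shaped and scales
    both harmonics.
    """
    eta = dict(eta or {})
    unknown = set(eta) - set(EFFECTS)
    if unknown:
        raise ParameterError(f"unknown random effect(s): {sorted(unknown)}")
    amp_scale = math.exp(boxcox_eta(eta.get("amp", 0.0), spec.boxcox_lambda))
    return {
        "hr_base": spec.hr_base * math.exp(eta.get("hr_base", 0.0)),
        "hr_rec": spec.hr_rec * math.exp(eta.get("hr_rec", 0.0)),
        "amp24": spec.amp24 * amp_scale,
        "amp12": spec.amp12 * amp_scale,
        "ec50": spec.ec50_m2 * math.exp(eta.get("ec50", 0.0)),
        "sigma_prop": spec.sigma_prop * math.exp(eta.get("ruv_prop", 0.0)),
        "sigma_add": spec.sigma_add * math.exp(eta.get("ruv_add", 0.0)),
    }


def subject_covariate_factors(subject: SubjectProfile, spec: HRModelSpec, t_weeks):
    """(F_ttp, F_age, F_composite(t)) covariate multipliers for one subject."""
    t = np.asarray(t_weeks, dtype=float)
    f_ttp = float(covariate_factor(subject.ttp_mgit_h, spec.ref_ttp_h, spec.cov_ttp_exp))
    f_age = float(covariate_factor(subject.age_y, spec.ref_age_y, spec.cov_age_exp))
    f_study = 1.0 - spec.cov_study if subject.study == "C209" else 1.0
    f_wt = covariate_factor(
        subject.weight_at(np.clip(t, 0.0, None)), spec.ref_weight_kg, spec.cov_weight_exp
    )
    f_alb = float(
        covariate_factor(subject.albumin_gL, spec.ref_albumin_gL, spec.cov_albumin_exp)
    )
    return f_ttp, f_age, f_study * f_wt * f_alb


def predict_hr(
    subject: SubjectProfile,
    spec: HRModelSpec,
    t_weeks,
    ctime_h,
    conc_m2=0.0,
    eta: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Composite heart-rate prediction (bpm) for one subject.

    Vectorised over ``t_weeks`` / ``ctime_h`` / ``conc_m2``.  Pretreatment
    times evaluate at the t = 0 structural state.  Raises on non-positive
    predictions (pathological parameters).
    """
    t = np.asarray(t_weeks, dtype=float)
    c = np.asarray(ctime_h, dtype=float)
    conc = np.asarray(conc_m2, dtype=float)
    ip = individual_params(spec, eta)
    f_ttp, f_age, f_comp = subject_covariate_factors(subject, spec, t)

    base = ip["hr_base"] * f_ttp
    rec = ip["hr_rec"] * f_age
    tc = np.clip(t, 0.0, None)
    if spec.time_effect_form == "linear":
        te = spec.alpha * tc
    else:
        if spec.t_prog <= 0:
            raise ParameterError("t_prog must be > 0")
        te = (rec - base) * -np.expm1(-LN2 * tc / spec.t_prog)
    diur = circadian(spec, c, amp24=ip["amp24"], amp12=ip["amp12"])
    pred = (base + te + diur) * (1.0 - m2_effect(spec, conc, ec50=ip["ec50"])) * f_comp
    if np.any(pred <= 0):
        raise ParameterError("non-positive HR prediction: pathological parameters")
    return pred
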