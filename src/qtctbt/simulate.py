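"""Virtual-cohort simulation: covariates, exposure, heart rate and QT.

The generator emulates the design of the two phase-IIb MDR-TB trials the
model was estimated on: ~440 subjects, ECG visits from Day -1 (pre-dose)
through Week 24, triplicate ECGs per visit at daytime clock times, a
placebo arm nested in one study, and covariate spreads matching the
published demographics (median age 33 y, weight 55 kg, albumin 35 g/L,
TTP MGIT 230.5 h).  Metabolite exposure uses a phenomenological
accumulation curve, ``Conc(t) = Css_i * (1 - 2^(-t / t_acc))``, scaled so
the population mean at Week 2 is ~300 ng/mL.  QT is generated from a
subject-level heart-rate-corrected QT (QTc0) through the *true*
time-varying exponent: ``QT = QTc0 * RR^CF_true(t) * e^(sigma_qt * eps)``.

Residual heart-rate error has two levels: a proportional component drawn
per replicate and an additive component drawn once per triplicate occasion
(shared by its replicates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .correction import CorrectionSpec, cf_tbt, rr_from_hr
from .data import DAY_MINUS_ONE, EcgRecord, SubjectProfile
from .hrmodel import LN2, HRModelSpec, predict_hr

#: Default visit schedule: (t_weeks, clock time or None => drawn, n replicates).
#: Day -1 pre-dose plus eight on-treatment visits covering every reporting bin.
DEFAULT_VISITS = tuple(
    (t, None, 3) for t in (DAY_MINUS_ONE, 1.0, 2.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0)
)

#: Covariate distributions: name -> (median, CV, lower, upper) of a truncated
#: log-normal, matched to the published medians and observed ranges.
DEFAULT_COVARIATES = {
    "age_y": (33.0, 0.30, 18.0, 68.0),
    "weight_kg": (55.0, 0.22, 30.0, 113.0),
    "albumin_gL": (35.0, 0.20, 15.0, 49.0),
    "ttp_mgit_h": (230.5, 0.70, 56.0, 1008.0),
}


@dataclass
class CohortDesign:
    """Everything the simulator needs to emulate the trial design."""

    n_subjects: int = 440
    placebo_fraction: float = 105.0 / 440.0  # placebo subjects (all in C208)
    c209_fraction: float = 233.0 / 440.0
    visits: tuple = DEFAULT_VISITS
    clock_window: tuple[float, float] = (8.0, 17.0)  # daytime ECGs
    covariates: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATES))
    # Exposure: Css median 600 ng/mL with t_acc = 2 weeks puts the
    # population mean concentration at Week 2 at 300 ng/mL.
    css_mean: float = 600.0
    css_cv: float = 0.45
    css_range: tuple[float, float] | None = None  # uniform Css (wide designs)
    t_acc_weeks: float = 2.0
    # QT truth.
    qtc0_median_ms: float = 400.0
    qtc0_cv: float = 0.05
    sigma_qt: float = 0.02
    cf_true: CorrectionSpec = field(default_factory=CorrectionSpec)

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (0 <= self.placebo_fraction <= 1):
            raise ValueError("placebo_fraction must be in [0, 1]")
        for cv in (self.css_cv, self.qtc0_cv, self.sigma_qt):
            if cv < 0:
                raise ValueError("CVs must be >= 0")
        if self.t_acc_weeks <= 0:
            raise ValueError("t_acc_weeks must be > 0")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _trunc_lognormal(rng, median, cv, lo, hi, size):
    """Log-normal with given median/CV, rejection-truncated to [lo, hi]."""
    if cv == 0:
        return np.full(size, float(median))
    sigma = math.sqrt(math.log1p(cv * cv))
    out = np.exp(rng.normal(math.log(median), sigma, size))
    bad = (out < lo) | (out > hi)
    tries = 0
    while np.any(bad) and tries < 1000:
        out[bad] = np.exp(rng.normal(math.log(median), sigma, int(bad.sum())))
        bad = (out < lo) | (out > hi)
        tries += 1
    return np.clip(out, lo, hi)


def make_cohort(design: CohortDesign, seed=0) -> list[SubjectProfile]:
    """Draw a virtual cohort of subject profiles.

    Covariates are mutually independent truncated log-normals; study labels
    and arms follow the design fractions, with the placebo arm nested in
    study C208 (as in the source trials).
    """
    design.validate()
    rng = _rng(seed)
    n = design.n_subjects
    draws = {
        name: _trunc_lognormal(rng, *params, n)
        for name, params in design.covariates.items()
    }
    n_c209 = int(round(design.c209_fraction * n))
    n_placebo = int(round(design.placebo_fraction * n))
    # C209 was single-arm active; placebo subjects therefore sit in C208.
    n_placebo = min(n_placebo, n - n_c209)
    studies = np.array(["C209"] * n_c209 + ["C208"] * (n - n_c209), dtype=object)
    arms = np.array(["active"] * n, dtype=object)
    arms[n_c209 : n_c209 + n_placebo] = "placebo"
    perm = rng.permutation(n)
    cohort = []
    for i in range(n):
        j = perm[i]
        cohort.append(
            SubjectProfile(
                subject_id=f"S{i + 1:04d}",
                study=str(studies[j]),
                arm=str(arms[j]),
                age_y=float(draws["age_y"][i]),
                weight_kg=float(draws["weight_kg"][i]),
                albumin_gL=float(draws["albumin_gL"][i]),
                ttp_mgit_h=float(draws["ttp_mgit_h"][i]),
            )
        )
    return cohort


def _draw_css(design: CohortDesign, rng) -> float:
    if design.css_range is not None:
        return float(rng.uniform(*design.css_range))
    if design.css_cv == 0:
        return design.css_mean
    sigma = math.sqrt(math.log1p(design.css_cv**2))
    return float(np.exp(rng.normal(math.log(design.css_mean), sigma)))


def m2_concentration(css: float, t_weeks, t_acc_weeks: float) -> np.ndarray:
    """Accumulation curve ``Css * (1 - 2^(-t/t_acc))``; zero pre-dose (t <= 0)."""
    t = np.asarray(t_weeks, dtype=float)
    return np.where(t > 0, css * -np.expm1(-LN2 * np.clip(t, 0, None) / t_acc_weeks), 0.0)


def simulate_m2_profile(
    subject: SubjectProfile, times, design: CohortDesign, seed=0
) -> np.ndarray:
    """M2 concentration (ng/mL) at the given treatment times for one subject.

    Placebo subjects and pre-dose times get 0.  The individual steady-state
    concentration is drawn once per call from the design's Css distribution.
    """
    t = np.asarray(times, dtype=float)
    if subject.arm != "active":
        return np.zeros_like(t)
    css = _draw_css(design, _rng(seed))
    return m2_concentration(css, t, design.t_acc_weeks)


def _design_rows(cohort, design, rng):
    """Per-subject design rows (no HR yet): times, clock times, occasions, conc."""
    rows = []
    lo, hi = design.clock_window
    for s in cohort:
        css = _draw_css(design, rng) if s.arm == "active" else 0.0
        for k, (t, ctime, nrep) in enumerate(design.visits):
            ct = float(rng.uniform(lo, hi)) if ctime is None else float(ctime)
            conc = float(m2_concentration(css, t, design.t_acc_weeks)) if css else 0.0
            for rep in range(1, nrep + 1):
                rows.append(
                    EcgRecord(
                        subject_id=s.subject_id,
                        study=s.study,
                        arm=s.arm,
                        t_weeks=float(t),
                        ctime_h=ct,
                        occasion_id=f"{s.subject_id}-occ{k}",
                        replicate=rep,
                        hr_bpm=math.nan,
                        conc_m2=conc,
                    )
                )
    return rows


def fill_hr(
    records: list[EcgRecord],
    cohort: list[SubjectProfile],
    model: HRModelSpec,
    seed=0,
    max_resample: int = 100,
) -> list[EcgRecord]:
    """Redraw heart rates for an existing design (used by simulation and VPC).

    For each subject a correlated random-effect vector is drawn from the
    model's omega matrix; observation noise is
    ``hr = pred * (1 + sigma_prop_i * eps1) + sigma_add_i * eps2`` with
    ``eps1`` per replicate and ``eps2`` shared per triplicate occasion.
    Non-positive draws are resampled (up to ``max_resample`` times).
    """
    model.validate()
    rng = _rng(seed)
    names, cov = model.omega_matrix()
    chol = np.linalg.cholesky(cov) if names else None
    by_subject: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_subject.setdefault(r.subject_id, []).append(i)
    profiles = {s.subject_id: s for s in cohort}
    out = [dc_replace(r) for r in records]
    from .hrmodel import individual_params  # local import avoids cycle confusion

    for sid, idx in by_subject.items():
        subj = profiles[sid]
        eta = {}
        if names:
            z = chol @ rng.standard_normal(len(names))
            eta = dict(zip(names, z))
        t = np.array([records[i].t_weeks for i in idx])
        ct = np.array([records[i].ctime_h for i in idx])
        conc = np.array([records[i].conc_m2 for i in idx])
        occ = np.array([records[i].occasion_id for i in idx])
        pred = predict_hr(subj, model, t, ct, conc, eta)
        ip = individual_params(model, eta)
        sp, sa = ip["sigma_prop"], ip["sigma_add"]
        uniq, inv = np.unique(occ, return_inverse=True)
        eps2 = rng.standard_normal(len(uniq))[inv]
        eps1 = rng.standard_normal(len(idx))
        hr = pred * (1.0 + sp * eps1) + sa * eps2
        for _ in range(max_resample):
            bad = hr <= 0
            if not np.any(bad):
                break
            nb = int(bad.sum())
            hr[bad] = pred[bad] * (1.0 + sp * rng.standard_normal(nb)) + sa * (
                rng.standard_normal(nb)
            )
        if np.any(hr <= 0):
            raise RuntimeError(f"subject {sid}: could not draw positive HR")
        for i, h in zip(idx, hr):
            out[i].hr_bpm = float(h)
    return out


def simulate_hr_observations(
    cohort: list[SubjectProfile],
    model: HRModelSpec,
    design: CohortDesign,
    seed=0,
) -> list[EcgRecord]:
    """Simulate the ECG design and heart-rate observations for a cohort."""
    design.validate()
    rng = _rng(seed)
    rows = _design_rows(cohort, design, rng)
    return fill_hr(rows, cohort, model, rng)


def simulate_qt_observations(
    records: list[EcgRecord], design: CohortDesign, seed=0
) -> list[EcgRecord]:
    """Fill QT on records that already carry heart rate.

    ``QT_ij = QTc0_i * RR_ij^CF_true(t_ij) * e^(sigma_qt * eps)`` with a
    log-normal subject-level QTc0 and the design's true (time-varying)
    correction exponent; CF clamps to its pretreatment value for t < 0.
    """
    rng = _rng(seed)
    out = [dc_replace(r) for r in records]
    sids = sorted({r.subject_id for r in records})
    if design.qtc0_cv > 0:
        sigma0 = math.sqrt(math.log1p(design.qtc0_cv**2))
        qtc0 = {
            sid: float(np.exp(rng.normal(math.log(design.qtc0_median_ms), sigma0)))
            for sid in sids
        }
    else:
        qtc0 = {sid: design.qtc0_median_ms for sid in sids}
    for r in out:
        if math.isnan(r.hr_bpm):
            raise ValueError("simulate_qt_observations needs HR-filled records")
        rr = float(rr_from_hr(r.hr_bpm))
        cf = float(cf_tbt(r.t_weeks, design.cf_true))
        noise = math.exp(design.sigma_qt * rng.standard_normal()) if design.sigma_qt else 1.0
        r.qt_ms = qtc0[r.subject_id] * rr**cf * noise
    return out


def make_dataset(
    design: CohortDesign, model: HRModelSpec, seed=0
) -> tuple[list[EcgRecord], list[SubjectProfile]]:
    """Cohort -> HR -> QT in one call; returns (records, cohort)."""
    ss = np.random.SeedSequence(seed)
    s_cohort, s_hr, s_qt = ss.spawn(3)
    cohort = make_cohort(design, np.random.default_rng(s_cohort))
    records = simulate_hr_observations(cohort, model, design, np.random.default_rng(s_hr))
    records = simulate_qt_observations(records, design, np.random.default_rng(s_qt))
    return records, cohort
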