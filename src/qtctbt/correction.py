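"""QT-interval heart-rate correction formulas, including the time-varying
correction factor for TB patients on treatment (QTcTBT).

Power-law corrections divide QT by a power of the RR interval in seconds,
``QTc = QT / RR^x``: Bazett (x = 0.5), Fridericia (x = 0.33), Olliaro's
pretreatment-TB factor (x = 0.4081) and the time-varying TBT factor

    CF(t) = 0.4081 - 0.0781 * (1 - 2^(-t / 7.74)),   t in weeks,

which declines from the Olliaro exponent at treatment start to the
Fridericia exponent with the 7.74-week half-life of heart-rate recovery.
Two linear corrections are also provided: Framingham
``QTc = QT + 154 (1 - RR_s)`` (ms) and Van de Water
``QTc = QT - 0.087 (RR_ms - 1000)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

LN2 = math.log(2.0)

#: Fixed exponents of the named power-law corrections.
POWER_EXPONENTS = {"bazett": 0.5, "fridericia": 0.33, "olliaro": 0.4081}

METHODS = (
    "bazett",
    "fridericia",
    "olliaro",
    "framingham",
    "vandewater",
    "tbt",
    "custom-power",
    "custom-time-varying",
)


@dataclass(frozen=True)
class CorrectionSpec:
    """Identity and parameters of a QT correction method.

    ``exponent`` applies to the constant power-law methods;
    ``cf_pre``/``cf_post``/``t_half`` parameterise the time-varying factor
    (declining from ``cf_pre`` at t = 0 to ``cf_post`` asymptotically).
    """

    method: str = "tbt"
    exponent: float | None = None
    cf_pre: float = 0.4081
    cf_post: float = 0.33
    t_half: float = 7.74  # weeks

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown correction method {self.method!r}")
        if self.method in ("tbt", "custom-time-varying"):
            if self.t_half <= 0:
                raise ValueError("t_half must be > 0")
            if self.cf_pre <= 0 or self.cf_post <= 0:
                raise ValueError("cf_pre and cf_post must be > 0")
        if self.method == "custom-power" and (self.exponent is None or self.exponent <= 0):
            raise ValueError("custom-power needs a positive exponent")

    @property
    def label(self) -> str:
        return {"bazett": "QTcB", "fridericia": "QTcF", "olliaro": "QTcO",
                "framingham": "QTcFra", "vandewater": "QTcVa", "tbt": "QTcTBT"}.get(
            self.method, self.method
        )


def method_spec(method: str, **kwargs) -> CorrectionSpec:
    """Build a :class:`CorrectionSpec` from a method name."""
    return CorrectionSpec(method=method, **kwargs)


def rr_from_hr(hr_bpm) -> np.ndarray:
    """RR interval in seconds from heart rate in bpm: RR = 60 / HR."""
    hr = np.asarray(hr_bpm, dtype=float)
    if np.any(hr <= 0):
        raise ValueError("hr_bpm must be > 0")
    return 60.0 / hr


def hr_from_rr(rr_s) -> np.ndarray:
    """Heart rate in bpm from RR interval in seconds (inverse of rr_from_hr)."""
    rr = np.asarray(rr_s, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("rr_s must be > 0")
    return 60.0 / rr


def cf_tbt(t_weeks, spec: CorrectionSpec | None = None) -> np.ndarray:
    """Time-varying correction exponent CF(t).

    ``CF(t) = cf_pre - (cf_pre - cf_post) * (1 - 2^(-t / t_half))``;
    pretreatment times (t < 0) clamp to ``cf_pre``.
    """
    spec = spec or CorrectionSpec()
    t = np.clip(np.asarray(t_weeks, dtype=float), 0.0, None)
    return spec.cf_pre - (spec.cf_pre - spec.cf_post) * -np.expm1(
        -LN2 * t / spec.t_half
    )


def correct_qt(qt_ms, hr_bpm, t_weeks=0.0, spec: CorrectionSpec | str = "fridericia"):
    """Heart-rate-corrected QT (ms) by any supported method.

    ``t_weeks`` matters only for the time-varying methods.  All formulas fix
    the HR = 60 bpm (RR = 1 s) point: QTc = QT there.
    """
    if isinstance(spec, str):
        spec = method_spec(spec)
    qt = np.asarray(qt_ms, dtype=float)
    rr_s = rr_from_hr(hr_bpm)
    m = spec.method
    if m in POWER_EXPONENTS or m == "custom-power":
        x = POWER_EXPONENTS.get(m, spec.exponent)
        return qt / rr_s**x
    if m in ("tbt", "custom-time-varying"):
        return qt / rr_s ** cf_tbt(t_weeks, spec)
    if m == "framingham":
        return qt + 154.0 * (1.0 - rr_s)
    if m == "vandewater":
        return qt - 0.087 * (rr_s * 1000.0 - 1000.0)
    raise ValueError(f"unknown correction method {m!r}")
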