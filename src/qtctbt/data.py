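"""Shared data model and tabular I/O for ECG replicate data.

The canonical in-memory representation is a long-format table with one row
per ECG replicate.  Two light dataclasses mirror the two natural entities:
:class:`EcgRecord` (one replicate) and :class:`SubjectProfile` (one virtual
or real patient with baseline covariates).  All analysis functions accept
either a list of records or the equivalent :class:`pandas.DataFrame`.

Units are canonical throughout: heart rate in bpm, QT in ms, treatment time
in weeks (negative = pretreatment; Day -1 is -1/7), clock time in hours
[0, 24), metabolite concentration in ng/mL.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("qtctbt")

#: Day -1 expressed in treatment weeks.
DAY_MINUS_ONE = -1.0 / 7.0

#: Canonical column vocabulary of the ECG table, in writing order.
ECG_COLUMNS = (
    "subject_id",
    "study",
    "arm",
    "t_weeks",
    "ctime_h",
    "occasion_id",
    "replicate",
    "hr_bpm",
    "qt_ms",
    "conc_m2",
    "assessment",
)

#: Covariate columns appended when subject profiles are written alongside.
COVARIATE_COLUMNS = ("age_y", "weight_kg", "albumin_gL", "ttp_mgit_h", "sex", "hiv")

MANDATORY_COLUMNS = (
    "subject_id",
    "study",
    "arm",
    "t_weeks",
    "ctime_h",
    "occasion_id",
    "replicate",
    "hr_bpm",
)


class SchemaError(ValueError):
    """A mandatory column is missing or unmappable."""


class ValidationError(ValueError):
    """One or more rows violate the data-model invariants."""

    def __init__(self, message: str, rows: Sequence[int] = ()):  # noqa: D107
        super().__init__(message)
        self.rows = list(rows)


@dataclass
class EcgRecord:
    """One ECG replicate measurement.

    ``qt_ms`` may be NaN for heart-rate-only records (e.g. between the HR
    and QT simulation stages); when present it must be positive.
    """

    subject_id: str
    study: str  # {"C208", "C209", "other"}
    arm: str  # {"active", "placebo"}
    t_weeks: float
    ctime_h: float
    occasion_id: str
    replicate: int
    hr_bpm: float
    qt_ms: float = math.nan
    conc_m2: float = 0.0
    assessment: str = "predose"


@dataclass
class SubjectProfile:
    """Baseline covariates and design arm for one patient.

    ``weight_kg`` may be a scalar or a list of ``(t_weeks, kg)`` pairs for
    time-varying body weight; :meth:`weight_at` interpolates.
    """

    subject_id: str
    study: str = "C208"
    arm: str = "active"
    age_y: float = 33.0
    weight_kg: float | list[tuple[float, float]] = 56.0
    albumin_gL: float = 35.0
    ttp_mgit_h: float = 230.5
    hiv: bool | None = None
    sex: str | None = None

    def weight_at(self, t_weeks: float | np.ndarray) -> np.ndarray:
        """Body weight at treatment time ``t_weeks`` (step-free interpolation)."""
        t = np.asarray(t_weeks, dtype=float)
        if isinstance(self.weight_kg, (int, float)):
            return np.broadcast_to(float(self.weight_kg), t.shape).copy()
        pts = sorted(self.weight_kg)
        xs = np.array([p[0] for p in pts], dtype=float)
        ys = np.array([p[1] for p in pts], dtype=float)
        return np.interp(t, xs, ys)

    def validate(self) -> None:
        if self.age_y < 18:
            raise ValidationError(
                f"subject {self.subject_id}: age_y must be >= 18, got {self.age_y}"
            )
        w = self.weight_kg if isinstance(self.weight_kg, (int, float)) else [
            kg for _, kg in self.weight_kg
        ]
        if np.any(np.asarray(w) <= 0):
            raise ValidationError(f"subject {self.subject_id}: non-positive weight")
        if self.ttp_mgit_h <= 0:
            raise ValidationError(f"subject {self.subject_id}: non-positive TTP MGIT")


def validate_records(records: Iterable[EcgRecord]) -> None:
    """Check every record against the data-model invariants.

    Raises :class:`ValidationError` naming the offending row indices
    (0-based position in the iterable).  Rows are checked individually, and
    triplicate-occasion consistency (shared subject, time, clock time) is
    checked across rows.
    """
    bad: list[tuple[int, str]] = []
    occ_key: dict[tuple[str, str], tuple] = {}
    for i, r in enumerate(records):
        if not (r.hr_bpm > 0):
            bad.append((i, f"hr_bpm={r.hr_bpm!r} not > 0"))
        if not math.isnan(r.qt_ms) and not (r.qt_ms > 0):
            bad.append((i, f"qt_ms={r.qt_ms!r} not > 0"))
        if r.conc_m2 < 0:
            bad.append((i, f"conc_m2={r.conc_m2!r} < 0"))
        if not (0 <= r.ctime_h < 24):
            bad.append((i, f"ctime_h={r.ctime_h!r} outside [0, 24)"))
        if r.replicate not in (1, 2, 3):
            bad.append((i, f"replicate={r.replicate!r} not in 1..3"))
        key = (r.subject_id, r.occasion_id)
        sig = (r.t_weeks, r.ctime_h)
        if key in occ_key and occ_key[key] != sig:
            bad.append((i, f"occasion {r.occasion_id} has inconsistent time stamps"))
        occ_key.setdefault(key, sig)
    if bad:
        detail = "; ".join(f"row {i}: {msg}" for i, msg in bad[:20])
        rows = list(dict.fromkeys(i for i, _ in bad))  # dedupe, keep order
        raise ValidationError(f"{len(rows)} invalid row(s): {detail}", rows)


def records_to_frame(
    records: Iterable[EcgRecord],
    subjects: Iterable[SubjectProfile] | None = None,
) -> pd.DataFrame:
    """Convert records (and optionally subject covariates) to the long table."""
    df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=list(ECG_COLUMNS))
    if subjects is not None:
        rows = []
        for s in subjects:
            w = s.weight_kg
            if not isinstance(w, (int, float)):
                w = sorted(w)[0][1]  # baseline weight when time-varying
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "age_y": s.age_y,
                    "weight_kg": w,
                    "albumin_gL": s.albumin_gL,
                    "ttp_mgit_h": s.ttp_mgit_h,
                    "sex": s.sex,
                    "hiv": s.hiv,
                }
            )
        cov = pd.DataFrame(rows)
        df = df.merge(cov, on="subject_id", how="left")
    return df


def frame_to_records(df: pd.DataFrame) -> tuple[list[EcgRecord], list[SubjectProfile]]:
    """Split a long table into validated records and subject profiles."""
    records = []
    for _, row in df.iterrows():
        conc = row.get("conc_m2", 0.0)
        if pd.isna(conc):
            logger.warning(
                "subject %s: missing conc_m2 treated as 0", row["subject_id"]
            )
            conc = 0.0
        records.append(
            EcgRecord(
                subject_id=str(row["subject_id"]),
                study=str(row["study"]),
                arm=str(row["arm"]),
                t_weeks=float(row["t_weeks"]),
                ctime_h=float(row["ctime_h"]),
                occasion_id=str(row["occasion_id"]),
                replicate=int(row["replicate"]),
                hr_bpm=float(row["hr_bpm"]),
                qt_ms=float(row["qt_ms"]) if "qt_ms" in row and pd.notna(row["qt_ms"]) else math.nan,
                conc_m2=float(conc),
                assessment=str(row["assessment"]) if "assessment" in row and pd.notna(row.get("assessment")) else "predose",
            )
        )
    subjects = []
    have_cov = all(c in df.columns for c in ("age_y", "weight_kg", "albumin_gL", "ttp_mgit_h"))
    for sid, grp in df.groupby("subject_id", sort=False):
        first = grp.iloc[0]
        prof = SubjectProfile(
            subject_id=str(sid), study=str(first["study"]), arm=str(first["arm"])
        )
        if have_cov:
            prof.age_y = float(first["age_y"])
            prof.weight_kg = float(first["weight_kg"])
            prof.albumin_gL = float(first["albumin_gL"])
            prof.ttp_mgit_h = float(first["ttp_mgit_h"])
            if "sex" in df.columns and pd.notna(first.get("sex")):
                prof.sex = str(first["sex"])
            if "hiv" in df.columns and pd.notna(first.get("hiv")):
                prof.hiv = bool(first["hiv"])
        subjects.append(prof)
    validate_records(records)
    return records, subjects


def as_frame(data, subjects=None) -> pd.DataFrame:
    """Coerce a record list or a DataFrame to the canonical long table."""
    if isinstance(data, pd.DataFrame):
        return data
    return records_to_frame(data, subjects)


def read_ecg_table(
    path,
    dialect: Mapping[str, str] | None = None,
    sep: str = ",",
) -> tuple[list[EcgRecord], list[SubjectProfile]]:
    """Read a delimiter-separated ECG table.

    Parameters
    ----------
    path
        File location.
    dialect
        Optional mapping ``canonical column -> file column`` absorbing
        alternative headings.
    sep
        Field delimiter (default comma).

    Returns validated records and the subject profiles recoverable from the
    covariate columns (minimal profiles when covariates are absent).
    """
    df = pd.read_csv(path, sep=sep)
    if dialect:
        rename = {v: k for k, v in dialect.items()}
        df = df.rename(columns=rename)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    return frame_to_records(df)


def write_ecg_table(
    records: Iterable[EcgRecord],
    path,
    subjects: Iterable[SubjectProfile] | None = None,
    sep: str = ",",
) -> None:
    """Write records (plus optional covariates) as a delimited text table.

    Numeric fields are written at full precision so that
    ``read_ecg_table(write_ecg_table(x)) == x`` field-by-field.
    """
    records = list(records)
    validate_records(records)
    df = records_to_frame(records, subjects)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


@dataclass
class AnalysisConfig:
    """Run-level configuration: seed, design, estimation and binning choices."""

    seed: int = 0
    design: dict = field(default_factory=dict)
    estimation: dict = field(
        default_factory=lambda: {"inner_tol": 1e-6, "outer_tol": 1e-4, "max_iter": 200}
    )
    bin_scheme: str = "default"
    correction_method: str = "tbt"

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def configure_logging(level: int = logging.INFO) -> None:
    """Route package logs to stderr with the given level."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)
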