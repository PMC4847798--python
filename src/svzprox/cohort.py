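"""Cohort assembly: clinical records, endpoint construction, dichotomization.

Merges clinical covariates with per-patient tumor geometry and produces the
binary analysis table used by the survival workflow. Dichotomization
boundaries follow the study conventions: age ≥40 years, KPS <80, tumor
volume ≥60 cm³ and centroid–ventricle distance CS ≤30 mm, each with the
boundary value assigned to the group named by the label (age 40 → ≥40;
KPS 80 → ≥80; volume 60 → ≥60; CS 30 mm → ≤30).

Endpoints: overall survival (OS) runs from primary surgery to death or last
contact; progression-free survival (PFS) runs to progression, and a death
without observed progression censors PFS at the date of death.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

__all__ = [
    "Thresholds",
    "PatientRecord",
    "AnalysisRow",
    "CohortSplit",
    "CovariateMissingError",
    "EndpointError",
    "COVARIATE_COLUMNS",
    "CLINICAL_COLUMNS",
    "build_endpoints",
    "dichotomize",
    "split_cohorts",
    "load_clinical",
    "build_analysis_table",
    "rows_to_frame",
    "follow_up_summary",
]

#: Binary covariates of the analysis table, in report order.
COVARIATE_COLUMNS = [
    "age_ge40",
    "male",
    "kps_lt80",
    "volume_ge60",
    "cs_le30",
    "frontal_horn_vs_others",
    "less_than_gtr",
    "radiation",
    "chemotherapy",
]

#: Required columns of a clinical table (CSV or XLSX).
CLINICAL_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "kps",
    "extent_of_resection",
    "radiation",
    "chemotherapy",
    "os_days",
    "os_event",
    "pfs_days",
    "pfs_event",
]


class CovariateMissingError(ValueError):
    """A required covariate is missing; carries the offending field names."""

    def __init__(self, patient_id: str, missing: list[str]):
        self.patient_id = patient_id
        self.missing = missing
        super().__init__(f"patient {patient_id}: missing {', '.join(missing)}")


class EndpointError(ValueError):
    """Invalid endpoint data (negative durations, PFS after OS, ...)."""


@dataclass(frozen=True)
class Thresholds:
    """Dichotomization cut points (defaults are the study conventions)."""

    age_years: float = 40.0
    kps: float = 80.0
    volume_cm3: float = 60.0
    cs_mm: float = 30.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"threshold {f.name} must be positive")


@dataclass(frozen=True)
class PatientRecord:
    """Clinical covariates plus OS/PFS time-and-event pairs for one patient."""

    patient_id: str
    age: float | None
    sex: str | None  # "male" | "female"
    kps: float | None
    extent_of_resection: str | None  # "GTR" | "<GTR"
    radiation: bool | None
    chemotherapy: bool | None
    os_days: float
    os_event: bool
    pfs_days: float
    pfs_event: bool

    @classmethod
    def from_mapping(cls, row: dict) -> "PatientRecord":
        def _opt(key, cast=float):
            v = row.get(key)
            if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
                return None
            return cast(v)

        return cls(
            patient_id=str(row["patient_id"]),
            age=_opt("age"),
            sex=_opt("sex", lambda s: str(s).strip().lower()),
            kps=_opt("kps"),
            extent_of_resection=_opt("extent_of_resection", lambda s: str(s).strip()),
            radiation=_opt("radiation", lambda v: bool(int(v))),
            chemotherapy=_opt("chemotherapy", lambda v: bool(int(v))),
            os_days=float(row["os_days"]),
            os_event=bool(int(row["os_event"])),
            pfs_days=float(row["pfs_days"]),
            pfs_event=bool(int(row["pfs_event"])),
        )


@dataclass(frozen=True)
class AnalysisRow:
    """One patient's binary covariates, cohort flag, and endpoints.

    ``cs_le30`` and ``frontal_horn_vs_others`` are defined only for
    SVZ-involved (contacting) tumors and are ``None`` otherwise.
    """

    patient_id: str
    age_ge40: int
    male: int
    kps_lt80: int
    volume_ge60: int
    less_than_gtr: int
    radiation: int
    chemotherapy: int
    svz_involved: int
    cs_le30: int | None
    frontal_horn_vs_others: int | None
    os_days: float
    os_event: int
    pfs_days: float
    pfs_event: int
    volume_cm3: float = field(default=float("nan"))
    cs_mm: float = field(default=float("nan"))
    ts_mm: float = field(default=float("nan"))
    dominant_region: str = "none"


def build_endpoints(record: PatientRecord) -> dict[str, tuple[float, int]]:
    """Validated (time, event) pairs for OS and PFS.

    PFS is censored at the date of death when death precedes progression, so
    ``pfs_days <= os_days`` always, and a death without progression must carry
    ``pfs_days == os_days``.
    """
    if record.os_days < 0 or record.pfs_days < 0:
        raise EndpointError(f"patient {record.patient_id}: negative duration")
    if record.pfs_days > record.os_days:
        raise EndpointError(
            f"patient {record.patient_id}: pfs_days {record.pfs_days} exceeds "
            f"os_days {record.os_days}"
        )
    if record.os_event and not record.pfs_event and record.pfs_days != record.os_days:
        raise EndpointError(
            f"patient {record.patient_id}: death without progression must censor "
            "PFS at the date of death"
        )
    return {
        "os": (record.os_days, int(record.os_event)),
        "pfs": (record.pfs_days, int(record.pfs_event)),
    }


def dichotomize(record: PatientRecord, geometry, thresholds: Thresholds | None = None) -> AnalysisRow:
    """Merge one clinical record with its tumor geometry into an AnalysisRow.

    Raises :class:`CovariateMissingError` listing every absent clinical field
    so callers can exclude the patient listwise with a logged reason.
    """
    th = thresholds or Thresholds()
    missing = [
        name
        for name in ("age", "sex", "kps", "extent_of_resection", "radiation", "chemotherapy")
        if getattr(record, name) is None
    ]
    if missing:
        raise CovariateMissingError(record.patient_id, missing)
    endpoints = build_endpoints(record)
    involved = int(geometry.contact)
    return AnalysisRow(
        patient_id=record.patient_id,
        age_ge40=int(record.age >= th.age_years),
        male=int(record.sex == "male"),
        kps_lt80=int(record.kps < th.kps),
        volume_ge60=int(geometry.volume_cm3 >= th.volume_cm3),
        less_than_gtr=int(record.extent_of_resection != "GTR"),
        radiation=int(record.radiation),
        chemotherapy=int(record.chemotherapy),
        svz_involved=involved,
        cs_le30=int(geometry.cs_mm <= th.cs_mm) if involved else None,
        frontal_horn_vs_others=(
            int(geometry.dominant_region == "frontal_horn") if involved else None
        ),
        os_days=endpoints["os"][0],
        os_event=endpoints["os"][1],
        pfs_days=endpoints["pfs"][0],
        pfs_event=endpoints["pfs"][1],
        volume_cm3=float(geometry.volume_cm3),
        cs_mm=float(geometry.cs_mm),
        ts_mm=float(geometry.ts_mm),
        dominant_region=geometry.dominant_region or "none",
    )


@dataclass(frozen=True)
class CohortSplit:
    """Partition of the cohort by SVZ involvement; counts are conserved."""

    all_patients: pd.DataFrame
    involved: pd.DataFrame
    non_involved: pd.DataFrame

    @property
    def counts(self) -> dict[str, int]:
        return {
            "all": len(self.all_patients),
            "involved": len(self.involved),
            "non_involved": len(self.non_involved),
        }


def rows_to_frame(rows: list[AnalysisRow]) -> pd.DataFrame:
    frame = pd.DataFrame([vars(r) for r in rows])
    return frame.sort_values("patient_id", kind="stable").reset_index(drop=True)


def split_cohorts(rows: list[AnalysisRow] | pd.DataFrame) -> CohortSplit:
    """Split the analysis table into all / SVZ-involved / non-involved."""
    frame = rows if isinstance(rows, pd.DataFrame) else rows_to_frame(rows)
    if len(frame) == 0:
        raise ValueError("empty analysis table")
    involved = frame[frame["svz_involved"] == 1].reset_index(drop=True)
    non_involved = frame[frame["svz_involved"] == 0].reset_index(drop=True)
    return CohortSplit(frame.reset_index(drop=True), involved, non_involved)


def load_clinical(path: str | os.PathLike) -> pd.DataFrame:
    """Load a clinical table (CSV, or XLSX such as a deposited minimal data set)."""
    path = os.fspath(path)
    if path.endswith((".xlsx", ".xls")):
        frame = pd.read_excel(path)
    else:
        frame = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    return frame


def build_analysis_table(
    clinical: pd.DataFrame,
    geometry: dict[str, "object"] | pd.DataFrame,
    thresholds: Thresholds | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Assemble AnalysisRows for every patient present in both inputs.

    ``geometry`` maps patient_id → :class:`~svzprox.geometry.TumorGeometry`,
    or is a geometry CSV frame as written by the pipeline. Returns the tidy
    analysis table plus a list of per-patient exclusion records
    (``{"patient_id", "reason"}``); included + excluded covers every clinical
    row.
    """
    from .geometry import TumorGeometry  # local import to avoid cycle

    if isinstance(geometry, pd.DataFrame):
        geo_map = {}
        for _, g in geometry.iterrows():
            dom = g.get("dominant_region", "none")
            geo_map[str(g["patient_id"])] = TumorGeometry(
                volume_cm3=float(g["volume_cm3"]),
                centroid_mm=np.array(
                    [g["centroid_x_mm"], g["centroid_y_mm"], g["centroid_z_mm"]]
                ),
                contact=bool(g["contact"]),
                ts_mm=float(g["ts_mm"]),
                cs_mm=float(g["cs_mm"]),
                dominant_region=None if dom in ("none", None) else str(dom),
            )
    else:
        geo_map = dict(geometry)

    rows: list[AnalysisRow] = []
    exclusions: list[dict] = []
    for _, raw in clinical.iterrows():
        pid = str(raw["patient_id"])
        try:
            record = PatientRecord.from_mapping(raw.to_dict())
            geo = geo_map.get(pid)
            if geo is None:
                raise KeyError(f"patient {pid}: no geometry available")
            rows.append(dichotomize(record, geo, thresholds))
        except (CovariateMissingError, EndpointError, KeyError, ValueError) as exc:
            exclusions.append({"patient_id": pid, "reason": str(exc)})
    return rows_to_frame(rows) if rows else pd.DataFrame(), exclusions


def follow_up_summary(frame: pd.DataFrame) -> dict[str, float]:
    """Event counts and median follow-up among patients alive at last contact."""
    alive = frame.loc[frame["os_event"] == 0, "os_days"]
    return {
        "n": int(len(frame)),
        "deaths": int(frame["os_event"].sum()),
        "progressions": int(frame["pfs_event"].sum()),
        "median_follow_up_days_alive": float(alive.median()) if len(alive) else float("nan"),
    }
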