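"""Patient cohort table: domain types, gold-standard labelling, CSV I/O.

Left-sided breast irradiation can be delivered with the patient supine or
prone; which position spares the left anterior descending coronary artery
(LAD) better varies from patient to patient.  The quantity that drives the
choice is the *LAD mean dose difference*: mean LAD dose in the supine plan
minus mean LAD dose in the prone plan, in Gy.  A positive difference means
the prone position is preferable (coded 0), a negative difference means the
supine position is preferable (coded 1).  This binary choice, made from full
treatment plans in both positions, is the gold standard against which
prediction models are judged.

Each patient carries four easily measurable covariates:

==========  =====================================================  =======
column      meaning                                                unit
==========  =====================================================  =======
bmi         body-mass index                                        kg/m^2
a_heart     heart area inside the field on a mid-heart supine CT   cm^2
d_median    median distance between the LAD and the chest wall     mm
ptv         planning target volume (a proxy for breast size)       cm^3
==========  =====================================================  =======

plus the two positional LAD mean doses (Gy) and, optionally, the mean heart
dose difference (Gy), which is used only for generator calibration checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

COVARIATES = ("bmi", "a_heart", "d_median", "ptv")

#: canonical CSV column order
CSV_COLUMNS = (
    "patient_id",
    "bmi",
    "a_heart",
    "d_median",
    "ptv",
    "lad_supine",
    "lad_prone",
    "dose_diff",
    "heart_diff",
    "label",
)


class CohortError(ValueError):
    """Raised for invalid patient records or malformed cohort tables."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient's anatomy covariates plus positional LAD mean doses.

    ``lad_supine``/``lad_prone`` may be ``None`` when the table supplies the
    dose difference directly; ``heart_diff`` is the optional mean heart dose
    difference (supine - prone, Gy).
    """

    patient_id: str
    bmi: float
    a_heart: float
    d_median: float
    ptv: float
    lad_supine: float | None = None
    lad_prone: float | None = None
    heart_diff: float | None = None

    def __post_init__(self) -> None:
        checks = (
            ("bmi", self.bmi, True),
            ("a_heart", self.a_heart, False),
            ("d_median", self.d_median, False),
            ("ptv", self.ptv, True),
        )
        for name, value, strict in checks:
            if not math.isfinite(value):
                raise CohortError(f"patient {self.patient_id!r}: {name} is not finite")
            if (strict and value <= 0) or (not strict and value < 0):
                bound = "> 0" if strict else ">= 0"
                raise CohortError(
                    f"patient {self.patient_id!r}: {name}={value} violates {name} {bound}"
                )
        for name in ("lad_supine", "lad_prone"):
            value = getattr(self, name)
            if value is None:
                continue
            if not math.isfinite(value) or value < 0:
                raise CohortError(
                    f"patient {self.patient_id!r}: {name}={value} must be a finite dose >= 0"
                )


def compute_dose_difference(record: PatientRecord) -> float:
    """LAD mean dose difference (supine - prone) in Gy.

    The sign carries the clinical meaning: positive favours prone, negative
    favours supine.  Raises :class:`CohortError` if either dose is missing.
    """
    if record.lad_supine is None or record.lad_prone is None:
        raise CohortError(
            f"patient {record.patient_id!r}: both positional LAD doses are required "
            "to compute the dose difference"
        )
    return record.lad_supine - record.lad_prone


def gold_standard_label(dose_diff):
    """Binary preferred-position label from the LAD mean dose difference.

    ``1`` = supine preferred (negative difference), ``0`` = prone preferred
    (positive difference).  An exact tie at 0 Gy is labelled 0 (prone) so the
    rule is deterministic.  Accepts a scalar or array; non-finite input raises.
    """
    arr = np.asarray(dose_diff, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise CohortError("dose difference must be finite to derive a label")
    label = (arr < 0).astype(int)
    return label if arr.ndim else int(label)


@dataclass(frozen=True)
class LabelledCohort:
    """Patient records plus the continuous dose difference and binary label."""

    records: tuple[PatientRecord, ...]
    dose_diff: np.ndarray
    label: np.ndarray

    def __post_init__(self) -> None:
        dd = np.asarray(self.dose_diff, dtype=float)
        lab = np.asarray(self.label, dtype=int)
        object.__setattr__(self, "dose_diff", dd)
        object.__setattr__(self, "label", lab)
        n = len(self.records)
        if dd.shape != (n,) or lab.shape != (n,):
            raise CohortError("records, dose_diff and label must have equal length")
        if n == 0:
            raise CohortError("cohort is empty")
        if not np.all(np.isfinite(dd)):
            raise CohortError("dose_diff contains non-finite values")
        if not np.all(np.isin(lab, (0, 1))):
            raise CohortError("label must be binary (0 = prone, 1 = supine)")
        for i, rec in enumerate(self.records):
            if rec.lad_supine is not None and rec.lad_prone is not None:
                expected = rec.lad_supine - rec.lad_prone
                if abs(expected - dd[i]) > 1e-9 * max(1.0, abs(expected)):
                    raise CohortError(
                        f"patient {rec.patient_id!r}: dose_diff {dd[i]} inconsistent "
                        f"with lad_supine - lad_prone = {expected}"
                    )

    @classmethod
    def from_records(cls, records: Sequence[PatientRecord]) -> "LabelledCohort":
        """Build a cohort deriving dose differences and gold-standard labels."""
        dd = np.array([compute_dose_difference(r) for r in records], dtype=float)
        return cls(tuple(records), dd, gold_standard_label(dd))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def frame(self) -> pd.DataFrame:
        """The cohort as a tidy DataFrame (one row per patient)."""
        rows = {
            "patient_id": [r.patient_id for r in self.records],
            "bmi": [r.bmi for r in self.records],
            "a_heart": [r.a_heart for r in self.records],
            "d_median": [r.d_median for r in self.records],
            "ptv": [r.ptv for r in self.records],
            "lad_supine": [r.lad_supine for r in self.records],
            "lad_prone": [r.lad_prone for r in self.records],
            "dose_diff": self.dose_diff,
            "heart_diff": [r.heart_diff for r in self.records],
            "label": self.label,
        }
        return pd.DataFrame(rows)

    def covariate_matrix(self, names: Sequence[str] = COVARIATES) -> np.ndarray:
        return np.column_stack(
            [np.array([getattr(r, name) for r in self.records], dtype=float) for name in names]
        )

    @property
    def prevalence(self) -> float:
        """Fraction of patients for whom supine is preferred (label 1)."""
        return float(np.mean(self.label))


def _resolve(columns, column_map: Mapping[str, str] | None, canonical: str) -> str | None:
    actual = canonical if column_map is None else column_map.get(canonical, canonical)
    return actual if actual in columns else None


def read_cohort_csv(path, column_map: Mapping[str, str] | None = None) -> LabelledCohort:
    """Read and validate a cohort CSV.

    ``column_map`` maps canonical names (see :data:`CSV_COLUMNS`) to the
    file's actual headers.  The dose difference is taken from a ``dose_diff``
    column when the positional doses are absent; labels are derived via
    :func:`gold_standard_label` unless a ``label`` column is supplied.  Rows
    violating record invariants are reported with their file row numbers
    (header = row 1).
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise CohortError(f"{path}: empty CSV") from exc
    if df.empty:
        raise CohortError(f"{path}: no data rows")

    cols = {c: _resolve(df.columns, column_map, c) for c in CSV_COLUMNS}
    missing = [c for c in COVARIATES if cols[c] is None]
    if missing:
        raise CohortError(f"{path}: missing required column(s) {missing}")
    have_doses = cols["lad_supine"] is not None and cols["lad_prone"] is not None
    if not have_doses and cols["dose_diff"] is None:
        raise CohortError(
            f"{path}: need either both lad_supine/lad_prone columns or a dose_diff column"
        )

    def numeric(canonical: str) -> np.ndarray | None:
        actual = cols[canonical]
        if actual is None:
            return None
        values = pd.to_numeric(df[actual], errors="coerce").to_numpy(dtype=float)
        bad = np.nonzero(~np.isfinite(values) & df[actual].notna().to_numpy())[0]
        if bad.size:
            raise CohortError(
                f"{path}: non-numeric value(s) in column {actual!r} at row(s) "
                f"{[int(i) + 2 for i in bad]}"
            )
        return values

    data = {c: numeric(c) for c in CSV_COLUMNS if c != "patient_id"}
    if cols["patient_id"] is not None:
        ids = df[cols["patient_id"]].astype(str).tolist()
    else:
        ids = [f"P{i + 1:04d}" for i in range(len(df))]

    records, errors = [], []
    for i in range(len(df)):
        def field(c):
            v = data[c]
            if v is None or not math.isfinite(v[i]):
                return None
            return float(v[i])

        try:
            records.append(
                PatientRecord(
                    patient_id=ids[i],
                    bmi=float(data["bmi"][i]),
                    a_heart=float(data["a_heart"][i]),
                    d_median=float(data["d_median"][i]),
                    ptv=float(data["ptv"][i]),
                    lad_supine=field("lad_supine"),
                    lad_prone=field("lad_prone"),
                    heart_diff=field("heart_diff"),
                )
            )
        except CohortError as exc:
            errors.append(f"row {i + 2}: {exc}")
    if errors:
        raise CohortError(f"{path}: invalid rows -- " + "; ".join(errors))

    if have_doses and np.all(np.isfinite(data["lad_supine"])) and np.all(
        np.isfinite(data["lad_prone"])
    ):
        dd = np.array([compute_dose_difference(r) for r in records])
    elif data["dose_diff"] is not None and np.all(np.isfinite(data["dose_diff"])):
        dd = data["dose_diff"]
    else:
        raise CohortError(f"{path}: dose columns contain missing values")

    if data["label"] is not None:
        label = data["label"].astype(int)
        if not np.all(np.isin(label, (0, 1))):
            raise CohortError(f"{path}: label column must be binary")
    else:
        label = gold_standard_label(dd)
    return LabelledCohort(tuple(records), dd, label)


def write_cohort_csv(cohort: LabelledCohort, path) -> None:
    """Write a cohort in the canonical CSV layout (full float precision)."""
    cohort.frame.to_csv(path, index=False)
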