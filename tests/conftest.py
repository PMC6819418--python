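"""Shared fixtures: hand-built and generated cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from posedca.cohort import LabelledCohort, PatientRecord
from posedca.synthetic import default_calibrated_config, generate_cohort


def make_cohort(columns: dict | None = None, label=None, dose_diff=None) -> LabelledCohort:
    """Build a cohort from raw covariate arrays without positional doses.

    ``dose_diff`` defaults to -1 Gy for label 1 and +1 Gy for label 0 so the
    gold-standard rule is always respected.
    """
    columns = columns or {}
    if label is None and dose_diff is None:
        raise ValueError("need label or dose_diff")
    if dose_diff is None:
        dose_diff = np.where(np.asarray(label) == 1, -1.0, 1.0)
    dose_diff = np.asarray(dose_diff, dtype=float)
    if label is None:
        label = (dose_diff < 0).astype(int)
    n = len(dose_diff)

    def col(name, default):
        return np.asarray(columns.get(name, np.full(n, default)), dtype=float)

    bmi = col("bmi", 25.0)
    a_heart = col("a_heart", 5.0)
    d_median = col("d_median", 15.0)
    ptv = col("ptv", 900.0)
    records = tuple(
        PatientRecord(
            patient_id=f"T{i + 1:04d}",
            bmi=bmi[i],
            a_heart=a_heart[i],
            d_median=d_median[i],
            ptv=ptv[i],
        )
        for i in range(n)
    )
    return LabelledCohort(records, dose_diff, np.asarray(label, dtype=int))


@pytest.fixture(scope="session")
def default_cohort_138() -> LabelledCohort:
    return generate_cohort(default_calibrated_config(n=138), seed=20)


@pytest.fixture(scope="session")
def default_cohort_5000() -> LabelledCohort:
    return generate_cohort(default_calibrated_config(n=5000), seed=21)


@pytest.fixture()
def tiny_records() -> list[PatientRecord]:
    return [
        PatientRecord("A", bmi=22.0, a_heart=3.0, d_median=20.0, ptv=700.0,
                      lad_supine=10.0, lad_prone=3.0),
        PatientRecord("B", bmi=31.0, a_heart=9.0, d_median=8.0, ptv=1200.0,
                      lad_supine=2.5, lad_prone=2.5),
        PatientRecord("C", bmi=27.0, a_heart=1.0, d_median=25.0, ptv=800.0,
                      lad_supine=1.2, lad_prone=4.0),
    ]
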