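"""Long-format visit table: in-memory containers, CSV round trip, validation.

The whole pipeline exchanges one currency: a cohort of per-patient ordered
visit series.  Each visit carries demographics, a set of binary
clinical/laboratory/treatment flags (the codebook), a binarized
disease-activity flag (SLEDAI-2K = 0 vs >= 1) and the cumulative SLICC/ACR
damage index (SDI).  Because chronic damage is by definition irreversible,
SDI must never decrease within a patient's history; that and the other
structural invariants are enforced here once so downstream stages can assume
clean input.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError

#: Fixed leading / trailing columns of the visit CSV; the binary-feature
#: codebook occupies the columns between ``sex`` and ``activity_flag``.
LEADING_COLUMNS = ("patient_id", "month_index", "age_years", "sex")
TRAILING_COLUMNS = ("activity_flag", "sdi_score")

VALID_SEX = ("M", "F")


@dataclass
class VisitRecord:
    """One clinic visit of one patient."""

    patient_id: str
    month_index: float  # months since the patient's first visit
    age_years: float
    sex: str  # 'M' or 'F', constant within a patient
    feature_flags: dict[str, int]  # codebook name -> {0, 1}
    activity_flag: int  # SLEDAI-2K binarized: 0 inactive, 1 any activity
    sdi_score: int  # cumulative damage index, non-negative


@dataclass
class PatientSeries:
    """Chronologically ordered visits of a single patient.

    Invariants (checked by :func:`validate_cohort`): month_index strictly
    increasing and starting at 0, sdi_score non-decreasing, sex constant.
    """

    patient_id: str
    visits: list[VisitRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.visits)

    @property
    def months(self) -> np.ndarray:
        return np.array([v.month_index for v in self.visits], dtype=float)

    @property
    def sdi(self) -> np.ndarray:
        return np.array([v.sdi_score for v in self.visits], dtype=int)

    def feature_matrix(self, codebook: Iterable[str]) -> np.ndarray:
        """T x len(codebook) matrix of the binary flags, in codebook order."""
        names = list(codebook)
        return np.array(
            [[v.feature_flags[name] for name in names] for v in self.visits],
            dtype=float,
        )


@dataclass
class CohortTable:
    """A cohort: list of patient series plus the ordered feature codebook."""

    patients: list[PatientSeries]
    codebook: list[str]

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def n_visits(self) -> int:
        return sum(len(p) for p in self.patients)

    def columns(self) -> list[str]:
        return list(LEADING_COLUMNS) + self.codebook + list(TRAILING_COLUMNS)


@dataclass
class Violation:
    """A single cohort-invariant violation, locatable for reporting."""

    kind: str  # e.g. 'sdi_decrease', 'unsorted_visits', 'duplicate_id'
    patient_id: str
    detail: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.kind}] patient {self.patient_id}: {self.detail}"


def _to_dataframe(cohort: CohortTable) -> pd.DataFrame:
    rows = []
    for series in cohort.patients:
        for v in series.visits:
            row = {
                "patient_id": v.patient_id,
                "month_index": v.month_index,
                "age_years": v.age_years,
                "sex": v.sex,
                **{name: v.feature_flags[name] for name in cohort.codebook},
                "activity_flag": v.activity_flag,
                "sdi_score": v.sdi_score,
            }
            rows.append(row)
    df = pd.DataFrame(rows, columns=cohort.columns())
    if not df.empty:
        df = df.sort_values(["patient_id", "month_index"], kind="stable")
    return df


def write_visits_csv(cohort: CohortTable, path) -> None:
    """Write one row per visit; deterministic row and column order."""
    df = _to_dataframe(cohort)
    df.to_csv(path, index=False)


def to_csv_string(cohort: CohortTable) -> str:
    buf = io.StringIO()
    write_visits_csv(cohort, buf)
    return buf.getvalue()


def read_visits_csv(path) -> CohortTable:
    """Read a visit CSV, infer the codebook from the header, and validate.

    Raises
    ------
    SchemaError
        if a required column is missing or the codebook region is empty
        while flag columns are expected.
    DataError
        on non-binary flag values or any cohort-invariant violation.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "sex": str})
    cols = list(df.columns)
    for required in LEADING_COLUMNS + TRAILING_COLUMNS:
        if required not in cols:
            raise SchemaError(f"missing required column '{required}'")
    try:
        lo = cols.index("sex") + 1
        hi = cols.index("activity_flag")
    except ValueError as exc:  # pragma: no cover - guarded above
        raise SchemaError(str(exc)) from exc
    codebook = cols[lo:hi]

    for col in codebook + ["activity_flag"]:
        bad = ~df[col].isin([0, 1])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(
                f"non-binary value in flag column '{col}' at data row {row}"
            )
    if (df["sdi_score"] < 0).any() or (df["sdi_score"] % 1 != 0).any():
        raise DataError("sdi_score must be a non-negative integer")

    patients: list[PatientSeries] = []
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("month_index", kind="stable")
        visits = [
            VisitRecord(
                patient_id=str(pid),
                month_index=float(r["month_index"]),
                age_years=float(r["age_years"]),
                sex=str(r["sex"]),
                feature_flags={name: int(r[name]) for name in codebook},
                activity_flag=int(r["activity_flag"]),
                sdi_score=int(r["sdi_score"]),
            )
            for _, r in grp.iterrows()
        ]
        patients.append(PatientSeries(patient_id=str(pid), visits=visits))
    cohort = CohortTable(patients=patients, codebook=codebook)
    violations = validate_cohort(cohort)
    if violations:
        raise DataError(
            "invalid cohort: " + "; ".join(str(v) for v in violations[:5])
        )
    return cohort


def validate_cohort(cohort: CohortTable) -> list[Violation]:
    """Collect every invariant violation; an empty list means valid.

    Violations are returned as data rather than raised so that callers can
    report all problems in a file at once (the ``validate`` CLI subcommand).
    """
    out: list[Violation] = []
    seen: set[str] = set()
    codebook = set(cohort.codebook)
    for series in cohort.patients:
        pid = series.patient_id
        if pid in seen:
            out.append(Violation("duplicate_id", pid, "patient_id appears twice"))
        seen.add(pid)
        if not series.visits:
            out.append(Violation("empty_series", pid, "patient has no visits"))
            continue
        months = series.months
        if months[0] != 0:
            out.append(
                Violation("nonzero_start", pid, f"first month_index is {months[0]}")
            )
        if np.any(np.diff(months) <= 0):
            i = int(np.flatnonzero(np.diff(months) <= 0)[0]) + 1
            out.append(
                Violation("unsorted_visits", pid, f"month_index not increasing at visit {i}")
            )
        sdi = series.sdi
        if np.any(np.diff(sdi) < 0):
            i = int(np.flatnonzero(np.diff(sdi) < 0)[0]) + 1
            out.append(
                Violation("sdi_decrease", pid, f"SDI decreases at visit {i} (damage is irreversible)")
            )
        sexes = {v.sex for v in series.visits}
        if len(sexes) > 1:
            out.append(Violation("sex_change", pid, "sex not constant across visits"))
        elif sexes - set(VALID_SEX):
            out.append(Violation("bad_sex", pid, f"sex value {sexes}"))
        for i, v in enumerate(series.visits):
            if set(v.feature_flags) != codebook:
                out.append(
                    Violation("codebook_mismatch", pid, f"visit {i} flags do not match codebook")
                )
                break
    return out
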