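"""Case/control eligibility, the rare-feature filter, and feature encoding.

Eligibility rules
-----------------
*Cases* are patients free of damage at their first visit (SDI = 0) who later
accrue damage (SDI >= 1); the model sees every visit strictly before the
first damaged visit, labelled 1.  Patients already damaged at baseline are
excluded outright.

*Controls* are patients with SDI = 0 at every visit, at least ``min_visits``
visits, and enough damage-free follow-up that a prefix of visits remains
after reserving the final ``min_horizon_months`` (24 by default) as the
label-confirming window.  Only the prefix feeds the model, labelled 0, so a
control label carries the same semantics as a case label: "no damage in the
next two years" was actually observed.

Damage-free patients with too few visits or too short a horizon are in
neither group — a short quiet history is not evidence of a negative patient.

Binary features positive in fewer than four patients across the whole study
sample are discarded before modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort_io import CohortTable, PatientSeries
from .errors import ConfigurationError, DataError, SchemaError


@dataclass
class LabeledSequence:
    """Encoded model input: T x p feature matrix plus a binary label."""

    patient_id: str
    features: np.ndarray  # (T, p) float
    label: int  # 1 = damage within the 2-year horizon

    @property
    def length(self) -> int:
        return self.features.shape[0]


@dataclass
class ModelDataset:
    """Labeled sequences plus the retained feature names and encoding metadata.

    ``metadata['age_index']`` locates the (raw) age column; the age scaling
    parameters fitted at encode time are stored alongside so they can be
    re-fitted on a training fold only during cross-validation.
    """

    sequences: list[LabeledSequence]
    feature_names: list[str]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.sequences], dtype=int)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


def _first_damage_index(series: PatientSeries) -> int | None:
    sdi = series.sdi
    pos = np.flatnonzero(sdi >= 1)
    return int(pos[0]) if pos.size else None


def select_cases(cohort: CohortTable) -> list[tuple[PatientSeries, list]]:
    """Damage developers with clean baselines; prefix ends before damage.

    Returns ``(patient, visit_prefix)`` pairs, label 1 implied.
    """
    out = []
    for series in cohort.patients:
        if not series.visits or series.visits[0].sdi_score >= 1:
            continue  # damaged at baseline: excluded from the study entirely
        idx = _first_damage_index(series)
        if idx is None:
            continue
        prefix = series.visits[:idx]
        if prefix:
            out.append((series, prefix))
    return out


def select_controls(
    cohort: CohortTable,
    min_visits: int = 5,
    min_horizon_months: float = 24.0,
) -> list[tuple[PatientSeries, list]]:
    """Persistently damage-free patients with a confirmed 2-year horizon.

    The final ``min_horizon_months`` of follow-up are reserved as the
    damage-free confirmation window; the returned prefix excludes it.
    """
    out = []
    for series in cohort.patients:
        if not series.visits:
            continue
        if np.any(series.sdi >= 1):
            continue
        if len(series) < min_visits:
            continue
        last_month = series.visits[-1].month_index
        cutoff = last_month - min_horizon_months
        prefix = [v for v in series.visits if v.month_index <= cutoff]
        if prefix:
            out.append((series, prefix))
    return out


def encode_features(
    selections: list[tuple[PatientSeries, list, int]],
    codebook: list[str],
    standardize_age: bool = True,
) -> ModelDataset:
    """Turn (patient, visit_prefix, label) triples into model-ready matrices.

    Column order: codebook binary flags, activity flag, sex (M=1), age.
    Binary flags and the activity flag pass through as 0/1.  Age is kept raw
    in the matrices; the standardization parameters fitted over all visits
    here are stored in metadata, and :func:`standardize_ages` applies them
    (cross-validation re-fits them on each training fold to avoid leakage).
    """
    if not selections:
        raise DataError("no selections to encode")
    names = list(codebook) + ["activity_flag", "sex_male", "age_years"]
    age_index = len(names) - 1
    sequences = []
    for series, prefix, label in selections:
        rows = []
        for v in prefix:
            try:
                flags = [float(v.feature_flags[name]) for name in codebook]
            except KeyError as exc:
                raise SchemaError(f"unknown feature in codebook: {exc}") from exc
            rows.append(
                flags
                + [float(v.activity_flag), 1.0 if v.sex == "M" else 0.0, float(v.age_years)]
            )
        sequences.append(
            LabeledSequence(
                patient_id=series.patient_id,
                features=np.asarray(rows, dtype=float),
                label=int(label),
            )
        )
    dataset = ModelDataset(sequences=sequences, feature_names=names,
                           metadata={"age_index": age_index})
    if standardize_age:
        mean, sd = fit_age_scaler(dataset.sequences, age_index)
        dataset.metadata["age_mean"] = mean
        dataset.metadata["age_sd"] = sd
    return dataset


def fit_age_scaler(sequences: list[LabeledSequence], age_index: int) -> tuple[float, float]:
    """Mean and SD of age pooled over every visit of the given sequences."""
    ages = np.concatenate([s.features[:, age_index] for s in sequences])
    sd = float(ages.std(ddof=0))
    return float(ages.mean()), (sd if sd > 0 else 1.0)


def standardize_ages(
    sequences: list[LabeledSequence], age_index: int, mean: float, sd: float
) -> list[LabeledSequence]:
    """Return copies with the age column standardized by (mean, sd)."""
    out = []
    for s in sequences:
        X = s.features.copy()
        X[:, age_index] = (X[:, age_index] - mean) / sd
        out.append(LabeledSequence(s.patient_id, X, s.label))
    return out


def build_dataset(
    cohort: CohortTable,
    min_visits: int = 5,
    min_horizon_months: float = 24.0,
    min_positive: int = 4,
) -> ModelDataset:
    """Full selection pipeline: cases + controls, encode, drop rare features."""
    cases = select_cases(cohort)
    controls = select_controls(cohort, min_visits, min_horizon_months)
    selections = [(s, p, 1) for s, p in cases] + [(s, p, 0) for s, p in controls]
    if not selections:
        raise DataError("selection produced no eligible patients")
    dataset = encode_features(selections, cohort.codebook)
    return filter_rare_binary_features(dataset, min_positive=min_positive)


def filter_rare_binary_features(
    dataset: ModelDataset, min_positive: int = 4, per_visit: bool = False
) -> ModelDataset:
    """Drop binary features with fewer than ``min_positive`` positive patients.

    A patient counts as positive for a feature if the flag is 1 at any of
    their visits (ever-positive); ``per_visit=True`` counts visits instead.
    Non-binary columns (age) are always retained.  Feature order is
    preserved; the operation is idempotent.
    """
    if not dataset.sequences:
        raise DataError("empty dataset")
    if min_positive < 0:
        raise ConfigurationError("min_positive must be >= 0")
    p = dataset.n_features
    keep = np.ones(p, dtype=bool)
    for j in range(p):
        col = [s.features[:, j] for s in dataset.sequences]
        values = np.concatenate(col)
        if not np.isin(values, (0.0, 1.0)).all():
            continue  # not binary: never dropped by this rule
        if per_visit:
            count = int(values.sum())
        else:
            count = int(sum(bool(c.any()) for c in col))
        if count < min_positive:
            keep[j] = False
    if not keep.any():
        raise DataError("rare-feature filter removed every feature")
    names = [n for n, k in zip(dataset.feature_names, keep) if k]
    sequences = [
        LabeledSequence(s.patient_id, s.features[:, keep], s.label)
        for s in dataset.sequences
    ]
    metadata = dict(dataset.metadata)
    if "age_index" in metadata:
        old = metadata["age_index"]
        if keep[old]:
            metadata["age_index"] = int(keep[:old].sum())
        else:  # pragma: no cover - age is never binary, hence never dropped
            del metadata["age_index"]
    return ModelDataset(sequences=sequences, feature_names=names, metadata=metadata)
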