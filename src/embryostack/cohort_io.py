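"""Cohort file format, feature schema, and design-matrix encoding.

The cohort is a per-transfer table: one row per transfer event carrying the
patient's clinical features, the morphology features of the one (SET) or two
(DET) embryos transferred, and the observed implantation count.  Nineteen
features — sixteen patient-level and three per-embryo morphology grades —
form the selected-feature set used throughout the modelling pipeline.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import CohortParseError

__all__ = [
    "PATIENT_FEATURES",
    "EMBRYO_FEATURES",
    "SELECTED_FEATURES",
    "FEATURE_KINDS",
    "FeatureSchema",
    "PatientRecord",
    "EmbryoRecord",
    "TransferRecord",
    "read_cohort",
    "write_cohort",
    "records_to_frame",
    "frame_to_records",
    "encode_features",
    "decode_categoricals",
    "reselect_features",
]

# The 16 patient-level selected features, in canonical column order.
PATIENT_FEATURES: tuple[str, ...] = (
    "age",
    "attempt_times_ivf",
    "antral_follicle_count",
    "fsh",
    "lh",
    "e2_hcg_day",
    "endometrial_thickness",
    "mii",
    "two_pn",
    "oocyte_number",
    "two_pn_mii_ratio",
    "agonist_protocol",
    "endometrial_type_a",
    "endometrial_type_c",
    "secondary_infertility",
    "icsi",
)

# Per-embryo day-3 morphology grades.
EMBRYO_FEATURES: tuple[str, ...] = ("blastomere_number", "fragment", "equality")

SELECTED_FEATURES: tuple[str, ...] = PATIENT_FEATURES + EMBRYO_FEATURES

FeatureKind = Literal["continuous", "ordinal", "binary", "categorical"]

FEATURE_KINDS: dict[str, FeatureKind] = {
    "age": "continuous",
    "attempt_times_ivf": "ordinal",
    "antral_follicle_count": "continuous",
    "fsh": "continuous",
    "lh": "continuous",
    "e2_hcg_day": "continuous",
    "endometrial_thickness": "continuous",
    "mii": "ordinal",
    "two_pn": "ordinal",
    "oocyte_number": "ordinal",
    "two_pn_mii_ratio": "continuous",
    "agonist_protocol": "binary",
    "endometrial_type_a": "binary",
    "endometrial_type_c": "binary",
    "secondary_infertility": "binary",
    "icsi": "binary",
    "blastomere_number": "ordinal",
    "fragment": "ordinal",
    "equality": "ordinal",
}

META_COLUMNS = ("patient_id", "transfer_type", "implantation_count")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature names, their kinds, and the selected subsets.

    ``categorical_levels`` maps each categorical feature to its ordered level
    labels; the 19 selected features are all numeric, binary or ordinal, so
    the default schema has none, but the encoder supports them for extended
    cohorts.
    """

    features: tuple[str, ...] = SELECTED_FEATURES
    kinds: dict[str, FeatureKind] = field(default_factory=lambda: dict(FEATURE_KINDS))
    categorical_levels: dict[str, tuple[str, ...]] = field(default_factory=dict)
    selected: tuple[str, ...] = SELECTED_FEATURES
    patient_level: tuple[str, ...] = PATIENT_FEATURES
    embryo_level: tuple[str, ...] = EMBRYO_FEATURES

    def __post_init__(self) -> None:
        unknown = set(self.selected) - set(self.features)
        if unknown:
            raise ValueError(f"selected features not in schema: {sorted(unknown)}")
        for name in self.features:
            if name not in self.kinds:
                raise ValueError(f"feature without a kind: {name}")
            if self.kinds[name] == "categorical" and name not in self.categorical_levels:
                raise ValueError(f"categorical feature without levels: {name}")


DEFAULT_SCHEMA = FeatureSchema()


@dataclass
class PatientRecord:
    """Clinical features of one patient (the 16 patient-level features)."""

    features: dict[str, float]

    def __getitem__(self, name: str) -> float:
        return self.features[name]


@dataclass
class EmbryoRecord:
    """Morphology grades of one embryo, plus its score once predicted."""

    embryo_id: str
    features: dict[str, float]
    predicted_probability: float | None = None

    def __getitem__(self, name: str) -> float:
        return self.features[name]


@dataclass
class TransferRecord:
    """One transfer event: patient, one or two embryos, observed outcome."""

    patient_id: str
    patient: PatientRecord
    embryos: list[EmbryoRecord]
    transfer_type: Literal["SET", "DET"]
    implantation_count: int

    def __post_init__(self) -> None:
        n = len(self.embryos)
        if self.transfer_type == "SET":
            if n != 1 or self.implantation_count not in (0, 1):
                raise CohortParseError(
                    f"patient {self.patient_id}: SET requires 1 embryo and count in {{0,1}}, "
                    f"got {n} embryos, count {self.implantation_count}"
                )
        elif self.transfer_type == "DET":
            if n != 2 or self.implantation_count not in (0, 1, 2):
                raise CohortParseError(
                    f"patient {self.patient_id}: DET requires 2 embryos and count in {{0,1,2}}, "
                    f"got {n} embryos, count {self.implantation_count}"
                )
        else:
            raise CohortParseError(
                f"patient {self.patient_id}: unknown transfer type {self.transfer_type!r}"
            )

    @property
    def clinical_pregnancy(self) -> int:
        """1 if at least one embryo implanted (gestational sac with heartbeat)."""
        return int(self.implantation_count >= 1)

    @property
    def twin(self) -> int:
        """1 if both embryos of a DET implanted."""
        return int(self.implantation_count == 2)


def _cohort_columns(schema: FeatureSchema) -> list[str]:
    cols = list(META_COLUMNS) + list(schema.patient_level)
    for suffix in ("_1", "_2"):
        cols += [f"{name}{suffix}" for name in schema.embryo_level]
    return cols


def records_to_frame(
    records: Sequence[TransferRecord], schema: FeatureSchema = DEFAULT_SCHEMA
) -> pd.DataFrame:
    """Flatten transfer records into the canonical one-row-per-transfer table."""
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "patient_id": rec.patient_id,
            "transfer_type": rec.transfer_type,
            "implantation_count": rec.implantation_count,
        }
        for name in schema.patient_level:
            row[name] = rec.patient.features.get(name, np.nan)
        for i, suffix in enumerate(("_1", "_2")):
            embryo = rec.embryos[i] if i < len(rec.embryos) else None
            for name in schema.embryo_level:
                row[f"{name}{suffix}"] = (
                    embryo.features.get(name, np.nan) if embryo is not None else np.nan
                )
        rows.append(row)
    return pd.DataFrame(rows, columns=_cohort_columns(schema))


def frame_to_records(
    frame: pd.DataFrame, schema: FeatureSchema = DEFAULT_SCHEMA
) -> list[TransferRecord]:
    """Typed records from the canonical table; raises on structural violations."""
    expected = set(_cohort_columns(schema))
    unknown = set(frame.columns) - expected
    if unknown:
        raise CohortParseError(f"unknown column(s): {sorted(unknown)}")
    missing_cols = expected - set(frame.columns)
    if missing_cols:
        raise CohortParseError(f"missing column(s): {sorted(missing_cols)}")

    records: list[TransferRecord] = []
    for idx, row in frame.iterrows():
        ttype = row["transfer_type"]
        try:
            count = int(row["implantation_count"])
        except (TypeError, ValueError):
            raise CohortParseError(
                f"row {idx}: non-integer implantation_count {row['implantation_count']!r}"
            ) from None
        patient = PatientRecord(
            {name: _cell_to_float(row[name], idx, name) for name in schema.patient_level}
        )
        embryos = []
        n_embryos = 1 if ttype == "SET" else 2
        for i in range(n_embryos):
            suffix = f"_{i + 1}"
            feats = {
                name: _cell_to_float(row[f"{name}{suffix}"], idx, f"{name}{suffix}")
                for name in schema.embryo_level
            }
            embryos.append(EmbryoRecord(embryo_id=f"{row['patient_id']}-e{i + 1}", features=feats))
        try:
            records.append(
                TransferRecord(
                    patient_id=str(row["patient_id"]),
                    patient=patient,
                    embryos=embryos,
                    transfer_type=ttype,
                    implantation_count=count,
                )
            )
        except CohortParseError as exc:
            raise CohortParseError(f"row {idx}: {exc}") from None
    return records


def _cell_to_float(value: object, row: object, column: str) -> float:
    if value is None or (isinstance(value, str) and value.strip() == ""):
        return np.nan
    if isinstance(value, float) and np.isnan(value):
        return np.nan
    try:
        return float(value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise CohortParseError(
            f"row {row}, column {column}: non-numeric value {value!r}"
        ) from None


def read_cohort(path, schema: FeatureSchema = DEFAULT_SCHEMA) -> list[TransferRecord]:
    """Read a comma-separated cohort file into typed transfer records.

    Empty cells denote missing values; the outcome and transfer-type columns
    must never be missing.  Malformed rows are rejected with their row number.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if frame.empty:
        # header-only file
        if set(frame.columns) - set(_cohort_columns(schema)):
            raise CohortParseError(
                f"unknown column(s): {sorted(set(frame.columns) - set(_cohort_columns(schema)))}"
            )
        return []
    for col in ("transfer_type", "implantation_count"):
        blank = frame[col].str.strip() == ""
        if blank.any():
            raise CohortParseError(f"row {int(np.argmax(blank.values))}: missing {col}")
    return frame_to_records(frame, schema)


def write_cohort(records: Sequence[TransferRecord], path, schema: FeatureSchema = DEFAULT_SCHEMA) -> None:
    """Write records as comma-separated text; missing values become empty cells."""
    frame = records_to_frame(records, schema)
    buf = io.StringIO()
    frame.to_csv(buf, index=False, na_rep="")
    text = buf.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)


def encode_features(
    table: pd.DataFrame,
    schema: FeatureSchema,
    subset: Iterable[str],
    drop_reference: bool = False,
) -> pd.DataFrame:
    """Numeric design matrix for the requested feature subset.

    Continuous/ordinal features pass through unchanged; binary features are
    0/1 columns; categorical features are one-hot encoded with one column per
    level (``drop_reference=True`` drops the first level, for regression
    designs that need a full-rank matrix).  Missing values propagate as NaN —
    no imputation.  Column order depends only on the schema, never on the
    data.
    """
    subset = list(subset)
    unknown = set(subset) - set(schema.features)
    if unknown:
        raise ValueError(f"subset features not in schema: {sorted(unknown)}")
    absent = set(subset) - set(table.columns)
    if absent:
        raise ValueError(f"table lacks required feature column(s): {sorted(absent)}")

    columns: dict[str, np.ndarray] = {}
    for name in subset:
        kind = schema.kinds[name]
        values = table[name]
        if kind in ("continuous", "ordinal", "binary"):
            columns[name] = pd.to_numeric(values, errors="raise").to_numpy(dtype=float)
        else:  # categorical → one-hot, NaN rows propagate NaN in every level column
            levels = schema.categorical_levels[name]
            start = 1 if drop_reference else 0
            is_na = values.isna().to_numpy()
            for level in levels[start:]:
                col = (values == level).to_numpy(dtype=float)
                col[is_na] = np.nan
                columns[f"{name}={level}"] = col
    return pd.DataFrame(columns, index=table.index)


def decode_categoricals(
    encoded: pd.DataFrame, schema: FeatureSchema, subset: Iterable[str]
) -> pd.DataFrame:
    """Invert one-hot encoding back to level labels (round-trip check helper)."""
    out: dict[str, object] = {}
    for name in subset:
        if schema.kinds[name] != "categorical":
            out[name] = encoded[name]
            continue
        levels = schema.categorical_levels[name]
        block = encoded[[f"{name}={lv}" for lv in levels]]
        labels = np.asarray(levels, dtype=object)[block.to_numpy().argmax(axis=1)]
        labels = np.where(block.isna().any(axis=1), None, labels)
        out[name] = labels
    return pd.DataFrame(out, index=encoded.index)


def reselect_features(importance: dict[str, float], threshold: float = 0.0) -> tuple[str, ...]:
    """Importance-based feature selection: keep features with importance > threshold.

    The shipped 19-name selected set is a fixed constant; this re-runs the
    selection rule on a supplied importance map for cohorts where the fixed
    list is not wanted.
    """
    return tuple(name for name in SELECTED_FEATURES if importance.get(name, 0.0) > threshold)
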