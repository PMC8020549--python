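"""Two-level stacked implantation model.

Level 1 scores a single embryo's implantation probability from the 19
selected features (16 patient-level + 3 embryo morphology).  For a double
transfer the two embryos are scored separately (P1, P2) and two symmetric
engineered features — P1 + P2 and P1 × P2 — are appended to the 16 patient
features to form the level-2 design (width 18).  Two level-2 models are
trained on it: one for the chance of clinical pregnancy (≥ 1 implantation)
and one for twin risk (both implant).

Label attribution drives the level-1 training set: a SET embryo takes the
transfer outcome; both embryos of a DET with 0 (or 2) implantations are
labelled 0 (or 1); the two embryos of a DET with exactly one implantation are
excluded, because which of them implanted is unobservable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cohort_io import (
    DEFAULT_SCHEMA,
    EmbryoRecord,
    FeatureSchema,
    PatientRecord,
    TransferRecord,
    encode_features,
)
from .errors import EstimationError
from .learners import BinaryScorer, BoosterConfig, GradientBoostedScorer

__all__ = [
    "LEVEL2_ENGINEERED",
    "FirstLevelTable",
    "SecondLevelTable",
    "HierarchicalModel",
    "build_first_level_training",
    "train_first_level",
    "build_second_level_features",
    "train_second_level",
    "fit_hierarchical_model",
    "predict_single",
    "predict_single_batch",
    "predict_det",
    "predict_det_batch",
    "feature_importance",
    "save_model",
    "load_model",
]

LEVEL2_ENGINEERED = ("p_sum", "p_product")

LearnerFactory = Callable[[int], BinaryScorer]


def _default_factory(config: BoosterConfig) -> LearnerFactory:
    return lambda seed: GradientBoostedScorer(config).with_seed(seed)


@dataclass
class FirstLevelTable:
    """Per-embryo level-1 training table with row provenance."""

    X: pd.DataFrame  # one row per labelled embryo, the 19 selected features
    y: np.ndarray  # implantation label
    provenance: pd.DataFrame  # patient_id, embryo_id, transfer_type, implantation_count
    n_excluded: int  # embryos from one-implantation DETs, dropped


@dataclass
class SecondLevelTable:
    """Per-DET level-2 design with pregnancy and twin labels."""

    X: pd.DataFrame  # 16 patient features + p_sum + p_product
    y_pregnancy: np.ndarray
    y_twin: np.ndarray
    provenance: pd.DataFrame


def _embryo_feature_rows(
    records: Sequence[TransferRecord], schema: FeatureSchema
) -> tuple[list[dict], list[dict], list[int]]:
    """(feature rows, provenance rows, labels) applying the attribution rule."""
    rows, prov, labels = [], [], []
    for rec in records:
        if rec.transfer_type == "DET" and rec.implantation_count == 1:
            continue  # attribution unobservable
        label = rec.clinical_pregnancy if rec.transfer_type == "SET" else rec.twin
        for embryo in rec.embryos:
            rows.append({**rec.patient.features, **embryo.features})
            prov.append(
                {
                    "patient_id": rec.patient_id,
                    "embryo_id": embryo.embryo_id,
                    "transfer_type": rec.transfer_type,
                    "implantation_count": rec.implantation_count,
                }
            )
            labels.append(label)
    return rows, prov, labels


def build_first_level_training(
    records: Sequence[TransferRecord], schema: FeatureSchema = DEFAULT_SCHEMA
) -> FirstLevelTable:
    """One labelled row per embryo whose outcome is attributable.

    SET embryo → the transfer's pregnancy flag; DET with 0 implantations →
    both embryos 0; DET with 2 → both 1; DET with exactly 1 → both excluded.
    """
    rows, prov, labels = _embryo_feature_rows(records, schema)
    n_excluded = 2 * sum(
        1 for r in records if r.transfer_type == "DET" and r.implantation_count == 1
    )
    raw = pd.DataFrame(rows, columns=list(schema.selected))
    X = encode_features(raw, schema, schema.selected)
    return FirstLevelTable(
        X=X,
        y=np.asarray(labels, dtype=float),
        provenance=pd.DataFrame(
            prov, columns=["patient_id", "embryo_id", "transfer_type", "implantation_count"]
        ),
        n_excluded=n_excluded,
    )


def train_first_level(
    table: FirstLevelTable,
    config: BoosterConfig | None = None,
    learner_factory: LearnerFactory | None = None,
) -> BinaryScorer:
    """Fit the per-embryo implantation scorer on the attributed table."""
    config = config or BoosterConfig()
    factory = learner_factory or _default_factory(config)
    return factory(config.seed).fit(table.X, table.y)


def predict_single_batch(
    level1: BinaryScorer, table: pd.DataFrame, schema: FeatureSchema = DEFAULT_SCHEMA
) -> np.ndarray:
    """Implantation probabilities for a table of 19-feature embryo rows."""
    X = encode_features(table.reindex(columns=list(schema.selected)), schema, schema.selected)
    return level1.predict_proba(X)


def _single_row(
    patient: PatientRecord, embryo: EmbryoRecord, schema: FeatureSchema
) -> pd.DataFrame:
    return pd.DataFrame([{**patient.features, **embryo.features}]).reindex(
        columns=list(schema.selected)
    )


def predict_single(
    model: "HierarchicalModel | BinaryScorer",
    patient: PatientRecord,
    embryo: EmbryoRecord,
    schema: FeatureSchema = DEFAULT_SCHEMA,
) -> float:
    """Level-1 implantation probability for one embryo; tolerates missing features."""
    level1 = model.level1 if isinstance(model, HierarchicalModel) else model
    if level1 is None:
        raise EstimationError("untrained model: level1 scorer absent")
    return float(predict_single_batch(level1, _single_row(patient, embryo, schema), schema)[0])


def build_second_level_features(
    level1: BinaryScorer,
    det_records: Sequence[TransferRecord],
    schema: FeatureSchema = DEFAULT_SCHEMA,
) -> SecondLevelTable:
    """Level-2 design: 16 patient features + (P1+P2, P1×P2) per DET record.

    Only symmetric functions of (P1, P2) enter, so the design is invariant
    under embryo reordering.
    """
    for rec in det_records:
        if rec.transfer_type != "DET":
            raise ValueError(f"patient {rec.patient_id}: second level accepts DET records only")
    det_records = list(det_records)
    if det_records:
        rows_a = pd.DataFrame(
            [{**r.patient.features, **r.embryos[0].features} for r in det_records]
        ).reindex(columns=list(schema.selected))
        rows_b = pd.DataFrame(
            [{**r.patient.features, **r.embryos[1].features} for r in det_records]
        ).reindex(columns=list(schema.selected))
        p1 = predict_single_batch(level1, rows_a, schema)
        p2 = predict_single_batch(level1, rows_b, schema)
        patient_raw = pd.DataFrame(
            [dict(r.patient.features) for r in det_records]
        ).reindex(columns=list(schema.patient_level))
    else:
        p1 = p2 = np.array([])
        patient_raw = pd.DataFrame(columns=list(schema.patient_level))
    X = encode_features(patient_raw, schema, schema.patient_level)
    X["p_sum"] = p1 + p2
    X["p_product"] = p1 * p2
    for i, rec in enumerate(det_records):
        rec.embryos[0].predicted_probability = float(p1[i])
        rec.embryos[1].predicted_probability = float(p2[i])
    return SecondLevelTable(
        X=X,
        y_pregnancy=np.asarray([r.clinical_pregnancy for r in det_records], dtype=float),
        y_twin=np.asarray([r.twin for r in det_records], dtype=float),
        provenance=pd.DataFrame(
            {"patient_id": [r.patient_id for r in det_records]}, columns=["patient_id"]
        ),
    )


def train_second_level(
    det_table: SecondLevelTable,
    config: BoosterConfig | None = None,
    learner_factory: LearnerFactory | None = None,
    twin_on_all: bool = True,
) -> tuple[BinaryScorer, BinaryScorer]:
    """Fit the DET pregnancy and twin scorers on all DET rows.

    ``twin_on_all=False`` is the sensitivity variant that conditions the twin
    model on pregnant DETs only; the default follows the primary formulation
    (every DET row, non-pregnant ones twin-negative).
    """
    config = config or BoosterConfig()
    factory = learner_factory or _default_factory(config)
    pregnancy = factory(config.seed + 1).fit(det_table.X, det_table.y_pregnancy)
    if twin_on_all:
        twin_X, twin_y = det_table.X, det_table.y_twin
    else:
        keep = det_table.y_pregnancy == 1
        twin_X, twin_y = det_table.X.loc[keep], det_table.y_twin[keep]
    twin = factory(config.seed + 2).fit(twin_X, twin_y)
    return pregnancy, twin


@dataclass
class HierarchicalModel:
    """Trained level-1 scorer plus the two level-2 DET scorers."""

    level1: BinaryScorer
    level2_pregnancy: BinaryScorer
    level2_twin: BinaryScorer
    schema: FeatureSchema = field(default_factory=lambda: DEFAULT_SCHEMA)
    booster_config: BoosterConfig = field(default_factory=BoosterConfig)
    n_level1_excluded: int = 0


def fit_hierarchical_model(
    records: Sequence[TransferRecord],
    config: BoosterConfig | None = None,
    schema: FeatureSchema = DEFAULT_SCHEMA,
    learner_factory: LearnerFactory | None = None,
    twin_on_all: bool = True,
) -> HierarchicalModel:
    """Train the full hierarchy on a cohort.

    One master seed (``config.seed``) fans out to per-scorer sub-seeds
    (seed, seed+1, seed+2) so row/column subsampling differs across the three
    scorers while the whole fit stays reproducible.
    """
    config = config or BoosterConfig()
    level1_table = build_first_level_training(records, schema)
    level1 = train_first_level(level1_table, config, learner_factory)
    det_records = [r for r in records if r.transfer_type == "DET"]
    det_table = build_second_level_features(level1, det_records, schema)
    pregnancy, twin = train_second_level(det_table, config, learner_factory, twin_on_all)
    return HierarchicalModel(
        level1=level1,
        level2_pregnancy=pregnancy,
        level2_twin=twin,
        schema=schema,
        booster_config=config,
        n_level1_excluded=level1_table.n_excluded,
    )


def _det_design_rows(
    model: HierarchicalModel,
    patients: Sequence[PatientRecord],
    embryos_a: Sequence[EmbryoRecord],
    embryos_b: Sequence[EmbryoRecord],
) -> pd.DataFrame:
    schema = model.schema
    rows_a = pd.DataFrame(
        [{**p.features, **e.features} for p, e in zip(patients, embryos_a)]
    ).reindex(columns=list(schema.selected))
    rows_b = pd.DataFrame(
        [{**p.features, **e.features} for p, e in zip(patients, embryos_b)]
    ).reindex(columns=list(schema.selected))
    p1 = predict_single_batch(model.level1, rows_a, schema)
    p2 = predict_single_batch(model.level1, rows_b, schema)
    patient_raw = pd.DataFrame([dict(p.features) for p in patients]).reindex(
        columns=list(schema.patient_level)
    )
    X = encode_features(patient_raw, schema, schema.patient_level)
    X["p_sum"] = p1 + p2
    X["p_product"] = p1 * p2
    return X


def predict_det_batch(
    model: HierarchicalModel,
    patients: Sequence[PatientRecord],
    embryos_a: Sequence[EmbryoRecord],
    embryos_b: Sequence[EmbryoRecord],
) -> tuple[np.ndarray, np.ndarray]:
    """(pregnancy, twin) probabilities for aligned sequences of DET candidates."""
    if model.level1 is None or model.level2_pregnancy is None or model.level2_twin is None:
        raise EstimationError("untrained model: all three scorers are required")
    X = _det_design_rows(model, patients, embryos_a, embryos_b)
    return model.level2_pregnancy.predict_proba(X), model.level2_twin.predict_proba(X)


def predict_det(
    model: HierarchicalModel,
    patient: PatientRecord,
    embryo_a: EmbryoRecord,
    embryo_b: EmbryoRecord,
) -> tuple[float, float]:
    """(pregnancy probability, twin probability) for one candidate pair.

    Invariant under swapping the two embryos: the level-2 design uses only
    P1 + P2 and P1 × P2.
    """
    preg, twin = predict_det_batch(model, [patient], [embryo_a], [embryo_b])
    return float(preg[0]), float(twin[0])


def feature_importance(model: HierarchicalModel, level: str) -> dict[str, int]:
    """Split counts per feature for one scorer of the hierarchy.

    ``level`` is one of ``level1``, ``level2_pregnancy``, ``level2_twin``.
    A feature never used to split is absent from the map.
    """
    scorer = getattr(model, level, None)
    if scorer is None:
        raise ValueError(f"unknown level {level!r}")
    if not hasattr(scorer, "feature_importance"):
        raise EstimationError(f"{level} scorer does not expose split counts")
    return scorer.feature_importance()


def save_model(model: HierarchicalModel, path) -> None:
    """Serialize the trained hierarchy to one portable JSON file."""
    doc = {
        "booster_config": model.booster_config.__dict__,
        "n_level1_excluded": model.n_level1_excluded,
        "schema": {
            "selected": list(model.schema.selected),
            "patient_level": list(model.schema.patient_level),
            "embryo_level": list(model.schema.embryo_level),
        },
        "level1": model.level1.to_json(),
        "level2_pregnancy": model.level2_pregnancy.to_json(),
        "level2_twin": model.level2_twin.to_json(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def load_model(path) -> HierarchicalModel:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    return HierarchicalModel(
        level1=GradientBoostedScorer.from_json(doc["level1"]),
        level2_pregnancy=GradientBoostedScorer.from_json(doc["level2_pregnancy"]),
        level2_twin=GradientBoostedScorer.from_json(doc["level2_twin"]),
        schema=DEFAULT_SCHEMA,
        booster_config=BoosterConfig(**doc["booster_config"]),
        n_level1_excluded=int(doc["n_level1_excluded"]),
    )
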