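"""Evaluation machinery: ROC AUC, repeated train/test evaluation, calibration
tables, and the rank-based multi-algorithm comparison (Dunn's test with
Benjamini–Hochberg FDR correction).

The three prediction tasks evaluated throughout are:

* ``set_pregnancy`` — level-1 scores vs pregnancy on held-out SET transfers;
* ``det_pregnancy`` — level-2 pregnancy scores vs pregnancy on held-out DETs;
* ``det_twin`` — level-2 twin scores vs twin outcome on held-out DETs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from .cohort_io import DEFAULT_SCHEMA, FeatureSchema, TransferRecord
from .errors import EstimationError
from .hierarchical_model import (
    fit_hierarchical_model,
    predict_det_batch,
    predict_single_batch,
)
from .learners import (
    BoosterConfig,
    GradientBoostedScorer,
    LogisticScorer,
    SingleTreeScorer,
)

__all__ = [
    "TASKS",
    "EvaluationReport",
    "ComparisonReport",
    "auc",
    "stratified_split",
    "evaluate_once",
    "repeated_evaluation",
    "calibration_bins",
    "dunn_test",
    "bh_fdr",
    "default_algorithms",
    "compare_algorithms",
]

TASKS = ("set_pregnancy", "det_pregnancy", "det_twin")

# Train:validation proportions of the source cohorts (5828 : 3383).
DEFAULT_TEST_FRACTION = 3383 / (5828 + 3383)


def auc(scores, labels) -> float:
    """Area under the ROC curve as the Mann–Whitney concordance probability.

    Equals P(score of a random positive > score of a random negative), with
    ties counted 1/2, computed from the rank-sum identity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and aligned")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise EstimationError("AUC undefined: need at least one positive and one negative label")
    ranks = rankdata(scores)  # mid-ranks for ties
    rank_sum_pos = float(np.sum(ranks[labels == 1]))
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def stratified_split(
    records: Sequence[TransferRecord],
    test_fraction: float,
    rng: np.random.Generator,
) -> tuple[list[TransferRecord], list[TransferRecord]]:
    """Random train/test split stratified by (transfer type, implantation count).

    Every non-empty stratum must contribute at least one record to each side;
    a stratum too small to split raises an error naming it.
    """
    strata: dict[tuple[str, int], list[TransferRecord]] = {}
    for rec in records:
        strata.setdefault((rec.transfer_type, rec.implantation_count), []).append(rec)
    train: list[TransferRecord] = []
    test: list[TransferRecord] = []
    for key in sorted(strata):
        members = strata[key]
        if len(members) < 2:
            raise EstimationError(
                f"stratum {key[0]} with {key[1]} implantation(s) has {len(members)} record(s); "
                "too small to stratify"
            )
        order = rng.permutation(len(members))
        n_test = int(round(test_fraction * len(members)))
        n_test = min(max(n_test, 1), len(members) - 1)
        for pos, idx in enumerate(order):
            (test if pos < n_test else train).append(members[idx])
    return train, test


def _score_tasks(
    model, test: Sequence[TransferRecord], schema: FeatureSchema
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """(scores, labels) per task on a held-out set."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    set_recs = [r for r in test if r.transfer_type == "SET"]
    det_recs = [r for r in test if r.transfer_type == "DET"]
    if set_recs:
        rows = pd.DataFrame(
            [{**r.patient.features, **r.embryos[0].features} for r in set_recs]
        ).reindex(columns=list(schema.selected))
        scores = predict_single_batch(model.level1, rows, schema)
        out["set_pregnancy"] = (scores, np.array([r.clinical_pregnancy for r in set_recs]))
    if det_recs:
        preg, twin = predict_det_batch(
            model,
            [r.patient for r in det_recs],
            [r.embryos[0] for r in det_recs],
            [r.embryos[1] for r in det_recs],
        )
        labels_preg = np.array([r.clinical_pregnancy for r in det_recs])
        labels_twin = np.array([r.twin for r in det_recs])
        out["det_pregnancy"] = (preg, labels_preg)
        out["det_twin"] = (twin, labels_twin)
    return out


def evaluate_once(
    records: Sequence[TransferRecord],
    config: BoosterConfig,
    seed: int,
    test_fraction: float = DEFAULT_TEST_FRACTION,
    schema: FeatureSchema = DEFAULT_SCHEMA,
    learner_factory=None,
    resample_split: bool = True,
    split_seed: int | None = None,
) -> dict[str, float]:
    """One stratified split, one full-hierarchy fit, three held-out AUCs."""
    from dataclasses import replace

    rng = np.random.default_rng(split_seed if split_seed is not None else seed)
    train, test = stratified_split(records, test_fraction, rng)
    model = fit_hierarchical_model(
        train, replace(config, seed=seed), schema, learner_factory=learner_factory
    )
    return {
        task: auc(scores, labels) for task, (scores, labels) in _score_tasks(model, test, schema).items()
    }


@dataclass
class EvaluationReport:
    """Per-repeat AUCs for the three tasks, with summary statistics."""

    auc_per_repeat: pd.DataFrame  # rows = repeats, columns = tasks
    n_repeats: int
    master_seed: int

    @property
    def mean(self) -> pd.Series:
        return self.auc_per_repeat.mean()

    @property
    def sd(self) -> pd.Series:
        return self.auc_per_repeat.std(ddof=1)


def repeated_evaluation(
    records: Sequence[TransferRecord],
    config: BoosterConfig | None = None,
    n_repeats: int = 30,
    master_seed: int = 0,
    test_fraction: float = DEFAULT_TEST_FRACTION,
    schema: FeatureSchema = DEFAULT_SCHEMA,
    learner_factory=None,
    resample_split: bool = True,
) -> EvaluationReport:
    """Repeat the split/train/score cycle to average out random factors.

    Each repeat draws a fresh stratified train/test split and fresh learner
    seeds from the master seed; ``resample_split=False`` freezes the split at
    the first draw and varies only the learner seeds.
    """
    config = config or BoosterConfig()
    ss = np.random.SeedSequence(master_seed)
    repeat_seeds = [int(s) for s in ss.generate_state(n_repeats) % (2**31)]
    rows = []
    for i, seed in enumerate(repeat_seeds):
        split_seed = seed if resample_split else repeat_seeds[0]
        rows.append(
            evaluate_once(
                records,
                config,
                seed=seed,
                test_fraction=test_fraction,
                schema=schema,
                learner_factory=learner_factory,
                split_seed=split_seed,
            )
        )
    frame = pd.DataFrame(rows, columns=list(TASKS))
    return EvaluationReport(auc_per_repeat=frame, n_repeats=n_repeats, master_seed=master_seed)


def calibration_bins(predicted, outcomes, n_bins: int = 10) -> pd.DataFrame:
    """Reliability table over equal-width probability bins on [0, 1].

    Columns: bin index, bin edges, mean predicted value, observed event rate
    and count.  Empty bins are reported with count 0 and NaN rates; counts sum
    to the number of observations.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    predicted = np.asarray(predicted, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    if predicted.shape != outcomes.shape:
        raise ValueError("predicted and outcomes must be aligned")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(predicted, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        count = int(mask.sum())
        rows.append(
            {
                "bin": b,
                "lower": edges[b],
                "upper": edges[b + 1],
                "mean_predicted": float(predicted[mask].mean()) if count else np.nan,
                "observed_rate": float(outcomes[mask].mean()) if count else np.nan,
                "count": count,
            }
        )
    return pd.DataFrame(rows)


def dunn_test(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Dunn's post-hoc pairwise comparison on jointly ranked data.

    All observations are ranked together with mid-ranks for ties; for groups
    i, j the statistic is

        z_ij = (R̄_i − R̄_j) / sqrt( (N(N+1)/12 − Σ(t³−t)/(12(N−1))) (1/n_i + 1/n_j) )

    with two-sided p-values from the standard normal.  Returns one row per
    unordered pair with columns group_a, group_b, z, p.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    values = [np.asarray(groups[name], dtype=float) for name in names]
    if any(len(v) == 0 for v in values):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(values)
    if np.all(pooled == pooled[0]):
        raise EstimationError("no rank variation: all values identical across groups")
    ranks = rankdata(pooled)
    n_total = len(pooled)
    # tie correction: sum of (t^3 - t) over tied-value groups
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts.astype(float) ** 3 - tie_counts))
    variance_core = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    mean_ranks, sizes = {}, {}
    start = 0
    for name, v in zip(names, values):
        mean_ranks[name] = float(np.mean(ranks[start : start + len(v)]))
        sizes[name] = len(v)
        start += len(v)

    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            se = np.sqrt(variance_core * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            rows.append(
                {"group_a": a, "group_b": b, "z": float(z), "p": float(2 * norm.sf(abs(z)))}
            )
    return pd.DataFrame(rows)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a non-empty 1-D collection")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def default_algorithms(config: BoosterConfig) -> dict[str, Callable]:
    """Learner factories for the three compared algorithms.

    Boosted trees use native missing-value routing; logistic regression and
    the single classification tree impute (median/mode) because they cannot
    accept NaN — the asymmetry is part of the realistic comparison.
    """
    return {
        "boosted_trees": lambda seed: GradientBoostedScorer(config).with_seed(seed),
        "logistic_regression": lambda seed: LogisticScorer(seed=seed),
        "single_tree": lambda seed: SingleTreeScorer(seed=seed),
    }


@dataclass
class ComparisonReport:
    """AUC matrix (algorithm × task × repeat) with Dunn + BH-FDR per task."""

    auc_table: pd.DataFrame  # columns: algorithm, repeat, one column per task
    tests: dict[str, pd.DataFrame] = field(default_factory=dict)  # task → Dunn rows + p_adjusted

    def mean_auc(self) -> pd.DataFrame:
        return self.auc_table.drop(columns="repeat").groupby("algorithm").mean()


def compare_algorithms(
    records: Sequence[TransferRecord],
    config: BoosterConfig | None = None,
    algorithms: Mapping[str, Callable] | None = None,
    n_repeats: int = 30,
    master_seed: int = 0,
    test_fraction: float = DEFAULT_TEST_FRACTION,
    schema: FeatureSchema = DEFAULT_SCHEMA,
    tasks: Sequence[str] = TASKS,
) -> ComparisonReport:
    """Repeatedly evaluate each algorithm on identical splits and compare.

    Within each repeat all algorithms share the same stratified train/test
    split; per task, the per-repeat AUC samples of the algorithms are compared
    with Dunn's test and the pairwise p-values are BH-FDR adjusted.
    """
    config = config or BoosterConfig()
    algorithms = algorithms or default_algorithms(config)
    ss = np.random.SeedSequence(master_seed)
    repeat_seeds = [int(s) for s in ss.generate_state(n_repeats) % (2**31)]
    rows = []
    for i, seed in enumerate(repeat_seeds):
        for name, factory in algorithms.items():
            result = evaluate_once(
                records,
                config,
                seed=seed,
                test_fraction=test_fraction,
                schema=schema,
                learner_factory=factory,
                split_seed=seed,  # identical split across algorithms in a repeat
            )
            rows.append({"algorithm": name, "repeat": i, **{t: result[t] for t in tasks}})
    table = pd.DataFrame(rows)

    tests: dict[str, pd.DataFrame] = {}
    for task in tasks:
        groups = {
            name: table.loc[table["algorithm"] == name, task].to_numpy()
            for name in algorithms
        }
        if len(groups) < 2:
            continue
        dunn = dunn_test(groups)
        dunn["p_adjusted"] = bh_fdr(dunn["p"].to_numpy())
        tests[task] = dunn
    return ComparisonReport(auc_table=table, tests=tests)
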