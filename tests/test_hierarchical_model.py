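"""Stacked-model correctness: label attribution, determinism, symmetry of the
DET pathway, engineered features, and split-count importance."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy.stats import spearmanr

from embryostack.cohort_io import EmbryoRecord, PatientRecord, TransferRecord
from embryostack.errors import EstimationError
from embryostack.hierarchical_model import (
    build_first_level_training,
    build_second_level_features,
    feature_importance,
    fit_hierarchical_model,
    load_model,
    predict_det,
    predict_det_batch,
    predict_single,
    predict_single_batch,
    save_model,
    train_first_level,
    train_second_level,
)
from embryostack.learners import BoosterConfig, GradientBoostedScorer
from embryostack.evaluation import auc
from embryostack.synthetic_cohort import (
    DEFAULT_MARGINALS,
    GeneratorConfig,
    TruthModel,
    default_config,
    generate_cohort,
)


def _mk_record(pid, ttype, count, n_embryos):
    patient = PatientRecord({"age": 30.0})
    embryos = [
        EmbryoRecord(f"{pid}-e{i+1}", {"blastomere_number": 8.0 - i}) for i in range(n_embryos)
    ]
    return TransferRecord(pid, patient, embryos, ttype, count)


def test_attribution_rule_on_mixed_example():
    """4 SET + 3 DET (counts 0, 1, 2) → 4 + 2 + 2 labelled embryos, 2 excluded."""
    records = [_mk_record(f"s{i}", "SET", i % 2, 1) for i in range(4)]
    records += [_mk_record(f"d{c}", "DET", c, 2) for c in (0, 1, 2)]
    table = build_first_level_training(records)
    assert len(table.X) == 8
    assert table.n_excluded == 2
    labels = dict(zip(table.provenance["patient_id"], table.y))
    assert labels["d0"] == 0 and labels["d2"] == 1
    assert "d1" not in set(table.provenance["patient_id"])


def test_attribution_rule_all_set_cohort():
    records = [_mk_record(f"s{i}", "SET", i % 2, 1) for i in range(10)]
    table = build_first_level_training(records)
    assert len(table.X) == len(records) and table.n_excluded == 0


def test_attribution_rule_matches_bruteforce_recount(small_cohort):
    table = build_first_level_training(small_cohort)
    expected = sum(
        1 if r.transfer_type == "SET" else (2 if r.implantation_count in (0, 2) else 0)
        for r in small_cohort
    )
    assert len(table.X) == expected
    one_implant = {
        r.patient_id for r in small_cohort
        if r.transfer_type == "DET" and r.implantation_count == 1
    }
    assert one_implant  # the rule is actually exercised
    assert one_implant.isdisjoint(set(table.provenance["patient_id"]))


def test_single_class_labels_rejected():
    records = [_mk_record(f"s{i}", "SET", 0, 1) for i in range(10)]
    table = build_first_level_training(records)
    with pytest.raises(EstimationError, match="degenerate"):
        train_first_level(table, BoosterConfig(seed=1))


def test_training_is_deterministic_given_seed(small_cohort):
    table = build_first_level_training(small_cohort)
    a = train_first_level(table, BoosterConfig(seed=5)).predict_proba(table.X)
    b = train_first_level(table, BoosterConfig(seed=5)).predict_proba(table.X)
    np.testing.assert_array_equal(a, b)
    c = train_first_level(table, BoosterConfig(seed=6)).predict_proba(table.X)
    assert not np.array_equal(a, c)


def test_resubstitution_auc_beats_chance(small_cohort, trained_model):
    table = build_first_level_training(small_cohort)
    scores = trained_model.level1.predict_proba(table.X)
    assert auc(scores, table.y) > 0.5


def test_predictions_are_probabilities_and_functionally_deterministic(small_cohort, trained_model):
    rows = pd.DataFrame(
        [{**r.patient.features, **r.embryos[0].features} for r in small_cohort[:500]]
    )
    scores = predict_single_batch(trained_model.level1, rows)
    assert np.all((scores >= 0) & (scores <= 1))
    rec = small_cohort[0]
    twin_embryo = EmbryoRecord("copy", dict(rec.embryos[0].features))
    assert predict_single(trained_model, rec.patient, rec.embryos[0]) == predict_single(
        trained_model, rec.patient, twin_embryo
    )


def test_scores_rank_correlate_with_truth_marginals():
    config = default_config(4000, seed=31, latent_sd=0.0)
    model = fit_hierarchical_model(generate_cohort(config), BoosterConfig(seed=32))
    held = generate_cohort(replace(default_config(1500, seed=33, latent_sd=0.0), missing_rate=0.0))
    table = build_first_level_training(held)
    scores = predict_single_batch(model.level1, table.X)
    truth_eta = config.truth.log_odds(table.X)
    rho = spearmanr(scores, truth_eta).statistic
    assert rho > 0.5


# --- second level -------------------------------------------------------------


class _FixedScorer:
    """Contract stand-in: score = blastomere_number / 10."""

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return X["blastomere_number"].to_numpy(dtype=float) / 10.0


def test_engineered_features_match_hand_arithmetic():
    rec = TransferRecord(
        "d1",
        PatientRecord({"age": 30.0}),
        [EmbryoRecord("a", {"blastomere_number": 6.0}), EmbryoRecord("b", {"blastomere_number": 5.0})],
        "DET",
        0,
    )
    table = build_second_level_features(_FixedScorer(), [rec])
    assert table.X.shape[1] == 18
    assert table.X.loc[0, "p_sum"] == pytest.approx(0.6 + 0.5)
    assert table.X.loc[0, "p_product"] == pytest.approx(0.6 * 0.5)
    zero = TransferRecord(
        "d2",
        PatientRecord({"age": 30.0}),
        [EmbryoRecord("a", {"blastomere_number": 0.0}), EmbryoRecord("b", {"blastomere_number": 0.0})],
        "DET",
        0,
    )
    z = build_second_level_features(_FixedScorer(), [zero])
    assert z.X.loc[0, "p_sum"] == 0.0 and z.X.loc[0, "p_product"] == 0.0


def test_second_level_rejects_set_records():
    with pytest.raises(ValueError, match="DET"):
        build_second_level_features(_FixedScorer(), [_mk_record("s", "SET", 0, 1)])


def test_second_level_design_width_is_18(small_cohort, trained_model):
    det = [r for r in small_cohort if r.transfer_type == "DET"]
    table = build_second_level_features(trained_model.level1, det)
    assert table.X.shape[1] == 18
    assert list(table.X.columns[-2:]) == ["p_sum", "p_product"]


def test_embryo_swap_leaves_det_row_unchanged(small_cohort, trained_model):
    det = [r for r in small_cohort if r.transfer_type == "DET"][:50]
    fwd = build_second_level_features(trained_model.level1, det)
    swapped = [
        TransferRecord(r.patient_id, r.patient, [r.embryos[1], r.embryos[0]],
                       "DET", r.implantation_count)
        for r in det
    ]
    rev = build_second_level_features(trained_model.level1, swapped)
    pd.testing.assert_frame_equal(fwd.X, rev.X)


def test_predict_det_swap_invariance_bitwise(small_cohort, trained_model):
    det = [r for r in small_cohort if r.transfer_type == "DET"]
    patients = [r.patient for r in det]
    e1 = [r.embryos[0] for r in det]
    e2 = [r.embryos[1] for r in det]
    preg_fwd, twin_fwd = predict_det_batch(trained_model, patients, e1, e2)
    preg_rev, twin_rev = predict_det_batch(trained_model, patients, e2, e1)
    np.testing.assert_array_equal(preg_fwd, preg_rev)
    np.testing.assert_array_equal(twin_fwd, twin_rev)
    assert np.all((preg_fwd >= 0) & (preg_fwd <= 1) & (twin_fwd >= 0) & (twin_fwd <= 1))


def test_twin_model_single_class_rejected_pregnancy_unaffected(small_cohort, trained_model):
    det = [r for r in small_cohort if r.transfer_type == "DET"]
    table = build_second_level_features(trained_model.level1, det)
    table.y_twin = np.zeros_like(table.y_twin)  # a clinic where no DET ever twins
    with pytest.raises(EstimationError, match="degenerate"):
        train_second_level(table, BoosterConfig(seed=2))
    # the pregnancy model itself still trains on the same design
    scorer = GradientBoostedScorer(BoosterConfig(seed=2)).fit(table.X, table.y_pregnancy)
    assert np.all(scorer.predict_proba(table.X) >= 0)


def test_twin_model_calibration_in_the_large():
    """The twin scorer's mean prediction matches the twin rate of the DETs it
    was trained on; on held-out DETs the mean shifts down by a bounded amount
    because level 2 consumes in-sample level-1 scores (stacking leakage), but
    stays well within the observed rate's order of magnitude."""
    train_recs = generate_cohort(default_config(6000, seed=41))
    model = fit_hierarchical_model(train_recs, BoosterConfig(seed=42))
    det_train = [r for r in train_recs if r.transfer_type == "DET"]
    table = build_second_level_features(model.level1, det_train)
    in_sample = model.level2_twin.predict_proba(table.X)
    train_rate = np.mean([r.twin for r in det_train])
    assert abs(in_sample.mean() - train_rate) < 0.01

    held = generate_cohort(replace(default_config(5000, seed=43), det_fraction=1.0))
    _, twin = predict_det_batch(
        model,
        [r.patient for r in held],
        [r.embryos[0] for r in held],
        [r.embryos[1] for r in held],
    )
    observed = np.mean([r.twin for r in held])
    assert 0.5 * observed < twin.mean() < 1.5 * observed


def test_twin_model_discrimination_close_to_independence_baseline():
    """Under the shared-latent mechanism the product P1 x P2 is a near-optimal
    twin ranking (the latent is feature-independent), so the learned twin
    scorer cannot beat it systematically — but it must track it closely and
    discriminate clearly above chance."""
    diffs, model_aucs = [], []
    for seed in (0, 1, 2):
        cfg = replace(default_config(5000, seed=seed, latent_sd=1.5), det_fraction=0.5)
        model = fit_hierarchical_model(generate_cohort(cfg), BoosterConfig(seed=seed + 200))
        held = generate_cohort(
            replace(default_config(2500, seed=seed + 500, latent_sd=1.5), det_fraction=1.0)
        )
        table = build_second_level_features(model.level1, held)
        scores = model.level2_twin.predict_proba(table.X)
        y = table.y_twin
        diffs.append(auc(table.X["p_product"].to_numpy(), y) - auc(scores, y))
        model_aucs.append(auc(scores, y))
    assert np.mean(model_aucs) > 0.55
    assert np.mean(diffs) < 0.05


# --- importance ----------------------------------------------------------------


def test_split_counts_match_tree_dump_walk(trained_model):
    reported = trained_model.level1.feature_importance()
    recounted = trained_model.level1.split_count_from_dump()
    assert reported == recounted
    assert sum(reported.values()) == sum(recounted.values()) > 0


def test_constant_feature_absent_from_importance(small_cohort):
    table = build_first_level_training(small_cohort)
    X = table.X.copy()
    X["icsi"] = 1.0  # constant in training
    scorer = GradientBoostedScorer(BoosterConfig(seed=3)).fit(X, table.y)
    assert "icsi" not in scorer.feature_importance()


def test_planted_strong_features_rank_high():
    """A truth using only three features strongly puts them in the importance
    top five in the majority of seeds.  The planted features are continuous so
    the check is fair under split-count importance's cardinality bias."""
    strong = {"age": -0.4, "endometrial_thickness": 0.6, "e2_hcg_day": 0.0006}
    truth = TruthModel(
        intercept=-sum(c * DEFAULT_MARGINALS[f].exact_mean() for f, c in strong.items()),
        coefficients=strong,
        latent_sd=0.0,
    )
    hits = 0
    for seed in range(10):
        cfg = GeneratorConfig(n_patients=2500, truth=truth, seed=seed)
        table = build_first_level_training(generate_cohort(cfg))
        scorer = train_first_level(table, BoosterConfig(seed=seed + 50))
        counts = scorer.feature_importance()
        top5 = sorted(counts, key=counts.get, reverse=True)[:5]
        hits += set(strong) <= set(top5)
    assert hits >= 6


def test_feature_importance_level_dispatch(trained_model):
    l1 = feature_importance(trained_model, "level1")
    l2 = feature_importance(trained_model, "level2_twin")
    assert set(l1) <= set(trained_model.schema.selected)
    assert set(l2) <= set(trained_model.schema.patient_level) | {"p_sum", "p_product"}
    with pytest.raises(ValueError):
        feature_importance(trained_model, "level3")


def test_model_save_load_round_trip(tmp_path, small_cohort, trained_model):
    path = tmp_path / "model.json"
    save_model(trained_model, path)
    loaded = load_model(path)
    det = [r for r in small_cohort if r.transfer_type == "DET"][:20]
    for r in det:
        assert predict_det(loaded, r.patient, *r.embryos) == predict_det(
            trained_model, r.patient, *r.embryos
        )
    assert loaded.n_level1_excluded == trained_model.n_level1_excluded
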