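import numpy as np
import pytest

from dyslexiscan import (
    InfeasibleFoldsError,
    SimConfig,
    TrainConfig,
    ValidationError,
    compute_metrics,
    fit_fold,
    generate_folds,
    reading_time_baseline,
    reading_time_threshold_resubstitution,
    run_experiment,
    simulate_cohort,
)
from dyslexiscan.evaluation import _fold_seed, replace_seed
from dyslexiscan.preprocess import prepare_signal

FAST_TRAIN = TrainConfig(max_epochs=15, early_stopping_patience=5)


# ---------------------------------------------------------------------------
# fold generation


def _fake_manifest(n_hr, n_lr):
    from dyslexiscan import ManifestEntry, CohortManifest

    entries = [ManifestEntry(f"HR{i:03d}", "HR", "", 100) for i in range(n_hr)]
    entries += [ManifestEntry(f"LR{i:03d}", "LR", "", 100) for i in range(n_lr)]
    return CohortManifest(entries)


def test_fold_plan_satisfies_all_constraints():
    manifest = _fake_manifest(30, 28)
    plan = generate_folds(manifest, n_folds=25, seed=0)
    all_ids = set(manifest.ids_by_label("HR")) | set(manifest.ids_by_label("LR"))
    for fold in plan.folds:
        test = set(fold.test)
        assert len(test) == 16
        assert sum(1 for s in test if s.startswith("HR")) == 8
        assert sum(1 for s in test if s.startswith("LR")) == 8
        train, val = set(fold.train), set(fold.val)
        assert not (test & train) and not (test & val) and not (train & val)
        assert test | train | val == all_ids
        # 90/10 stratified split of the 42 remaining subjects
        assert len(val) == round(0.1 * (len(all_ids) - 16))
    assert plan.max_pairwise_overlap() <= 8


def test_fold_plan_deterministic_under_seed():
    manifest = _fake_manifest(20, 20)
    p1 = generate_folds(manifest, n_folds=10, seed=4)
    p2 = generate_folds(manifest, n_folds=10, seed=4)
    assert [f.test for f in p1.folds] == [f.test for f in p2.folds]
    assert [f.val for f in p1.folds] == [f.val for f in p2.folds]


def test_minimal_cohort_infeasible_by_pigeonhole():
    with pytest.raises(InfeasibleFoldsError):
        generate_folds(_fake_manifest(8, 8), n_folds=2, seed=0)


def test_too_small_class_rejected():
    with pytest.raises(ValidationError):
        generate_folds(_fake_manifest(7, 20), n_folds=1, seed=0)


# ---------------------------------------------------------------------------
# metrics


def test_metrics_perfect_fold():
    y = ["HR"] * 8 + ["LR"] * 8
    m = compute_metrics(y, y)
    assert (m.accuracy, m.tpr, m.tnr) == (100.0, 100.0, 100.0)


def test_metrics_all_predicted_lr():
    y_true = ["HR"] * 8 + ["LR"] * 8
    m = compute_metrics(y_true, ["LR"] * 16)
    assert (m.accuracy, m.tpr, m.tnr) == (50.0, 0.0, 100.0)


def test_metrics_from_contingency_counts():
    y_true = ["HR"] * 8 + ["LR"] * 8
    y_pred = ["HR"] * 7 + ["LR"] + ["LR"] * 6 + ["HR"] * 2
    m = compute_metrics(y_true, y_pred)
    assert m.accuracy == pytest.approx(81.25)
    assert m.tpr == pytest.approx(87.5)
    assert m.tnr == pytest.approx(75.0)


def test_metrics_absent_positive_class_reported_missing():
    m = compute_metrics(["LR", "LR"], ["LR", "HR"])
    assert m.tpr is None
    assert m.tnr == pytest.approx(50.0)
    with pytest.raises(ValidationError):
        compute_metrics([], [])


# ---------------------------------------------------------------------------
# experiment runner


@pytest.fixture(scope="module")
def tiny_experiment():
    cfg = SimConfig(lr_line_duration_s=(0.3, 0.06), seed=21)
    cohort, manifest = simulate_cohort(14, 14, cfg)
    plan = generate_folds(manifest, n_folds=2, test_per_class=3, seed=21)
    return cohort, plan


def test_run_experiment_deterministic(tiny_experiment):
    cohort, plan = tiny_experiment
    r1 = run_experiment(cohort, "SPEC_INTERP", "cnn2", plan, FAST_TRAIN, seed=5)
    r2 = run_experiment(cohort, "SPEC_INTERP", "cnn2", plan, FAST_TRAIN, seed=5)
    assert r1.to_dict()["per_fold"] == r2.to_dict()["per_fold"]
    assert r1.to_dict()["aggregate"] == r2.to_dict()["aggregate"]


def test_report_aggregates_are_fold_means(tiny_experiment):
    cohort, plan = tiny_experiment
    rep = run_experiment(
        cohort, "TIME_ZEROPAD", "cnn2", plan, FAST_TRAIN,
        target_length_policy="global", seed=6,
    )
    accs = [m.accuracy for m in rep.per_fold]
    assert rep.mean("accuracy") == pytest.approx(np.mean(accs))
    assert rep.std("accuracy") == pytest.approx(np.std(accs, ddof=1))
    for m in rep.per_fold:
        assert 0 <= m.accuracy <= 100


def test_leakage_audit_test_subjects_never_influence_fit(tiny_experiment):
    """Replacing the test fold's traces changes no fitted quantity."""
    cohort, plan = tiny_experiment
    fold = plan.folds[0]
    prepared = {r.subject_id: prepare_signal(r) for r in cohort}
    tampered = dict(prepared)
    for sid in fold.test:
        sig = prepared[sid]
        tampered[sid] = prepare_signal(
            type(cohort[0])(
                subject_id=sid,
                label=sig.label,
                lx=sig.x * 10 + 7,
                rx=sig.x * 10 + 7,
                reading_end_index=sig.original_length,
            )
        )
    cfgs = dict(train_cfg=replace_seed(FAST_TRAIN, 11), seed=11)
    fit_a = fit_fold(prepared, fold, "SPEC_INTERP", "cnn2", cfgs["train_cfg"], seed=11)
    fit_b = fit_fold(tampered, fold, "SPEC_INTERP", "cnn2", cfgs["train_cfg"], seed=11)
    assert fit_a.target_length == fit_b.target_length
    for a, b in zip(fit_a.model.get_weights(), fit_b.model.get_weights()):
        np.testing.assert_array_equal(a, b)


def test_errors_carry_fold_context(tiny_experiment):
    cohort, plan = tiny_experiment
    with pytest.raises(ValidationError, match="fold 0"):
        run_experiment(
            cohort, "SPEC_INTERP", "cnn2", plan, FAST_TRAIN,
            energy_correction="bogus", seed=0,
        )


# ---------------------------------------------------------------------------
# reading-time baseline


def test_baseline_perfect_when_distributions_disjoint():
    cfg = SimConfig(
        lr_line_duration_s=(0.3, 0.02),
        hr_slowdown_factor=3.0,
        fixation_jitter_sd=0.0,
        eye_noise_sd=0.0,
        seed=13,
    )
    cohort, manifest = simulate_cohort(14, 14, cfg)
    plan = generate_folds(manifest, n_folds=3, test_per_class=3, seed=13)
    rep = reading_time_baseline(cohort, plan)
    assert rep.mean("accuracy") == 100.0
    assert reading_time_threshold_resubstitution(cohort) == 100.0


def test_baseline_chance_when_time_matched():
    cfg = SimConfig(
        hr_slowdown_factor=1.0,
        regression_rate_per_line=0.0,
        lr_line_duration_s=(0.3, 0.06),
        seed=17,
    )
    cohort, manifest = simulate_cohort(20, 20, cfg)
    plan = generate_folds(manifest, n_folds=5, test_per_class=5, seed=17)
    rep = reading_time_baseline(cohort, plan)
    assert 25.0 <= rep.mean("accuracy") <= 75.0


def test_baseline_deterministic(tiny_experiment):
    cohort, plan = tiny_experiment
    r1 = reading_time_baseline(cohort, plan)
    r2 = reading_time_baseline(cohort, plan)
    assert r1.to_dict()["per_fold"] == r2.to_dict()["per_fold"]
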