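"""Training loop mechanics, classical baselines, grade-0/1 label probing."""

import numpy as np
import pytest

from conftest import make_fake_slice
from kneegrade.datapipe import AugmentConfig, CohortSplit, build_sets, patient_split
from kneegrade.isolation import isolate
from kneegrade.model import KneeGradeModel
from kneegrade.phantom import generate_cohort
from kneegrade.trainer import (
    BaselineConfig,
    TrainConfig,
    evaluate,
    fit_baselines,
    grade01_confusability,
    slices_to_arrays,
    train,
)


def _toy_split(n_per_class=4, classes=(0, 2, 4), seed=0):
    rng = np.random.default_rng(seed)
    slices = [make_fake_slice(f"P{g}{i}", grade=g, seed=int(rng.integers(1 << 30)))
              for g in classes for i in range(n_per_class)]
    val = [make_fake_slice(f"P{g}v", grade=g, seed=int(rng.integers(1 << 30)))
           for g in classes]
    return CohortSplit(train=slices, val=val, test=[])


def test_zero_learning_rate_freezes_parameters():
    model = KneeGradeModel(backbone="tiny", seed=1)
    before = [p.value.copy() for p in model.params() if p.trainable]
    cfg = TrainConfig(learning_rate=0.0, max_epochs=1, seed=2)
    train(model, _toy_split(), cfg)
    after = [p.value for p in model.params() if p.trainable]
    assert max(np.abs(a - b).max() for a, b in zip(after, before)) < 1e-12


def _freeze_batchnorm(module):
    from kneegrade import nn
    if isinstance(module, nn.BatchNorm2d):
        module.momentum = 1.0  # running stats never move
    for v in vars(module).values():
        if isinstance(v, nn.Module):
            _freeze_batchnorm(v)
        elif isinstance(v, (list, tuple)):
            for item in v:
                if isinstance(item, nn.Module):
                    _freeze_batchnorm(item)


def test_early_stopping_halts_when_no_improvement_possible():
    """With lr=0 and frozen normalization statistics the validation loss is
    constant, so patience-1 early stopping must fire on the second epoch."""
    model = KneeGradeModel(backbone="tiny", seed=3)
    _freeze_batchnorm(model.net)
    cfg = TrainConfig(learning_rate=0.0, max_epochs=10, early_stop_patience=1, seed=4)
    _, hist = train(model, _toy_split(), cfg)
    assert hist.stopped_epoch == 1
    assert hist.n_epochs == 2


def test_history_traces_have_matching_lengths():
    model = KneeGradeModel(backbone="tiny", seed=5)
    cfg = TrainConfig(learning_rate=1e-3, max_epochs=3, seed=6)
    _, hist = train(model, _toy_split(), cfg)
    lengths = {len(v) for v in hist.train.values()} | {len(v) for v in hist.val.values()}
    assert lengths == {hist.n_epochs}


def test_best_epoch_attains_min_val_loss():
    model = KneeGradeModel(backbone="tiny", seed=7)
    cfg = TrainConfig(learning_rate=1e-3, max_epochs=4, seed=8)
    _, hist = train(model, _toy_split(seed=9), cfg)
    assert hist.val["loss"][hist.best_epoch] == min(hist.val["loss"])


def test_training_learns_separable_three_class_phantoms():
    """Grades 2/3/4 differ in joint gap and osteophytes by construction, so
    a short training run must fit them well."""
    records = generate_cohort(24, [0, 0, 1 / 3, 1 / 3, 1 / 3], seed=31)
    train_rec, test_rec = patient_split(records, 0.2, seed=32)
    train_sl = [s for r in train_rec for s in isolate(r)]
    test_sl = [s for r in test_rec for s in isolate(r)]
    split = build_sets(train_sl, test_sl, AugmentConfig(copies_per_image=2, seed=33),
                       seed=33)
    model = KneeGradeModel(backbone="tiny", seed=34)
    cfg = TrainConfig(learning_rate=1e-3, max_epochs=16, seed=35)
    model, hist = train(model, split, cfg)
    # best-epoch model, eval mode, on the un-augmented training slices:
    # clearly above the 1/3 chance level at this deliberately small scale
    report = evaluate(model, train_sl)
    assert report.accuracy >= 0.65


# -- baselines --------------------------------------------------------------

@pytest.fixture(scope="module")
def separable_two_class():
    """Balanced grade-0 vs grade-4 knees: 28 train + 12 test per class."""
    lo = generate_cohort(20, [1, 0, 0, 0, 0], seed=51)
    hi = generate_cohort(20, [0, 0, 0, 0, 1], seed=52)
    lo_sl = [s for r in lo for s in isolate(r)]
    hi_sl = [s for r in hi for s in isolate(r)]
    train_sl = lo_sl[:28] + hi_sl[:28]
    test_sl = lo_sl[28:] + hi_sl[28:]
    return train_sl, test_sl


def test_baselines_fit_separable_grades(separable_two_class):
    train_sl, test_sl = separable_two_class
    table = fit_baselines(train_sl, test_sl, BaselineConfig(rf_n_estimators=100))
    for name in ("decision_tree", "svm", "random_forest"):
        assert table[name]["accuracy"] >= 0.9, name


def test_baselines_at_chance_on_shuffled_labels(separable_two_class):
    train_sl, test_sl = separable_two_class
    rng = np.random.default_rng(0)
    shuffled = [make_fake_slice(s.patient_id, s.side, int(g), seed=i)
                for i, (s, g) in enumerate(zip(
                    train_sl, rng.permutation([s.grade for s in train_sl])))]
    for i, s in enumerate(shuffled):  # keep real pixels, shuffled labels
        s.pixels = train_sl[i].pixels
    table = fit_baselines(shuffled, test_sl, BaselineConfig(rf_n_estimators=50))
    for name, row in table.items():
        assert abs(row["accuracy"] - 0.5) <= 0.35, name


def test_forest_size_does_not_hurt(separable_two_class):
    train_sl, test_sl = separable_two_class
    accs = {n: [] for n in (1, 100)}
    for seed in range(5):
        for n in accs:
            t = fit_baselines(train_sl, test_sl,
                              BaselineConfig(rf_n_estimators=n, seed=seed))
            accs[n].append(t["random_forest"]["accuracy"])
    assert np.mean(accs[100]) >= np.mean(accs[1]) - 0.05


def test_baselines_deterministic_under_seed(separable_two_class):
    train_sl, test_sl = separable_two_class
    cfg = BaselineConfig(rf_n_estimators=20, seed=3)
    a = fit_baselines(train_sl, test_sl, cfg)
    b = fit_baselines(train_sl, test_sl, cfg)
    assert a == b


def test_baselines_reject_single_class():
    sl = [make_fake_slice(f"P{i}", grade=2, seed=i) for i in range(6)]
    with pytest.raises(ValueError, match="2 classes"):
        fit_baselines(sl, sl, BaselineConfig())


# -- grade-0/1 confusability ------------------------------------------------

def test_confusability_requires_both_grades():
    model = KneeGradeModel(backbone="tiny", seed=9)
    sl = [make_fake_slice(f"P{i}", grade=2, seed=i) for i in range(4)]
    with pytest.raises(ValueError, match="grade 0 and grade 1"):
        grade01_confusability(model, sl)


def test_merging_confusable_grades_cannot_lower_accuracy():
    rng = np.random.default_rng(12)
    y = rng.integers(5, size=400)
    p = rng.dirichlet(np.ones(5), size=400)
    acc5 = np.mean(np.argmax(p, axis=1) == y)
    merged = np.column_stack([p[:, 0] + p[:, 1], p[:, 2:]])
    y_m = np.where(y <= 1, 0, y - 1)
    acc4 = np.mean(np.argmax(merged, axis=1) == y_m)
    assert acc4 >= acc5


def test_latent_pain_flag_carries_the_grade01_signal():
    """An oracle reading the pain flag separates grades 0/1 perfectly,
    confirming the label (not the image) holds the information."""
    records = generate_cohort(30, [0.5, 0.5, 0, 0, 0], seed=61)
    slices = [s for r in records for s in isolate(r)]
    y = np.array([s.grade for s in slices])
    pain_pred = np.array([1 if s.pain else 0 for s in slices])
    assert np.mean(pain_pred == y) == 1.0


def test_train_rejects_empty_sets():
    model = KneeGradeModel(backbone="tiny", seed=1)
    with pytest.raises(ValueError):
        train(model, CohortSplit(train=[], val=[], test=[]), TrainConfig())
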