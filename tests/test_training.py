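"""Training protocol: loss arithmetic, stopping rules, determinism,
checkpoint round-trips, and evaluation plumbing.  Heavy convergence checks
live with the benchmark suite; these tests use a few tiny epochs."""

import numpy as np
import pytest

from hippseg.errors import ValidationError
from hippseg.model import CSDAUNet, ModelConfig, binarize, load_checkpoint, save_checkpoint
from hippseg.training import (TrainConfig, bce_loss, evaluate, overfit_one_batch,
                              split_train_val, train)

TINY_MODEL = dict(input_height=64, input_width=64, base_channels=4, seed=0)


def _tiny_tc(**kw):
    base = dict(seed=0, max_epochs=2, early_stop_patience=50, augment=False)
    base.update(kw)
    return TrainConfig(**base)


# ------------------------------------------------------------------ loss

def test_bce_closed_forms(rng):
    truth = (rng.random((6, 6)) > 0.5).astype(float)
    assert bce_loss(np.full((6, 6), 0.5), truth) == pytest.approx(np.log(2), rel=1e-12)
    # four-pixel hand computation
    p = np.array([[0.9, 0.1], [0.8, 0.2]])
    y = np.array([[1.0, 0.0], [1.0, 0.0]])
    expected = -(np.log(0.9) + np.log(0.9) + np.log(0.8) + np.log(0.8)) / 4
    assert bce_loss(p, y) == pytest.approx(expected, rel=1e-12)
    # loss vanishes as predictions approach the truth
    assert bce_loss(np.abs(y - 1e-9), y) < 1e-6
    with pytest.raises(ValidationError):
        bce_loss(p, y[:1])


# -------------------------------------------------------------- training

def test_train_rejects_subject_leakage(bench_volumes):
    cfg = ModelConfig(**TINY_MODEL)
    with pytest.raises(ValidationError, match="leakage"):
        train(cfg, bench_volumes[:2], bench_volumes[1:3], _tiny_tc())


def test_early_stopping_with_zero_patience(bench_volumes):
    """With patience 0 and a learning rate too small to move the loss, the
    second epoch cannot improve and training stops early."""
    cfg = ModelConfig(**TINY_MODEL)
    tc = _tiny_tc(learning_rate=1e-30, max_epochs=10, early_stop_patience=0)
    _, log = train(cfg, bench_volumes[:1], bench_volumes[1:2], tc)
    assert log.stop_reason == "early_stop"
    assert len(log.val_loss) < 10
    assert log.best_epoch == int(np.argmin(log.val_loss))


def test_training_is_deterministic(bench_volumes):
    cfg = ModelConfig(**TINY_MODEL)
    runs = []
    for _ in range(2):
        weights, log = train(cfg, bench_volumes[:1], bench_volumes[1:2],
                             _tiny_tc(augment=True))
        runs.append((weights, log))
    (w1, l1), (w2, l2) = runs
    assert l1.train_loss == l2.train_loss
    assert l1.val_loss == l2.val_loss
    for k in w1:
        np.testing.assert_array_equal(w1[k], w2[k])


def test_best_epoch_tracks_minimum_val_loss(bench_volumes):
    cfg = ModelConfig(**TINY_MODEL)
    _, log = train(cfg, bench_volumes[:2], bench_volumes[2:3], _tiny_tc(max_epochs=3))
    assert log.best_epoch == int(np.argmin(log.val_loss))
    assert len(log.train_loss) <= 3
    assert log.stop_reason in ("max_epochs", "early_stop")


def test_overfit_loss_decreases(bench_volumes):
    v = bench_volumes[0]
    li = v.labeled_indices()[:2]
    from hippseg.preprocessing import normalize_intensity
    imgs = np.stack([normalize_intensity(v.slices[i]) for i in li])
    cfg = ModelConfig(sa_enabled=False, isa_enabled=False, **TINY_MODEL)
    losses = overfit_one_batch(cfg, imgs, v.masks[li], steps=40)
    assert losses[-1] < losses[0]


# ------------------------------------------------------------ evaluation

def test_checkpoint_round_trip_reproduces_metrics(tmp_path, bench_volumes,
                                                  small_config):
    model = CSDAUNet(small_config)
    report1, per1 = evaluate(model, bench_volumes[18:])
    save_checkpoint(model, tmp_path / "ckpt")
    restored = load_checkpoint(tmp_path / "ckpt")
    assert restored.config == small_config
    report2, per2 = evaluate(restored, bench_volumes[18:])
    assert report1 == report2
    assert per1.equals(per2)


def test_checkpoint_mismatch_is_explicit(tmp_path, small_config):
    model = CSDAUNet(small_config)
    save_checkpoint(model, tmp_path / "ckpt")
    other = ModelConfig(input_height=64, input_width=64, base_channels=4)
    with pytest.raises(ValidationError):
        load_checkpoint(tmp_path / "ckpt", config=other)
    with pytest.raises(ValidationError):
        load_checkpoint(tmp_path / "missing")


def test_evaluate_against_own_predictions_is_perfect(bench_volumes, small_config):
    """Using a model's binarized output as ground truth must give dice = 1."""
    from hippseg.phantom import SubjectVolume
    from hippseg.preprocessing import normalize_intensity
    model = CSDAUNet(small_config)
    vol = bench_volumes[0]
    imgs = np.stack([normalize_intensity(s) for s in vol.slices])
    preds = binarize(model.forward_subject(imgs.astype(np.float32)))
    selfvol = SubjectVolume(subject_id="self", slices=imgs, masks=preds)
    report, _ = evaluate(model, [selfvol])
    assert report.dice == pytest.approx(1.0)
    assert report.iou == pytest.approx(1.0)


def test_untrained_model_near_trivial_baseline(bench_volumes, small_config):
    """An untrained network scores near the all-background/all-foreground
    envelope on the phantoms (no free segmentation skill)."""
    model = CSDAUNet(small_config)
    report, _ = evaluate(model, bench_volumes[:2])
    # all-foreground baseline dice = 2*fg/(fg+1); fg ~ 1.7% of all pixels
    fg = np.mean([v.masks.mean() for v in bench_volumes[:2]])
    all_fg_dice = 2 * fg / (1 + fg)
    assert report.dice <= max(0.3, 3 * all_fg_dice)


def test_evaluate_pads_and_crops_odd_sizes(small_config):
    """Subjects smaller than the model canvas are padded in and cropped back."""
    from hippseg.phantom import PhantomParams, generate_subject
    params = PhantomParams(n_subjects=1, slices_per_subject=4, labeled_band=2,
                           image_size=(60, 52), crescent_outer_radius=(9.0, 11.0),
                           crescent_thickness=(4.0, 5.0), seed=2)
    vol = generate_subject(params, 7)
    model = CSDAUNet(small_config)
    report, per = evaluate(model, [vol])
    assert per.iloc[0]["n_slices"] == 4
    assert 0 <= report.dice <= 1


def test_run_ablation_four_variants(bench_volumes):
    """The harness trains the four attention variants under shared seeds and
    emits the metric table plus per-model CIs and paired-test columns."""
    from hippseg.training import run_ablation
    cfg = ModelConfig(**TINY_MODEL)
    tc = _tiny_tc(max_epochs=1)
    metrics, stats = run_ablation(bench_volumes[:3], bench_volumes[3:6], tc, cfg)
    assert list(metrics["Model"]) == ["U-Net", "U-Net+SA", "U-Net+ISA", "CSDA-UNet"]
    assert list(metrics.columns) == ["Model", "Precision", "Recall", "F1 Score",
                                     "Dice Coeff", "IOU"]
    assert metrics.drop(columns="Model").notna().all().all()
    assert len(stats) == 4
    for _, row in stats.iterrows():
        lo, hi = row["Dice 95% CI"]
        assert lo <= row["Dice Coeff"] <= hi
    assert np.isnan(stats.loc[stats.Model == "CSDA-UNet", "Dice p-value"]).all()


def test_split_train_val_is_subject_disjoint(bench_volumes):
    tr, val = split_train_val(bench_volumes[:10], TrainConfig(seed=1))
    assert len(val) == 1 and len(tr) == 9
    assert not {v.subject_id for v in tr} & {v.subject_id for v in val}
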