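"""Training protocol: Adam on binary cross-entropy (lr 0.001, batch 4),
early stopping and reduce-on-plateau scheduling, subject-level evaluation,
and the four-way ablation harness (U-Net / +SA / +ISA / full model).

A training sample is one slice of one subject.  When inter-slice attention
is enabled the forward pass also runs the encoder/decoder on the two
neighbouring slices (shared weights) so that gradients flow through the
attention masks; volume boundaries follow the model's boundary policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import preprocessing as pp
from .errors import ValidationError
from .metrics import (MetricReport, aggregate, confidence_interval,
                      confusion_counts, paired_t_test)
from .model import CSDAUNet, ModelConfig, binarize
from .nn import Adam, ReduceLROnPlateau, Tensor, backward
from .nn import autodiff as F
from .phantom import SubjectVolume


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 4
    max_epochs: int = 200
    loss: str = "bce"
    early_stop_patience: int = 20
    lr_schedule: str = "plateau_decay"
    lr_factor: float = 0.5
    lr_patience: int = 10
    min_lr: float = 1e-5
    seed: int = 0
    device: str = "cpu"
    augment: bool = True
    use_clahe: bool = False
    use_denoise: bool = False
    balance_empty: bool = True

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValidationError("batch_size and max_epochs must be >= 1")
        if self.loss != "bce":
            raise ValidationError("only binary cross-entropy is supported")


@dataclass
class TrainLog:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    val_iou: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(len(self.train_loss)),
            "train_loss": self.train_loss, "val_loss": self.val_loss,
            "val_dice": self.val_dice, "val_iou": self.val_iou, "lr": self.lr,
        })


def bce_loss(pred: np.ndarray, truth: np.ndarray, eps: float = 1e-12) -> float:
    """Mean binary cross-entropy of probabilities against a binary truth."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValidationError(
            f"prediction shape {pred.shape} != truth shape {truth.shape}")
    p = np.clip(pred, eps, 1.0 - eps)
    return float(-(truth * np.log(p) + (1.0 - truth) * np.log1p(-p)).mean())


# ----------------------------------------------------------- preprocessing

def _condition_subject(vol: SubjectVolume, config: ModelConfig, tc: TrainConfig
                       ) -> tuple[np.ndarray, np.ndarray, pp.PadSpec | None]:
    """Normalize (+ optional enhancement), then pad every slice onto the
    model's input canvas.  Masks only pass through the padding stage."""
    target = (config.input_height, config.input_width)
    imgs, masks, spec = [], [], None
    for i in range(vol.n_slices):
        img = pp.normalize_intensity(vol.slices[i])
        if tc.use_clahe:
            img = pp.clahe(img)
        if tc.use_denoise:
            img = pp.gaussian_denoise(img)
        if img.shape != target:
            img, spec = pp.pad_to_canvas(img, target)
            m, _ = pp.pad_to_canvas(vol.masks[i], target)
        else:
            m = vol.masks[i]
        imgs.append(img)
        masks.append(m)
    return (np.asarray(imgs, dtype=np.float32),
            np.asarray(masks, dtype=np.float32), spec)


def _select_samples(masks: np.ndarray, subject_index: int, balance: bool,
                    rng: np.random.Generator) -> list[tuple[int, int]]:
    """Slices with non-empty masks plus an equal number of empty-mask slices
    (or every slice when ``balance`` is off)."""
    s = masks.shape[0]
    labeled = np.flatnonzero(masks.reshape(s, -1).any(axis=1))
    if not balance:
        return [(subject_index, int(i)) for i in range(s)]
    empty = np.setdiff1d(np.arange(s), labeled)
    take = min(len(empty), len(labeled))
    chosen = rng.choice(empty, size=take, replace=False) if take else []
    idx = sorted(list(labeled) + [int(i) for i in chosen])
    return [(subject_index, int(i)) for i in idx]


# ------------------------------------------------------------ training loop

def _forward_batch(model: CSDAUNet, imgs: np.ndarray, masks: np.ndarray,
                   batch: list[tuple[int, int]] | None = None,
                   all_imgs: list[np.ndarray] | None = None) -> Tensor:
    """Loss of one minibatch.  ``imgs``/``masks``: stacked (B, H, W) current
    slices; when ISA is on, ``batch`` and ``all_imgs`` supply the neighbour
    slices (already conditioned) per sample."""
    cfg = model.config
    xc = Tensor(imgs[:, None])
    y = masks[:, None]
    if not cfg.isa_enabled:
        logits = model.segmentation_head(model.features(xc))
        return F.bce_with_logits(logits, y)
    prev_list, next_list, pkeep, nkeep = [], [], [], []
    for si, i in batch:
        s = all_imgs[si].shape[0]
        prev_list.append(all_imgs[si][max(i - 1, 0)])
        next_list.append(all_imgs[si][min(i + 1, s - 1)])
        pkeep.append(0.0 if (cfg.isa_boundary_policy == "zero" and i == 0) else 1.0)
        nkeep.append(0.0 if (cfg.isa_boundary_policy == "zero" and i == s - 1) else 1.0)
    fp = model.features(Tensor(np.stack(prev_list)[:, None]))
    fn = model.features(Tensor(np.stack(next_list)[:, None]))
    fc = model.features(xc)
    if cfg.isa_boundary_policy == "zero":
        keep = np.asarray(pkeep, dtype=imgs.dtype)[:, None, None, None]
        fp = F.mul(fp, Tensor(keep))
        keep = np.asarray(nkeep, dtype=imgs.dtype)[:, None, None, None]
        fn = F.mul(fn, Tensor(keep))
    fused = model.inter_slice_attention(fp, fc, fn)
    logits = model.segmentation_head(fused)
    return F.bce_with_logits(logits, y)


def train(model_config: ModelConfig, train_set: list[SubjectVolume],
          val_set: list[SubjectVolume], tc: TrainConfig
          ) -> tuple[dict[str, np.ndarray], TrainLog]:
    """Train a model and return the best-validation-loss weights and the log.

    Fully seeded: weight init from ``model_config.seed``; sampling, batch
    order and augmentation from ``tc.seed``.  Training stops when the
    validation loss has not improved for ``early_stop_patience`` epochs or at
    ``max_epochs``, whichever comes first.
    """
    if not train_set or not val_set:
        raise ValidationError("train and validation sets must be non-empty")
    train_ids = {v.subject_id for v in train_set}
    val_ids = {v.subject_id for v in val_set}
    leaked = train_ids & val_ids
    if leaked:
        raise ValidationError(f"subject leakage between train and val: {sorted(leaked)}")

    rng = np.random.default_rng(tc.seed)
    conditioned = [_condition_subject(v, model_config, tc) for v in train_set]
    all_imgs = [c[0] for c in conditioned]
    all_masks = [c[1] for c in conditioned]
    samples: list[tuple[int, int]] = []
    for si, masks in enumerate(all_masks):
        samples += _select_samples(masks, si, tc.balance_empty, rng)

    model = CSDAUNet(model_config)
    opt = Adam(model.parameters(), lr=tc.learning_rate)
    sched = (ReduceLROnPlateau(opt, tc.lr_factor, tc.lr_patience, tc.min_lr)
             if tc.lr_schedule == "plateau_decay" else None)
    log = TrainLog()
    best_val = np.inf
    best_state = model.state_dict()
    bad_epochs = 0

    for epoch in range(tc.max_epochs):
        order = rng.permutation(len(samples))
        epoch_losses = []
        for start in range(0, len(samples), tc.batch_size):
            batch = [samples[j] for j in order[start:start + tc.batch_size]]
            imgs, masks = [], []
            aug_seeds = rng.integers(0, 2 ** 31, size=len(batch))
            cur_imgs = all_imgs
            if tc.augment:
                # flips applied identically to the slice, its mask, and (via a
                # per-sample flipped copy of the subject stack) its neighbours
                cur_imgs = []
                for (si, i), sd in zip(batch, aug_seeds):
                    frng = np.random.default_rng(int(sd))
                    hflip = frng.random() < 0.5
                    vflip = frng.random() < 0.5
                    stack = all_imgs[si]
                    m = all_masks[si][i]
                    if hflip:
                        stack, m = stack[:, :, ::-1], m[:, ::-1]
                    if vflip:
                        stack, m = stack[:, ::-1, :], m[::-1, :]
                    cur_imgs.append(np.ascontiguousarray(stack))
                    imgs.append(cur_imgs[-1][i])
                    masks.append(np.ascontiguousarray(m))
                per_sample_imgs = cur_imgs
                batch_rel = [(k, i) for k, (_, i) in enumerate(batch)]
            else:
                per_sample_imgs = all_imgs
                batch_rel = batch
                for si, i in batch:
                    imgs.append(all_imgs[si][i])
                    masks.append(all_masks[si][i])
            loss = _forward_batch(model, np.stack(imgs), np.stack(masks),
                                  batch_rel, per_sample_imgs)
            opt.zero_grad()
            backward(loss)
            opt.step()
            epoch_losses.append(float(loss.data))

        vloss, vdice, viou = _validate(model, val_set, tc)
        log.train_loss.append(float(np.mean(epoch_losses)))
        log.val_loss.append(vloss)
        log.val_dice.append(vdice)
        log.val_iou.append(viou)
        log.lr.append(opt.lr)
        if vloss < best_val - 1e-9:
            best_val = vloss
            best_state = model.state_dict()
            log.best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > tc.early_stop_patience:
                log.stop_reason = "early_stop"
                break
        if sched is not None:
            sched.step(vloss)
    if not log.stop_reason:
        log.stop_reason = "max_epochs"
    return best_state, log


def _validate(model: CSDAUNet, val_set: list[SubjectVolume], tc: TrainConfig
              ) -> tuple[float, float, float]:
    losses, dices, ious = [], [], []
    for vol in val_set:
        imgs, masks, _ = _condition_subject(vol, model.config, tc)
        probs = model.forward_subject(imgs)
        losses.append(bce_loss(probs, masks))
        counts = [confusion_counts(binarize(probs[i]), masks[i].astype(np.uint8))
                  for i in range(len(probs))]
        r = aggregate(counts, "micro")
        dices.append(r.dice)
        ious.append(r.iou)
    return float(np.mean(losses)), float(np.mean(dices)), float(np.mean(ious))


# --------------------------------------------------------------- evaluation

def evaluate(model: CSDAUNet, test_set: list[SubjectVolume],
             tc: TrainConfig | None = None, threshold: float = 0.5,
             ) -> tuple[MetricReport, pd.DataFrame]:
    """Subject-level evaluation.

    Each subject is conditioned and padded to the model canvas, inferred as a
    stack, cropped back to its original size, and binarized at ``threshold``.
    Per-subject metrics come from micro-pooled counts; the summary report
    averages them across subjects (matching the paired-by-subject tests).
    Returns (summary report, per-subject metric table).
    """
    if not test_set:
        raise ValidationError("test set must be non-empty")
    tc = tc or TrainConfig()
    rows = []
    for vol in test_set:
        imgs, _, spec = _condition_subject(vol, model.config, tc)
        probs = model.forward_subject(imgs)
        counts = []
        for i in range(vol.n_slices):
            p = probs[i] if spec is None else pp.crop_back(probs[i], spec)
            counts.append(confusion_counts(binarize(p, threshold), vol.masks[i]))
        r = aggregate(counts, "micro")
        rows.append({"subject_id": vol.subject_id, "accuracy": r.accuracy,
                     "precision": r.precision, "recall": r.recall, "f1": r.f1,
                     "dice": r.dice, "iou": r.iou, "n_slices": vol.n_slices})
    per_subject = pd.DataFrame(rows)
    mean = per_subject.drop(columns=["subject_id", "n_slices"]).mean()
    report = MetricReport(accuracy=mean["accuracy"], precision=mean["precision"],
                          recall=mean["recall"], f1=mean["f1"], dice=mean["dice"],
                          iou=mean["iou"], aggregation="subject_mean",
                          n_slices=int(per_subject["n_slices"].sum()))
    return report, per_subject


# ----------------------------------------------------------------- ablation

ABLATION_VARIANTS = (
    ("U-Net", False, False),
    ("U-Net+SA", True, False),
    ("U-Net+ISA", False, True),
    ("CSDA-UNet", True, True),
)


def run_ablation(train_set: list[SubjectVolume], test_set: list[SubjectVolume],
                 tc: TrainConfig, base_config: ModelConfig,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Train and evaluate the four ablation variants with shared seeds and
    identical data order; the variants differ only in the two enable flags.

    Returns a metric table (one row per variant) and a statistics table with
    95% confidence intervals and paired-t p-values of the full model against
    each baseline on per-subject Dice and IoU.
    """
    if len(train_set) < 1 or len(test_set) < 2:
        raise ValidationError("ablation needs >= 1 train and >= 2 test subjects")
    per_subject: dict[str, pd.DataFrame] = {}
    metric_rows = []
    tr, val = split_train_val(train_set, tc)
    for name, sa, isa in ABLATION_VARIANTS:
        cfg = replace(base_config, sa_enabled=sa, isa_enabled=isa)
        weights, _ = train(cfg, tr, val, tc)
        model = CSDAUNet(cfg)
        model.load_state_dict(weights)
        report, table = evaluate(model, test_set, tc)
        per_subject[name] = table
        metric_rows.append({"Model": name, "Precision": report.precision,
                            "Recall": report.recall, "F1 Score": report.f1,
                            "Dice Coeff": report.dice, "IOU": report.iou})
    stat_rows = []
    full = per_subject["CSDA-UNet"]
    for name, _, _ in ABLATION_VARIANTS:
        table = per_subject[name]
        row = {"Model": name,
               "Dice Coeff": table["dice"].mean(),
               "Dice 95% CI": confidence_interval(table["dice"]),
               "IOU": table["iou"].mean(),
               "IoU 95% CI": confidence_interval(table["iou"])}
        if name != "CSDA-UNet" and len(table) >= 3:
            row["Dice p-value"] = paired_t_test(full["dice"], table["dice"])[1]
            row["IoU p-value"] = paired_t_test(full["iou"], table["iou"])[1]
        else:
            # the full model compared to itself, or too few subjects to test
            row["Dice p-value"] = np.nan
            row["IoU p-value"] = np.nan
        stat_rows.append(row)
    return pd.DataFrame(metric_rows), pd.DataFrame(stat_rows)


def _val_split(train_set: list[SubjectVolume], tc: TrainConfig,
               fraction: float = 0.1) -> list[SubjectVolume]:
    """Held-out validation subjects for early stopping: a seeded 10% of the
    training subjects (at least one)."""
    n = max(1, int(round(fraction * len(train_set))))
    rng = np.random.default_rng(tc.seed)
    idx = rng.choice(len(train_set), size=n, replace=False)
    return [train_set[i] for i in idx]


def split_train_val(train_set: list[SubjectVolume], tc: TrainConfig,
                    fraction: float = 0.1
                    ) -> tuple[list[SubjectVolume], list[SubjectVolume]]:
    """Subject-level train/val partition (val = seeded ``fraction``)."""
    val = _val_split(train_set, tc, fraction)
    val_ids = {v.subject_id for v in val}
    return [v for v in train_set if v.subject_id not in val_ids], val


def overfit_one_batch(model_config: ModelConfig, imgs: np.ndarray,
                      masks: np.ndarray, steps: int = 200,
                      lr: float = 1e-3) -> list[float]:
    """Drive the loss down on a single fixed batch (convergence smoke test).

    With ISA enabled each slice acts as its own neighbour triplet
    (single-slice replicate semantics).  Returns the per-step losses.
    """
    model = CSDAUNet(model_config)
    opt = Adam(model.parameters(), lr=lr)
    imgs = np.asarray(imgs, dtype=np.float32)
    masks = np.asarray(masks, dtype=np.float32)
    stacks = [imgs[i:i + 1] for i in range(len(imgs))]
    batch = [(i, 0) for i in range(len(imgs))]
    losses = []
    for _ in range(steps):
        loss = _forward_batch(model, imgs, masks, batch, stacks)
        opt.zero_grad()
        backward(loss)
        opt.step()
        losses.append(float(loss.data))
    return losses
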