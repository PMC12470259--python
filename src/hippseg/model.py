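"""Dual-attention U-Net for 2.5D hippocampus segmentation.

The network is a five-level encoder/decoder U-Net operating on single-channel
axial slices, extended with two lightweight attention operators:

* a **spatial attention** (SA) gate at the bottleneck: channel-wise max and
  average pooling produce two H x W descriptors, a single k x k convolution
  (k in {1, 3, 5, 7}, default 3) maps their concatenation to one channel, and
  a sigmoid yields a per-pixel gate in (0, 1) that multiplies the bottleneck
  features;
* an **inter-slice attention** (ISA) fusion at the decoder output: the same
  pooling/conv/sigmoid operator (with its own weights, shared between the two
  neighbours) turns the decoder features of slices i-1 and i+1 into attention
  masks, the current slice's features are multiplied by each mask, and the two
  gated maps are summed before the final 1 x 1 convolution + sigmoid head.

Disabling both modules yields a plain U-Net; the four ablation variants
(U-Net, +SA, +ISA, full model) differ only in the two enable flags, and share
identical weights for all common layers when built from the same seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, ShapeError, ValidationError
from .nn import Tensor, no_grad
from .nn import autodiff as F

_PROB_EPS = 1e-7  # keeps emitted probabilities strictly inside (0, 1)


@dataclass
class ModelConfig:
    """Every architectural switch; the ablation variants are one flag apart."""

    input_height: int = 256
    input_width: int = 256
    input_channels: int = 1
    depth: int = 5
    base_channels: int = 32
    sa_enabled: bool = True
    sa_kernel: int = 3
    isa_enabled: bool = True
    isa_boundary_policy: str = "replicate"   # or "zero"
    upsample_mode: str = "transposed_conv"   # or "interp_plus_conv"
    seed: int = 0

    def __post_init__(self):
        if self.depth < 2:
            raise ConfigurationError("depth must be >= 2")
        f = 2 ** (self.depth - 1)
        for name, v in (("input_height", self.input_height),
                        ("input_width", self.input_width)):
            if v % f != 0:
                raise ConfigurationError(
                    f"{name}={v} is not divisible by 2^(depth-1)={f}")
        if self.sa_kernel not in (1, 3, 5, 7):
            raise ConfigurationError(
                f"sa_kernel must be one of 1, 3, 5, 7 (got {self.sa_kernel})")
        if self.isa_boundary_policy not in ("replicate", "zero"):
            raise ConfigurationError(
                f"unknown isa_boundary_policy {self.isa_boundary_policy!r}")
        if self.upsample_mode not in ("transposed_conv", "interp_plus_conv"):
            raise ConfigurationError(
                f"unknown upsample_mode {self.upsample_mode!r}")
        if self.base_channels < 1 or self.input_channels < 1:
            raise ConfigurationError("channel counts must be >= 1")

    @property
    def channel_schedule(self) -> tuple[int, ...]:
        """Per-level widths: base_channels doubling at each encoder level."""
        return tuple(self.base_channels * 2 ** k for k in range(self.depth))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


class CSDAUNet:
    """U-Net with bottleneck spatial attention and decoder-end inter-slice
    attention.  Weights live in a flat name -> Tensor dict; initialization is
    He-uniform for conv kernels and zero for biases, drawn from a seeded
    generator in a fixed order (encoder, decoder, head, SA, ISA) so that the
    shared layers of every ablation variant are bit-identical for a seed.
    """

    def __init__(self, config: ModelConfig, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        self.params: dict[str, Tensor] = {}
        self._init_weights()

    # ------------------------------------------------------------- weights

    def _add_conv(self, rng, name: str, cin: int, cout: int, k: int) -> None:
        bound = np.sqrt(6.0 / (cin * k * k))
        w = rng.uniform(-bound, bound, size=(cout, cin, k, k)).astype(self.dtype)
        self.params[f"{name}_w"] = Tensor(w, requires_grad=True, name=f"{name}_w")
        self.params[f"{name}_b"] = Tensor(np.zeros(cout, dtype=self.dtype),
                                          requires_grad=True, name=f"{name}_b")

    def _add_upconv(self, rng, name: str, cin: int, cout: int) -> None:
        bound = np.sqrt(6.0 / (cin * 4))
        w = rng.uniform(-bound, bound, size=(cin, cout, 2, 2)).astype(self.dtype)
        self.params[f"{name}_w"] = Tensor(w, requires_grad=True, name=f"{name}_w")
        self.params[f"{name}_b"] = Tensor(np.zeros(cout, dtype=self.dtype),
                                          requires_grad=True, name=f"{name}_b")

    def _init_weights(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        widths = cfg.channel_schedule
        cin = cfg.input_channels
        for lvl, cout in enumerate(widths):
            self._add_conv(rng, f"enc{lvl}_conv1", cin, cout, 3)
            self._add_conv(rng, f"enc{lvl}_conv2", cout, cout, 3)
            cin = cout
        for lvl in range(cfg.depth - 2, -1, -1):
            cout = widths[lvl]
            if cfg.upsample_mode == "transposed_conv":
                self._add_upconv(rng, f"up{lvl}", cin, cout)
            else:
                self._add_conv(rng, f"up{lvl}", cin, cout, 3)
            self._add_conv(rng, f"dec{lvl}_conv1", cout * 2, cout, 3)
            self._add_conv(rng, f"dec{lvl}_conv2", cout, cout, 3)
            cin = cout
        self._add_conv(rng, "head", widths[0], 1, 1)
        if cfg.sa_enabled:
            self._add_conv(rng, "sa", 2, 1, cfg.sa_kernel)
        if cfg.isa_enabled:
            self._add_conv(rng, "isa", 2, 1, 3)

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    # ------------------------------------------------------------- forward

    def _dual_conv(self, x: Tensor, name: str) -> Tensor:
        x = F.relu(F.conv2d(x, self.params[f"{name}_conv1_w"],
                            self.params[f"{name}_conv1_b"]))
        x = F.relu(F.conv2d(x, self.params[f"{name}_conv2_w"],
                            self.params[f"{name}_conv2_b"]))
        return x

    def encode(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        """Contracting path.

        Returns the bottleneck (deepest level output, before SA) and the
        pre-pool skip feature maps of the shallower levels, shallow-first.
        """
        cfg = self.config
        n, c, h, w = x.data.shape
        if c != cfg.input_channels:
            raise ValidationError(f"expected {cfg.input_channels}-channel input, got {c}")
        f = 2 ** (cfg.depth - 1)
        for name, v in (("height", h), ("width", w)):
            if v % f != 0:
                raise ConfigurationError(
                    f"input {name}={v} is not divisible by 2^(depth-1)={f}")
        if not np.isfinite(x.data).all():
            raise ValidationError("input contains non-finite values")
        skips: list[Tensor] = []
        for lvl in range(cfg.depth - 1):
            x = self._dual_conv(x, f"enc{lvl}")
            skips.append(x)
            x = F.maxpool2x2(x)
        bottleneck = self._dual_conv(x, f"enc{cfg.depth - 1}")
        return bottleneck, skips

    def _attention_mask(self, feat: Tensor, name: str) -> Tensor:
        """Channel max+avg pooling -> concat -> conv -> sigmoid; (N,1,H,W) in (0,1)."""
        w = self.params[f"{name}_w"]
        k = w.data.shape[-1]
        if feat.data.shape[2] < k or feat.data.shape[3] < k:
            raise ConfigurationError(
                f"spatial dims {feat.data.shape[2:]} smaller than kernel {k}")
        desc = F.concat([F.channel_max(feat), F.channel_mean(feat)], axis=1)
        return F.sigmoid(F.conv2d(desc, w, self.params[f"{name}_b"]))

    def spatial_attention(self, feat: Tensor) -> Tensor:
        """Gate the bottleneck features with the SA attention map."""
        return F.mul(feat, self._attention_mask(feat, "sa"))

    def decode(self, bottleneck: Tensor, skips: list[Tensor]) -> Tensor:
        """Expanding path: 2x upsample, concatenate the matching skip, dual
        3x3 conv + ReLU per level; returns the full-resolution pre-head map."""
        cfg = self.config
        x = bottleneck
        for i, lvl in enumerate(range(cfg.depth - 2, -1, -1)):
            if cfg.upsample_mode == "transposed_conv":
                x = F.conv_transpose2x2(x, self.params[f"up{lvl}_w"],
                                        self.params[f"up{lvl}_b"])
            else:
                x = F.upsample2x_nearest(x)
                x = F.conv2d(x, self.params[f"up{lvl}_w"], self.params[f"up{lvl}_b"])
            skip = skips[lvl]
            if skip.data.shape[2:] != x.data.shape[2:]:
                raise ShapeError(
                    f"decoder level {i}: upsampled shape {x.data.shape} does not "
                    f"match skip shape {skip.data.shape}")
            x = F.concat([skip, x], axis=1)
            x = self._dual_conv(x, f"dec{lvl}")
        return x

    def segmentation_head(self, feat: Tensor) -> Tensor:
        """1x1 convolution producing per-pixel logits (sigmoid applied by
        callers that need probabilities)."""
        return F.conv2d(feat, self.params["head_w"], self.params["head_b"])

    def inter_slice_attention(self, prev: Tensor, curr: Tensor, nxt: Tensor) -> Tensor:
        """Fuse the current slice's features with attention masks derived from
        its two neighbours: (curr * M_prev) + (curr * M_next)."""
        for other, label in ((prev, "prev"), (nxt, "next")):
            if other.data.shape != curr.data.shape:
                raise ShapeError(
                    f"ISA {label} shape {other.data.shape} != curr shape {curr.data.shape}")
        m_prev = self._attention_mask(prev, "isa")
        m_next = self._attention_mask(nxt, "isa")
        return F.add(F.mul(curr, m_prev), F.mul(curr, m_next))

    def features(self, x: Tensor) -> Tensor:
        """Encoder (+SA) + decoder: input slices -> pre-head feature maps."""
        bottleneck, skips = self.encode(x)
        if self.config.sa_enabled:
            bottleneck = self.spatial_attention(bottleneck)
        return self.decode(bottleneck, skips)

    def _neighbor_feats(self, feats: Tensor, shift: int) -> Tensor:
        """Features of slice i+shift for every i, honouring the boundary policy."""
        s = feats.data.shape[0]
        idx = np.clip(np.arange(s) + shift, 0, s - 1)
        gathered = Tensor(feats.data[idx])  # inference path: no grad needed
        if self.config.isa_boundary_policy == "zero":
            out = gathered.data.copy()
            if shift < 0:
                out[0] = 0.0
            else:
                out[-1] = 0.0
            gathered = Tensor(out)
        return gathered

    def forward_subject(self, slices: np.ndarray, chunk: int = 16) -> np.ndarray:
        """Run inference over an ordered slice stack.

        Parameters
        ----------
        slices : (S, H, W) array of normalized intensities.
        chunk : number of slices per encoder/decoder minibatch.

        Returns an (S, H, W) array of probabilities strictly inside (0, 1).
        When ISA is enabled, slice i is fused with decoder features of slices
        i-1 and i+1; boundary neighbours follow ``isa_boundary_policy``.
        """
        slices = np.asarray(slices)
        if slices.ndim != 3 or slices.shape[0] == 0:
            raise ValidationError("expected a non-empty (S, H, W) slice stack")
        cfg = self.config
        with no_grad():
            feats = []
            for start in range(0, slices.shape[0], chunk):
                x = Tensor(slices[start:start + chunk, None].astype(self.dtype))
                feats.append(self.features(x).data)
            feats = Tensor(np.concatenate(feats, axis=0))
            if cfg.isa_enabled:
                fused = self.inter_slice_attention(
                    self._neighbor_feats(feats, -1), feats,
                    self._neighbor_feats(feats, +1))
            else:
                fused = feats
            probs = F.sigmoid(self.segmentation_head(fused)).data[:, 0]
        return np.clip(probs, _PROB_EPS, 1.0 - _PROB_EPS)

    # ----------------------------------------------------------- bookkeeping

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        if set(state) != set(self.params):
            missing = set(self.params) - set(state)
            extra = set(state) - set(self.params)
            raise ValidationError(
                f"checkpoint does not match config: missing={sorted(missing)}, "
                f"unexpected={sorted(extra)}")
        for k, v in state.items():
            if v.shape != self.params[k].data.shape:
                raise ShapeError(
                    f"parameter {k}: checkpoint shape {v.shape} != model shape "
                    f"{self.params[k].data.shape}")
            self.params[k].data = v.astype(self.dtype).copy()


# ------------------------------------------------------------------ helpers

def count_parameters(config: ModelConfig) -> int:
    """Total trainable scalar parameters of the configured network."""
    return sum(c for _, _, c in parameter_table(config))


def parameter_table(config: ModelConfig) -> list[tuple[str, tuple, int]]:
    """Per-parameter (name, shape, count) rows, in construction order."""
    model = CSDAUNet(config)
    return [(name, t.data.shape, int(t.data.size))
            for name, t in model.params.items()]


def binarize(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Probability map -> {0,1} mask; foreground iff p > threshold (strict)."""
    if not (0.0 < threshold < 1.0):
        raise ValidationError(f"threshold must lie in (0, 1), got {threshold}")
    return (np.asarray(probs) > threshold).astype(np.uint8)


def save_checkpoint(model: CSDAUNet, path: str | Path) -> Path:
    """Write weights as ``<path>.npz`` plus a JSON sidecar with the config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    npz = path.with_suffix(".npz")
    np.savez(npz, **model.state_dict())
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(model.config.to_dict(), indent=2))
    return npz


def load_checkpoint(path: str | Path, config: ModelConfig | None = None) -> CSDAUNet:
    """Rebuild a model from ``save_checkpoint`` output.

    If ``config`` is omitted it is read from the JSON sidecar.  Mismatched
    weights raise an explicit load error.
    """
    path = Path(path)
    npz = path.with_suffix(".npz")
    sidecar = path.with_suffix(".json")
    if not npz.exists():
        raise ValidationError(f"checkpoint not found: {npz}")
    if config is None:
        if not sidecar.exists():
            raise ValidationError(f"config sidecar not found: {sidecar}")
        config = ModelConfig.from_dict(json.loads(sidecar.read_text()))
    model = CSDAUNet(config)
    with np.load(npz) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
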