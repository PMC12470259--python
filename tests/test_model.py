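"""Architecture contracts: shape schedule, attention operators against
brute-force oracles, ablation equivalence, parameter accounting."""

import numpy as np
import pytest

from hippseg.errors import ConfigurationError, ShapeError, ValidationError
from hippseg.model import (CSDAUNet, ModelConfig, binarize, count_parameters,
                           parameter_table)
from hippseg.nn import Tensor, no_grad
from hippseg.nn import autodiff as F


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _loop_attention(feat, w, b):
    """Brute-force attention oracle: channel max/avg pool -> stack -> k x k
    same-padded conv (explicit loops) -> sigmoid."""
    c, h, wd = feat.shape
    desc = np.stack([feat.max(axis=0), feat.mean(axis=0)])
    k = w.shape[-1]
    pad = (k - 1) // 2
    dp = np.pad(desc, ((0, 0), (pad, pad), (pad, pad)))
    conv = np.zeros((h, wd))
    for i in range(h):
        for j in range(wd):
            acc = b[0]
            for ci in range(2):
                for di in range(k):
                    for dj in range(k):
                        acc += w[0, ci, di, dj] * dp[ci, i + di, j + dj]
            conv[i, j] = acc
    return _sigmoid(conv)


# --------------------------------------------------------------- shapes

def test_encoder_shape_schedule_64(small_config):
    model = CSDAUNet(small_config)
    with no_grad():
        b, skips = model.encode(Tensor(np.zeros((1, 1, 64, 64), np.float32)))
    assert [s.data.shape for s in skips] == [
        (1, 8, 64, 64), (1, 16, 32, 32), (1, 32, 16, 16), (1, 64, 8, 8)]
    assert b.data.shape == (1, 128, 4, 4)
    with no_grad():
        d = model.decode(b, skips)
    assert d.data.shape == (1, 8, 64, 64)
    with no_grad():
        head = model.segmentation_head(d)
    assert head.data.shape == (1, 1, 64, 64)


def test_zero_input_propagates_zeros(small_config):
    """Zero-initialized biases: an all-zero slice yields all-zero skips and
    bottleneck through the linear + ReLU stack."""
    model = CSDAUNet(small_config)
    with no_grad():
        b, skips = model.encode(Tensor(np.zeros((1, 1, 64, 64), np.float32)))
    assert all(np.all(s.data == 0) for s in skips)
    assert np.all(b.data == 0)


def test_encode_rejects_bad_inputs(small_config):
    model = CSDAUNet(small_config)
    with pytest.raises(ConfigurationError, match="height"):
        model.encode(Tensor(np.zeros((1, 1, 60, 64), np.float32)))
    bad = np.zeros((1, 1, 64, 64), np.float32)
    bad[0, 0, 0, 0] = np.nan
    with pytest.raises(ValidationError):
        model.encode(Tensor(bad))


def test_decode_reports_mismatched_skip(small_config):
    model = CSDAUNet(small_config)
    with no_grad():
        b, skips = model.encode(Tensor(np.zeros((1, 1, 64, 64), np.float32)))
        skips[0] = Tensor(np.zeros((1, 8, 32, 32), np.float32))
        with pytest.raises(ShapeError, match="level"):
            model.decode(b, skips)


def test_config_invariants():
    with pytest.raises(ConfigurationError):
        ModelConfig(input_height=100)      # not divisible by 16
    with pytest.raises(ConfigurationError):
        ModelConfig(sa_kernel=4)           # even kernel
    with pytest.raises(ConfigurationError):
        ModelConfig(sa_kernel=9)
    assert ModelConfig().channel_schedule == (32, 64, 128, 256, 512)
    assert ModelConfig(base_channels=8).channel_schedule == (8, 16, 32, 64, 128)


# ------------------------------------------------------------ attention

def test_spatial_attention_matches_loop_oracle(rng):
    cfg = ModelConfig(input_height=64, input_width=64, base_channels=8, seed=3)
    model = CSDAUNet(cfg)
    feat = rng.normal(size=(1, 2, 4, 4)).astype(np.float64)
    # overwrite SA weights with a fixed toy kernel; cast model to float64 path
    w = rng.normal(size=(1, 2, 3, 3))
    b = rng.normal(size=1)
    model.params["sa_w"].data = w
    model.params["sa_b"].data = b
    with no_grad():
        out = model.spatial_attention(Tensor(feat))
    expected = feat * _loop_attention(feat[0], w, b)[None, None]
    np.testing.assert_allclose(out.data, expected, atol=1e-5)


def test_attention_strictly_shrinks_magnitudes(rng, small_config):
    model = CSDAUNet(small_config)
    feat = rng.normal(size=(2, 16, 8, 8)).astype(np.float32)
    with no_grad():
        mask = model._attention_mask(Tensor(feat), "sa")
        gated = model.spatial_attention(Tensor(feat))
    assert np.all(mask.data > 0) and np.all(mask.data < 1)
    nz = feat != 0
    assert np.all(np.abs(gated.data[nz]) < np.abs(feat[nz]))
    assert gated.data.shape == feat.shape


def test_isa_mirrored_neighbors_double_the_gated_map(rng, small_config):
    model = CSDAUNet(small_config)
    curr = rng.normal(size=(1, 4, 4, 4)).astype(np.float64)
    prev = rng.normal(size=(1, 4, 4, 4)).astype(np.float64)
    with no_grad():
        fused = model.inter_slice_attention(Tensor(prev), Tensor(curr), Tensor(prev))
        mask = model._attention_mask(Tensor(prev), "isa")
    np.testing.assert_allclose(fused.data, 2 * curr * mask.data, rtol=1e-6)
    assert fused.data.shape == curr.shape


def test_isa_matches_composed_oracle(rng, small_config):
    model = CSDAUNet(small_config)
    w = rng.normal(size=(1, 2, 3, 3))
    b = rng.normal(size=1)
    model.params["isa_w"].data = w
    model.params["isa_b"].data = b
    prev = rng.normal(size=(1, 2, 4, 4))
    curr = rng.normal(size=(1, 2, 4, 4))
    nxt = rng.normal(size=(1, 2, 4, 4))
    with no_grad():
        fused = model.inter_slice_attention(Tensor(prev), Tensor(curr), Tensor(nxt))
    expected = (curr * _loop_attention(prev[0], w, b)[None, None]
                + curr * _loop_attention(nxt[0], w, b)[None, None])
    np.testing.assert_allclose(fused.data, expected, atol=1e-5)


def test_isa_rejects_mismatched_triplet(rng, small_config):
    model = CSDAUNet(small_config)
    a = Tensor(rng.normal(size=(1, 4, 4, 4)).astype(np.float32))
    bad = Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
    with pytest.raises(ShapeError):
        model.inter_slice_attention(bad, a, a)


# ------------------------------------------------------- subject forward

def test_forward_subject_contracts(rng, small_config):
    model = CSDAUNet(small_config)
    vol = rng.random((5, 64, 64)).astype(np.float32)
    probs = model.forward_subject(vol)
    assert probs.shape == (5, 64, 64)
    assert np.all(probs > 0) and np.all(probs < 1)
    # single-slice volume works under the replicate boundary policy
    single = model.forward_subject(vol[:1])
    assert single.shape == (1, 64, 64)
    with pytest.raises(ValidationError):
        model.forward_subject(np.empty((0, 64, 64)))


def test_disabling_both_modules_is_baseline_unet(rng):
    base = ModelConfig(input_height=64, input_width=64, base_channels=8,
                       sa_enabled=False, isa_enabled=False, seed=11)
    full_off = CSDAUNet(base)
    unet = CSDAUNet(ModelConfig(input_height=64, input_width=64,
                                base_channels=8, sa_enabled=False,
                                isa_enabled=False, seed=11))
    vol = rng.random((3, 64, 64)).astype(np.float32)
    np.testing.assert_array_equal(full_off.forward_subject(vol),
                                  unet.forward_subject(vol))


def test_shared_layers_identical_across_variants():
    kw = dict(input_height=64, input_width=64, base_channels=8, seed=5)
    unet = CSDAUNet(ModelConfig(sa_enabled=False, isa_enabled=False, **kw))
    full = CSDAUNet(ModelConfig(sa_enabled=True, isa_enabled=True, **kw))
    for name, t in unet.params.items():
        np.testing.assert_array_equal(t.data, full.params[name].data)


def test_forward_is_deterministic(rng, small_config):
    vol = rng.random((4, 64, 64)).astype(np.float32)
    p1 = CSDAUNet(small_config).forward_subject(vol)
    p2 = CSDAUNet(small_config).forward_subject(vol)
    np.testing.assert_array_equal(p1, p2)


# ------------------------------------------------------------ parameters

def test_parameter_count_hand_tally_tiny():
    """Independent layer-by-layer tally (k*k*Cin*Cout + Cout per conv) for a
    depth-5 width-4 model, computed here from first principles."""
    cfg = ModelConfig(input_height=32, input_width=32, base_channels=4,
                      sa_enabled=True, sa_kernel=3, isa_enabled=True)
    widths = [4, 8, 16, 32, 64]

    def conv(cin, cout, k):
        return k * k * cin * cout + cout

    expected = 0
    cin = 1
    for wdt in widths:                      # encoder: dual 3x3 per level
        expected += conv(cin, wdt, 3) + conv(wdt, wdt, 3)
        cin = wdt
    for lvl in range(3, -1, -1):            # decoder: 2x2 up + dual 3x3
        cout = widths[lvl]
        expected += 2 * 2 * cin * cout + cout
        expected += conv(2 * cout, cout, 3) + conv(cout, cout, 3)
        cin = cout
    expected += conv(widths[0], 1, 1)       # head
    expected += conv(2, 1, 3)               # SA
    expected += conv(2, 1, 3)               # ISA
    assert count_parameters(cfg) == expected


def test_parameter_count_monotone_in_width():
    assert (count_parameters(ModelConfig(base_channels=64))
            > count_parameters(ModelConfig(base_channels=32)))


def test_ablation_parameter_lattice():
    def n(sa, isa):
        return count_parameters(ModelConfig(sa_enabled=sa, isa_enabled=isa))

    unet, sa, isa, full = n(0, 0), n(1, 0), n(0, 1), n(1, 1)
    assert unet < sa <= full
    assert unet < isa <= full


def test_parameter_table_sums_to_count(small_config):
    rows = parameter_table(small_config)
    assert sum(c for _, _, c in rows) == count_parameters(small_config)


# -------------------------------------------------------------- binarize

def test_binarize_threshold_semantics():
    probs = np.full((4, 4), 0.5)
    assert binarize(probs, 0.5).sum() == 0          # strict inequality
    m = np.full((3, 3), 0.1)
    m[1, 1] = 0.9
    assert binarize(m).sum() == 1
    soft = np.random.default_rng(0).random((8, 8))
    hi, lo = binarize(soft, 0.7), binarize(soft, 0.3)
    assert np.all(lo[hi == 1] == 1)                 # mask(0.7) subset of mask(0.3)
    with pytest.raises(ValidationError):
        binarize(soft, 1.0)
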