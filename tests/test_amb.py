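"""Attention Mechanism Block: channel-mode oracle, channel-attention gates,
spatial-attention normalisation, serial composition."""

import numpy as np
import pytest
from _oracles import brute_force_mode
from hypothesis import given, settings
from hypothesis import strategies as st

from facnet import nn
from facnet.amb import (
    AttentionBlock,
    ChannelAttention,
    SpatialAttention,
    channel_mode,
)
from facnet.errors import ConfigurationError
from facnet.nn.tensor import Tensor


# ---------------------------------------------------------------------------
# channel mode
# ---------------------------------------------------------------------------

def test_mode_degenerate_range_returns_common_value():
    arr = np.full((5, 3, 3), 2.75)
    np.testing.assert_array_equal(channel_mode(arr, bins=8), np.full((1, 3, 3), 2.75))


def test_mode_hand_histogram_case():
    """(1,1,2) with 2 bins: intervals [1,1.5) and [1.5,2]; counts 2 vs 1, so
    the modal midpoint is 1.25."""
    arr = np.array([1.0, 1.0, 2.0]).reshape(3, 1, 1)
    assert channel_mode(arr, bins=2)[0, 0, 0] == pytest.approx(1.25)


def test_mode_tie_breaks_toward_smaller_midpoint():
    arr = np.array([0.0, 1.0]).reshape(2, 1, 1)  # one value per bin
    assert channel_mode(arr, bins=2)[0, 0, 0] == pytest.approx(0.25)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(c=st.sampled_from([3, 8, 64]), h=st.integers(2, 16), w=st.integers(2, 16),
       bins=st.sampled_from([2, 8, 32]), seed=st.integers(0, 2**31 - 1))
def test_mode_matches_per_pixel_histogram_oracle(c, h, w, bins, seed):
    arr = np.random.default_rng(seed).standard_normal((c, h, w)).astype(np.float32)
    np.testing.assert_allclose(channel_mode(arr, bins=bins),
                               brute_force_mode(arr, bins), rtol=0, atol=0)


def test_mode_rejects_single_bin():
    with pytest.raises(ConfigurationError):
        channel_mode(np.zeros((2, 2, 2)), bins=1)


def test_mode_is_constant_for_backprop(rng):
    t = Tensor(rng.standard_normal((1, 4, 3, 3)), requires_grad=True)
    out = channel_mode(t, bins=8)
    assert isinstance(out, Tensor)
    assert not out.requires_grad and out._parents == ()


# ---------------------------------------------------------------------------
# channel attention
# ---------------------------------------------------------------------------

def test_cam_zero_bottleneck_halves_input(rng):
    cam = ChannelAttention(16, reduction=4)
    for p in cam.parameters():
        p.data[:] = 0
    a = rng.standard_normal((2, 16, 5, 5)).astype(np.float32)
    wc, a_p = cam.forward_detail(a)
    np.testing.assert_array_equal(wc.data, np.full((2, 16, 1, 1), 0.5))
    np.testing.assert_allclose(a_p.data, a / 2, rtol=1e-6)


def test_cam_weights_bounded_and_zero_input_annihilated(rng):
    nn.manual_seed(3)
    cam = ChannelAttention(16, reduction=4)
    a = rng.standard_normal((1, 16, 4, 4)).astype(np.float32)
    wc, _ = cam.forward_detail(a)
    assert (wc.data >= 0).all() and (wc.data <= 1).all()
    _, a_p0 = cam.forward_detail(np.zeros((1, 16, 4, 4), dtype=np.float32))
    np.testing.assert_array_equal(a_p0.data, 0)


def test_cam_rejects_too_few_channels():
    with pytest.raises(ConfigurationError):
        ChannelAttention(8, reduction=16)


# ---------------------------------------------------------------------------
# spatial attention
# ---------------------------------------------------------------------------

def test_sam_constant_input_gives_uniform_softmax(rng):
    sam = SpatialAttention()
    c = 3.7
    a_p = np.full((1, 6, 4, 5), c, dtype=np.float64)
    wp, a_pp = sam.forward_detail(a_p)
    np.testing.assert_allclose(wp.data, np.full((1, 1, 4, 5), 1 / 20), rtol=1e-12)
    np.testing.assert_allclose(a_pp.data, c * (1 + 1 / 20), rtol=1e-12)


def test_sam_softmax_weights_sum_to_one(rng):
    sam = SpatialAttention()
    wp, _ = sam.forward_detail(rng.standard_normal((3, 8, 6, 6)))
    np.testing.assert_allclose(wp.data.sum(axis=(2, 3)), 1.0, rtol=1e-6)
    assert (wp.data >= 0).all()


def test_sam_sigmoid_norm_bounded(rng):
    sam = SpatialAttention(norm="sigmoid")
    wp, _ = sam.forward_detail(rng.standard_normal((1, 4, 5, 5)))
    assert (wp.data > 0).all() and (wp.data < 1).all()


def test_sam_dominant_pixel_gets_largest_weight(rng):
    a_p = np.zeros((1, 4, 6, 6))
    a_p[0, :, 2, 3] = 10.0  # max, mean and mode all peak here
    wp, _ = SpatialAttention().forward_detail(a_p)
    assert np.unravel_index(wp.data[0, 0].argmax(), (6, 6)) == (2, 3)


def test_sam_finite_under_extreme_magnitudes():
    a_p = np.array([[-1e30, 1e30], [1e30, -1e30]]).reshape(1, 1, 2, 2)
    a_p = np.repeat(a_p, 4, axis=1)
    wp, a_pp = SpatialAttention().forward_detail(a_p)
    assert np.isfinite(wp.data).all()


@pytest.mark.parametrize("stats", [("mode",), ("mode", "avg"), ("mode", "max"),
                                   ("max", "avg"), ("mode", "max", "avg")])
def test_sam_statistic_grid_constructible(rng, stats):
    """All five statistic combinations of the spatial-attention ablation are
    expressible by configuration."""
    sam = SpatialAttention(stats=stats)
    wp, a_pp = sam.forward_detail(rng.standard_normal((1, 8, 5, 5)))
    assert wp.shape == (1, 1, 5, 5) and a_pp.shape == (1, 8, 5, 5)


def test_sam_rejects_bad_stats():
    with pytest.raises(ConfigurationError):
        SpatialAttention(stats=())
    with pytest.raises(ConfigurationError):
        SpatialAttention(stats=("median",))


# ---------------------------------------------------------------------------
# serial composition
# ---------------------------------------------------------------------------

def test_amb_preserves_shape_and_composes(rng):
    nn.manual_seed(11)
    amb = AttentionBlock(64, reduction=16)
    a = rng.standard_normal((1, 64, 8, 8)).astype(np.float32)
    out = amb(a)
    assert out.shape == (1, 64, 8, 8)
    wc, a_p = amb.cam.forward_detail(nn.as_tensor(a))
    _, expected = amb.sam.forward_detail(a_p)
    np.testing.assert_array_equal(out.data, expected.data)


def test_amb_zero_input_gives_zero_output():
    nn.manual_seed(2)
    amb = AttentionBlock(32, reduction=8)
    out = amb(np.zeros((1, 32, 4, 4), dtype=np.float32))
    np.testing.assert_array_equal(out.data, 0)


def test_amb_gradient_flows_even_with_mode_only_statistic(rng):
    """With only the non-differentiable mode branch selected, gradients
    still reach the input through the gated residual path."""
    nn.manual_seed(5)
    amb = AttentionBlock(16, reduction=4, stats=("mode",))
    t = Tensor(rng.standard_normal((1, 16, 4, 4)), requires_grad=True)
    amb(t).sum().backward()
    assert t.grad is not None and np.abs(t.grad).max() > 0
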