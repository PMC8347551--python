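"""Feedback Fusion Block (FFB).

The block sits between two adjacent encoder stages.  The shallow stage
produces M (C x H x W), the deep stage produces N (2C x H/2 x W/2).  The
deep feature is fed *back* to the shallow one in two ways:

* as a per-channel weight: N is reduced by global max pooling to 2C x 1 x 1,
  projected to C channels by a 1x1 convolution and squashed to [0,1],
  giving the weight vector N' that gates a 3x3-convolved copy of M
  (M'' = M' * N');
* as a full-resolution map: N is upsampled to N'' (2C x H x W) and
  concatenated into the final fusion.

The gated map is concatenated with the original M (M''' = [M''|M],
2C x H x W), then with N'' (4C x H x W), and a 1x1 convolution restores C
channels, producing the output F that replaces the raw encoder feature on
the skip connection.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .errors import ShapeError
from .nn import functional as F
from .nn.tensor import Tensor


@dataclass
class FfbTensors:
    """All intermediates of one FFB pass (shapes relative to M = C x H x W)."""

    M: Tensor        # C x H x W        shallow input
    M_p: Tensor      # C x H x W        M' = conv3x3(M)
    M_pp: Tensor     # C x H x W        M'' = M' * N'
    M_ppp: Tensor    # 2C x H x W       M''' = [M'' | M]
    N: Tensor        # 2C x H/2 x W/2   deep input
    N_p: Tensor      # C x 1 x 1        N' = squash(conv1x1(maxpool(N)))
    N_pp: Tensor     # 2C x H x W       N'' = upsample(N)
    F: Tensor        # C x H x W        block output


class FeedbackFusionBlock(nn.Module):
    """Fuse a shallow encoder feature M with its deeper neighbour N.

    Parameters
    ----------
    channels:
        C, the channel count of the shallow input M (N must carry 2C).
    pool:
        Spatial reduction applied to N before the 1x1 projection. ``"max"``
        (default) keeps each channel's strongest response; ``"avg"`` is
        available for sensitivity checks.
    gate:
        ``"sigmoid"`` squashes N' to [0,1] before gating (default);
        ``"linear"`` leaves the projection unbounded.
    """

    def __init__(self, channels: int, pool: str = "max", gate: str = "sigmoid"):
        super().__init__()
        if pool not in ("max", "avg"):
            raise ValueError(f"pool must be 'max' or 'avg', got {pool!r}")
        if gate not in ("sigmoid", "linear"):
            raise ValueError(f"gate must be 'sigmoid' or 'linear', got {gate!r}")
        self.channels = channels
        self.pool = pool
        self.gate = gate
        self.conv_m = nn.Conv2d(channels, channels, 3, padding=1)
        self.conv_n = nn.Conv2d(2 * channels, channels, 1)
        self.conv_out = nn.Conv2d(4 * channels, channels, 1)

    def _validate(self, M: Tensor, N: Tensor) -> None:
        _, cm, h, w = M.shape
        _, cn, hn, wn = N.shape
        if cn != 2 * cm or (hn, wn) != (h // 2, w // 2) or h % 2 or w % 2:
            raise ShapeError(
                f"FFB expects N = 2C x H/2 x W/2 for M = C x H x W; "
                f"got M {tuple(M.shape[1:])} and N {tuple(N.shape[1:])}")
        if cm != self.channels:
            raise ShapeError(
                f"FFB built for C={self.channels}, got M with C={cm}")

    def forward_detail(self, M, N) -> FfbTensors:
        M, N = nn.as_tensor(M), nn.as_tensor(N)
        self._validate(M, N)
        h, w = M.shape[2:]
        # part two: deep feature -> channel weight and upsampled map
        pooled = F.global_max_pool(N) if self.pool == "max" else F.global_avg_pool(N)
        n_p = self.conv_n(pooled)
        if self.gate == "sigmoid":
            n_p = F.sigmoid(n_p)
        n_pp = F.bilinear_resize(N, (h, w))
        # part one: gate the convolved shallow feature, keep the original
        m_p = self.conv_m(M)
        m_pp = F.mul(m_p, n_p)
        m_ppp = F.concat([m_pp, M], axis=1)
        # connection: fuse both parts, restore C channels
        out = self.conv_out(F.concat([m_ppp, n_pp], axis=1))
        return FfbTensors(M=M, M_p=m_p, M_pp=m_pp, M_ppp=m_ppp,
                          N=N, N_p=n_p, N_pp=n_pp, F=out)

    def forward(self, M, N) -> Tensor:
        return self.forward_detail(M, N).F
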