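"""Independent reference implementations used as test oracles.

Everything here is deliberately written with different primitives than the
library (per-pixel loops, scipy.ndimage correlation, explicit index
formulas) so agreement is a genuine cross-check rather than a tautology.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def numeric_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar-valued f at x (float64)."""
    x = x.astype(np.float64)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp = x.copy(); xp[idx] += eps
        xm = x.copy(); xm[idx] -= eps
        g[idx] = (f(xp) - f(xm)) / (2 * eps)
    return g


def brute_force_mode(arr: np.ndarray, bins: int) -> np.ndarray:
    """Per-pixel histogram mode, pixel by pixel. arr: (C,H,W) -> (1,H,W)."""
    c, h, w = arr.shape
    out = np.zeros((1, h, w), dtype=arr.dtype)
    for i in range(h):
        for j in range(w):
            vals = arr[:, i, j].astype(np.float64)
            lo, hi = vals.min(), vals.max()
            if hi == lo:
                out[0, i, j] = lo
                continue
            counts = [0] * bins
            for v in vals:
                b = int((v - lo) / (hi - lo) * bins)
                counts[min(b, bins - 1)] += 1
            best = max(range(bins), key=lambda b: (counts[b], -b))
            out[0, i, j] = lo + (best + 0.5) * (hi - lo) / bins
    return out


def conv2d_same(x: np.ndarray, w: np.ndarray, b: np.ndarray | None) -> np.ndarray:
    """Stride-1 'same' cross-correlation via scipy.ndimage, one channel pair
    at a time.  x: (N,C,H,W), w: (Cout,Cin,k,k)."""
    n, cin, h, wid = x.shape
    cout = w.shape[0]
    out = np.zeros((n, cout, h, wid))
    for ni in range(n):
        for o in range(cout):
            acc = np.zeros((h, wid))
            for c in range(cin):
                acc += ndimage.correlate(x[ni, c].astype(np.float64),
                                         w[o, c].astype(np.float64),
                                         mode="constant", cval=0.0)
            out[ni, o] = acc + (0.0 if b is None else b[o])
    return out


def conv1x1(x: np.ndarray, w: np.ndarray, b: np.ndarray | None) -> np.ndarray:
    """x: (N,C,H,W), w: (Cout,Cin,1,1)."""
    out = np.einsum("nchw,oc->nohw", x.astype(np.float64), w[:, :, 0, 0])
    if b is not None:
        out += b.reshape(1, -1, 1, 1)
    return out


def bilinear_up2(x: np.ndarray) -> np.ndarray:
    """x2 bilinear upsampling, half-pixel centres, clamped edges; explicit
    per-output-pixel formula. x: (N,C,H,W)."""
    n, c, h, w = x.shape
    out = np.zeros((n, c, 2 * h, 2 * w))
    for oy in range(2 * h):
        sy = (oy + 0.5) / 2 - 0.5
        y0 = int(np.floor(sy))
        fy = sy - y0
        y0c, y1c = min(max(y0, 0), h - 1), min(max(y0 + 1, 0), h - 1)
        for ox in range(2 * w):
            sx = (ox + 0.5) / 2 - 0.5
            x0 = int(np.floor(sx))
            fx = sx - x0
            x0c, x1c = min(max(x0, 0), w - 1), min(max(x0 + 1, 0), w - 1)
            out[:, :, oy, ox] = (
                x[:, :, y0c, x0c] * (1 - fy) * (1 - fx)
                + x[:, :, y0c, x1c] * (1 - fy) * fx
                + x[:, :, y1c, x0c] * fy * (1 - fx)
                + x[:, :, y1c, x1c] * fy * fx)
    return out


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def ffb_pipeline(block, m: np.ndarray, n: np.ndarray) -> dict[str, np.ndarray]:
    """Hand-composed eight-step feedback-fusion pipeline (Conv3x3, multiply,
    concat, global max pool, conv1x1, upsample, concat, conv1x1) using the
    block's weights but none of its code paths."""
    w_m = block.conv_m.weight.data
    b_m = block.conv_m.bias.data
    w_n = block.conv_n.weight.data
    b_n = block.conv_n.bias.data
    w_o = block.conv_out.weight.data
    b_o = block.conv_out.bias.data
    m_p = conv2d_same(m, w_m, b_m)                       # Conv3x3
    pooled = n.max(axis=(2, 3), keepdims=True)           # global max pool
    n_p = conv1x1(pooled, w_n, b_n)                      # Conv1x1
    if block.gate == "sigmoid":
        n_p = sigmoid(n_p)
    n_pp = bilinear_up2(n)                               # Up-sampling
    m_pp = m_p * n_p                                     # element-wise multiply
    m_ppp = np.concatenate([m_pp, m], axis=1)            # Concat (part one)
    fused = np.concatenate([m_ppp, n_pp], axis=1)        # Concat (connection)
    out = conv1x1(fused, w_o, b_o)                       # Conv1x1
    return {"M_p": m_p, "N_p": n_p, "N_pp": n_pp, "M_pp": m_pp,
            "M_ppp": m_ppp, "F": out}
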