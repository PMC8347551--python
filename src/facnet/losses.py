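"""Dice loss, the training objective.

L = 1 - (2 * sum_i y_i p_i + eps) / (sum_i y_i + sum_i p_i + eps)

summed over every pixel in the batch; y_i is the binary ground truth, p_i
the predicted probability.  The smoothing constant eps (default 1) defines
the all-empty case: a perfect empty prediction scores loss 0 instead of
0/0.  With eps = 0 the loss is the literal complement of the Dice
coefficient.
"""

from __future__ import annotations

import numpy as np

from .errors import ShapeError
from .nn import functional as F
from .nn.tensor import Tensor, as_tensor


def dice_loss(pred, gt, smooth: float = 1.0):
    """Soft Dice loss over a batch.

    Accepts Tensors (differentiable) or arrays; returns a scalar of the same
    flavour.  ``pred`` must lie in [0,1] and ``gt`` must be binary.
    """
    pred_t = pred if isinstance(pred, Tensor) else as_tensor(np.asarray(pred, dtype=float))
    gt_arr = gt.data if isinstance(gt, Tensor) else np.asarray(gt)
    if pred_t.shape != gt_arr.shape:
        raise ShapeError(
            f"prediction shape {tuple(pred_t.shape)} != ground truth shape "
            f"{tuple(gt_arr.shape)}")
    pd = pred_t.data
    if pd.min() < 0 or pd.max() > 1:
        raise ValueError("predicted probabilities must lie in [0, 1]")
    if not np.isin(gt_arr, (0, 1)).all():
        raise ValueError("ground truth must be binary (0/1)")
    gt_t = as_tensor(gt_arr.astype(pd.dtype))
    inter = F.sum(F.mul(pred_t, gt_t))
    denom = F.add(F.sum(pred_t), F.sum(gt_t))
    loss = 1.0 - (2.0 * inter + smooth) / (denom + smooth)
    return loss if isinstance(pred, Tensor) else loss.item()
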