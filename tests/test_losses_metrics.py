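"""Dice loss and the six confusion-count metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from facnet.errors import ShapeError
from facnet.losses import dice_loss
from facnet.metrics import (
    ConfusionCounts,
    confusion,
    evaluate_set,
    metrics,
    report_table,
)
from facnet.nn.tensor import Tensor


# ---------------------------------------------------------------------------
# dice loss
# ---------------------------------------------------------------------------

def test_dice_loss_perfect_overlap_is_zero(rng):
    gt = (rng.random((2, 1, 8, 8)) > 0.6).astype(float)
    assert dice_loss(gt, gt, smooth=0.0) == pytest.approx(0.0)


def test_dice_loss_empty_prediction_is_one(rng):
    gt = np.zeros((1, 1, 8, 8)); gt[0, 0, :3, :3] = 1
    assert dice_loss(np.zeros_like(gt), gt, smooth=0.0) == pytest.approx(1.0)


def test_dice_loss_disjoint_sets_is_one():
    pred = np.zeros((1, 1, 4, 4)); pred[0, 0, 0, :2] = 1
    gt = np.zeros((1, 1, 4, 4)); gt[0, 0, 3, :3] = 1
    assert dice_loss(pred, gt, smooth=0.0) == pytest.approx(1.0)


def test_dice_loss_smoothing_defines_all_empty_case():
    z = np.zeros((1, 1, 4, 4))
    assert dice_loss(z, z, smooth=1.0) == pytest.approx(0.0)


def test_dice_loss_decreases_as_mispredicted_pixel_improves():
    gt = np.zeros((1, 1, 2, 2)); gt[0, 0, 0, 0] = 1
    losses = []
    for p in np.linspace(0.05, 0.95, 10):
        pred = np.full_like(gt, 0.0); pred[0, 0, 0, 0] = p
        losses.append(dice_loss(pred, gt))
    assert all(a > b for a, b in zip(losses, losses[1:]))


def test_dice_loss_validates_inputs(rng):
    gt = np.zeros((1, 1, 4, 4))
    with pytest.raises(ShapeError):
        dice_loss(np.zeros((1, 1, 4, 5)), gt)
    with pytest.raises(ValueError):
        dice_loss(np.full((1, 1, 4, 4), 1.5), gt)
    with pytest.raises(ValueError):
        dice_loss(np.zeros((1, 1, 4, 4)), np.full((1, 1, 4, 4), 0.5))


def test_dice_loss_is_differentiable(rng):
    pred = Tensor(rng.random((1, 1, 6, 6)), requires_grad=True)
    gt = (rng.random((1, 1, 6, 6)) > 0.5).astype(float)
    loss = dice_loss(pred, gt)
    loss.backward()
    assert pred.grad is not None and np.isfinite(pred.grad).all()
    # gradient pushes predictions toward the labels
    assert (pred.grad[gt == 1] < 0).all()


# ---------------------------------------------------------------------------
# confusion + metrics
# ---------------------------------------------------------------------------

def test_confusion_enumerated_two_by_two():
    pred = np.array([[1, 1], [0, 0]])
    gt = np.array([[1, 0], [1, 0]])
    c = confusion(pred, gt)
    assert (c.TP, c.FP, c.FN, c.TN) == (1, 1, 1, 1)


def test_confusion_identity_and_complement(rng):
    gt = (rng.random((16, 16)) > 0.5).astype(np.uint8)
    same = confusion(gt, gt)
    assert same.FP == same.FN == 0
    comp = confusion(1 - gt, gt)
    assert comp.TP == comp.TN == 0


def test_confusion_rejects_non_binary():
    with pytest.raises(ValueError):
        confusion(np.array([[0.5]]), np.array([[1]]))


@pytest.mark.parametrize("counts,expected", [
    (ConfusionCounts(TP=3, FP=0, TN=0, FN=1), {"SE": 0.75}),
    (ConfusionCounts(TP=1, FP=1, TN=0, FN=0), {"JA": 0.5, "DC": 2 / 3}),
    (ConfusionCounts(TP=1, FP=1, TN=1, FN=1),
     {"ACC": 0.5, "SE": 0.5, "SP": 0.5, "PC": 0.5, "JA": 1 / 3, "DC": 0.5}),
])
def test_metric_formulas_on_hand_cases(counts, expected):
    rep = metrics(counts)
    for name, val in expected.items():
        assert getattr(rep, name) == pytest.approx(val)


def test_all_zero_counts_marks_metrics_undefined():
    rep = metrics(ConfusionCounts(0, 0, 0, 0))
    assert all(math.isnan(getattr(rep, m)) for m in ("SE", "SP", "PC", "JA", "DC", "ACC"))


@settings(deadline=None, max_examples=200, derandomize=True)
@given(tp=st.integers(0, 10**6), fp=st.integers(0, 10**6),
       tn=st.integers(0, 10**6), fn=st.integers(0, 10**6))
def test_jaccard_dice_identity_and_bounds(tp, fp, tn, fn):
    rep = metrics(ConfusionCounts(tp, fp, tn, fn))
    vals = rep.as_dict()
    for v in vals.values():
        assert math.isnan(v) or 0 <= v <= 1
    if not math.isnan(vals["JA"]):
        assert vals["DC"] == pytest.approx(2 * vals["JA"] / (1 + vals["JA"]))
        assert vals["JA"] <= vals["DC"] + 1e-12


# ---------------------------------------------------------------------------
# set-level evaluation
# ---------------------------------------------------------------------------

def test_evaluate_set_perfect_predictions(rng):
    gts = [(rng.random((1, 8, 8)) > 0.5).astype(np.uint8) for _ in range(3)]
    mean, pooled, table = evaluate_set([g.astype(float) for g in gts], gts)
    for m in ("SE", "SP", "PC", "JA", "DC", "ACC"):
        assert getattr(mean, m) == pytest.approx(1.0)
        assert getattr(pooled, m) == pytest.approx(1.0)
    assert len(table) == 3


def test_evaluate_set_single_image_equals_direct_metrics(rng):
    gt = (rng.random((1, 8, 8)) > 0.5).astype(np.uint8)
    prob = rng.random((1, 8, 8))
    mean, pooled, _ = evaluate_set([prob], [gt])
    direct = metrics(confusion((prob >= 0.5).astype(np.uint8), gt))
    assert mean == direct and pooled == direct


def test_evaluate_set_mean_is_arithmetic():
    gt1 = np.zeros((1, 2, 2), dtype=np.uint8); gt1[0, 0] = 1
    pred1 = np.zeros((1, 2, 2)); pred1[0, 0, 0] = 1.0  # TP=1, FN=1 -> JA=0.5
    gt2 = gt1.copy()
    pred2 = gt2.astype(float)                           # JA=1.0
    mean, _, _ = evaluate_set([pred1, pred2], [gt1, gt2])
    assert mean.JA == pytest.approx(0.75)


def test_evaluate_set_rejects_empty_and_bad_threshold():
    with pytest.raises(ValueError):
        evaluate_set([], [])
    gt = np.ones((1, 2, 2), dtype=np.uint8)
    with pytest.raises(ValueError):
        evaluate_set([gt.astype(float)], [gt], threshold=1.5)


def test_report_table_layout(rng):
    rep = metrics(ConfusionCounts(TP=1, FP=1, TN=1, FN=1))
    table = report_table({"model-a": rep})
    assert list(table.columns) == ["ACC", "SE", "SP", "PC", "JA", "DC"]
    assert table.loc["model-a", "DC"] == "50.00"
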