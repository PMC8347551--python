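"""Training loop, evaluation, ablation harness and mask prediction.

Training follows the published recipe: Kaiming-initialised weights, the
adaptive-moment (Adam) optimiser, Dice loss, defaults of learning rate
1e-4, batch size 12 and 200 epochs.  Model selection keeps the checkpoint
with the best validation Jaccard index.  Every source of randomness
(initialisation, shuffling) derives from ``TrainConfig.seed``, so a run is
exactly reproducible.
"""

from __future__ import annotations

import copy
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import nn
from .backbone import ModelConfig, SegmentationModel, build_model, save_checkpoint
from .errors import ConfigurationError
from .losses import dice_loss
from .metrics import METRIC_ORDER, MetricsReport, evaluate_set, report_table
from .nn.optim import Adam


@dataclass
class TrainConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    learning_rate: float = 1e-4
    batch_size: int = 12
    epochs: int = 200
    seed: int = 0
    threshold: float = 0.5
    early_stop_ja: float | None = None  # stop once val JA reaches this

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigurationError(
                f"learning_rate must be > 0, got {self.learning_rate}")
        if self.batch_size < 1 or self.epochs < 0:
            raise ConfigurationError("batch_size >= 1 and epochs >= 0 required")


def _batches(samples, batch_size, order):
    for start in range(0, len(order), batch_size):
        idx = order[start:start + batch_size]
        images = np.stack([samples[i].image for i in idx])
        masks = np.stack([samples[i].mask for i in idx]).astype(np.float32)
        yield images, masks


def _forward_set(model: SegmentationModel, samples, batch_size: int = 12):
    """Probability maps for a sample list, without building a graph."""
    model.eval()
    preds = []
    with nn.no_grad():
        for images, _ in _batches(samples, batch_size,
                                  np.arange(len(samples))):
            preds.extend(model(images).data)
    return preds


def evaluate(model: SegmentationModel, samples, threshold: float = 0.5,
             batch_size: int = 12):
    """Per-image-mean metrics of a model over a sample list.

    Returns ``(mean_report, pooled_report, per_image_table)``.
    """
    preds = _forward_set(model, samples, batch_size)
    gts = [s.mask for s in samples]
    return evaluate_set(preds, gts, threshold=threshold)


def train(config: TrainConfig, train_samples, val_samples,
          checkpoint_path=None, verbose: bool = False
          ) -> tuple[SegmentationModel, pd.DataFrame]:
    """Train a FAC-Net variant; returns the best-validation-JA model and the
    per-epoch history (train loss, validation JA/DC)."""
    if not train_samples:
        raise ConfigurationError("training split is empty")
    model = build_model(config.model, seed=config.seed)
    rng = np.random.default_rng(config.seed + 1)
    params = list(model.parameters())
    opt = Adam(params, lr=config.learning_rate)
    best_state = model.state_dict()
    best_ja = -1.0
    history = []
    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(len(train_samples))
        losses = []
        t0 = time.time()
        for step, (images, masks) in enumerate(
                _batches(train_samples, config.batch_size, order)):
            opt.zero_grad()
            pred = model(images)
            loss = dice_loss(pred, masks)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite Dice loss at epoch {epoch}, step {step}")
            loss.backward()
            opt.step()
            losses.append(loss.item())
        row = {"epoch": epoch, "train_loss": float(np.mean(losses)),
               "seconds": time.time() - t0}
        if val_samples:
            mean_rep, _, _ = evaluate(model, val_samples,
                                      threshold=config.threshold,
                                      batch_size=config.batch_size)
            row["val_JA"] = mean_rep.JA
            row["val_DC"] = mean_rep.DC
            if mean_rep.JA > best_ja:
                best_ja = mean_rep.JA
                best_state = copy.deepcopy(model.state_dict())
        history.append(row)
        if verbose:
            print("  ".join(f"{k}={v:.4f}" if isinstance(v, float) else f"{k}={v}"
                            for k, v in row.items()))
        if (config.early_stop_ja is not None and val_samples
                and row["val_JA"] >= config.early_stop_ja):
            break
    if val_samples and best_ja >= 0:
        model.load_state_dict(best_state)
    model.eval()
    history_df = pd.DataFrame(history)
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, model,
                        extra={"best_val_ja": best_ja, "seed": config.seed})
    return model, history_df


MODULE_VARIANTS = {
    "CE-Net": dict(use_ffb=False, use_amb=False),
    "CE-Net+FFB": dict(use_ffb=True, use_amb=False),
    "CE-Net+AMB": dict(use_ffb=False, use_amb=True),
    "CE-Net+FFB+AMB": dict(use_ffb=True, use_amb=True),
}

SAM_VARIANTS = {
    "Mode": ("mode",),
    "Mode+Avg": ("mode", "avg"),
    "Mode+Max": ("mode", "max"),
    "Max+Avg": ("max", "avg"),
    "Mode+Max+Avg": ("mode", "max", "avg"),
}


def run_ablation(base: TrainConfig, train_samples, val_samples, test_samples,
                 grid: str = "modules", verbose: bool = False
                 ) -> tuple[pd.DataFrame, dict[str, MetricsReport]]:
    """Train and evaluate a variant grid under identical seed and settings.

    ``grid="modules"`` runs the four backbone/FFB/AMB combinations;
    ``grid="sam_stats"`` runs the five spatial-attention statistic
    combinations (all with FFB+AMB enabled).  Returns a percentage table in
    the standard metric column order plus the raw reports.
    """
    if grid == "modules":
        variants = {name: replace(base.model, **kw)
                    for name, kw in MODULE_VARIANTS.items()}
    elif grid == "sam_stats":
        variants = {name: replace(base.model, use_ffb=True, use_amb=True,
                                  sam_stats=stats)
                    for name, stats in SAM_VARIANTS.items()}
    else:
        raise ConfigurationError(f"unknown ablation grid {grid!r}")
    reports: dict[str, MetricsReport] = {}
    for name, mcfg in variants.items():
        cfg = replace(base, model=mcfg)
        if verbose:
            print(f"[ablation] {name}")
        model, _ = train(cfg, train_samples, val_samples, verbose=verbose)
        mean_rep, _, _ = evaluate(model, test_samples, threshold=cfg.threshold,
                                  batch_size=cfg.batch_size)
        reports[name] = mean_rep
    return report_table(reports), reports


def predict(model: SegmentationModel, image_paths, out_dir,
            size: int = 256, threshold: float = 0.5,
            batch_size: int = 12) -> list[Path]:
    """Segment images and write one bilevel PNG mask per input (255 =
    lesion), at each input's original resolution."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model.eval()
    written = []
    for path in map(Path, image_paths):
        img = Image.open(path).convert("RGB")
        orig_size = img.size  # (W, H)
        arr = np.asarray(img.resize((size, size), Image.BILINEAR),
                         dtype=np.float32).transpose(2, 0, 1) / 255.0
        with nn.no_grad():
            prob = model(arr[None]).data[0, 0]
        prob_img = Image.fromarray((prob * 255).astype(np.uint8)) \
            .resize(orig_size, Image.BILINEAR)
        mask = (np.asarray(prob_img) >= threshold * 255).astype(np.uint8) * 255
        out_path = out_dir / f"{path.stem}_mask.png"
        Image.fromarray(mask).save(out_path)
        written.append(out_path)
    return written
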