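# facnet

Skin-lesion segmentation for dermoscopy images with **FAC-Net**: a
CE-Net-style encoder/decoder augmented with a *Feedback Fusion Block*
(FFB) between adjacent encoder stages and an *Attention Mechanism Block*
(AMB) after each decoder skip fusion. The package is aimed at medical
image analysis practitioners who want a fully inspectable, dependency-light
implementation of the architecture, its Dice-loss training recipe, the
six-metric evaluation protocol (ACC/SE/SP/PC/JA/DC), the ISIC/ISBI dataset
split conventions, and an ablation harness — all runnable on a laptop CPU
thanks to a synthetic dermoscopy generator, with no dataset download.

## The model

The encoder produces a four-stage pyramid (channels C, 2C, 4C, 8C at
resolutions H/4 … H/32). Between each adjacent pair (M ∈ ℝ^{C×H×W},
N ∈ ℝ^{2C×H/2×W/2}) the FFB feeds the deep feature back into the shallow
one:

    N′  = σ(Conv1×1(GlobalMaxPool(N)))        ∈ ℝ^{C×1×1}
    M′′ = Conv3×3(M) ⊙ N′                     (channel-wise gating)
    F   = Conv1×1([ M′′ | M | Upsample₂(N) ]) ∈ ℝ^{C×H×W}

and F replaces M on the skip connection. After each decoder skip fusion
the AMB applies squeeze-excite channel attention, then a spatial attention
whose per-position statistics across channels are the **max**, the
**mean**, and — the distinctive ingredient — the histogram **mode**
(per-pixel equal-width binning, 32 bins). The three maps are summed,
softmax-normalised over positions into WP ∈ ℝ^{1×H×W}, and applied as a
gated residual A′′ = A′ + WP ⊙ A′. Training minimises the Dice loss
1 − 2Σyᵢpᵢ/(Σyᵢ+Σpᵢ) with Adam (lr 1e-4, batch 12, 200 epochs at full
scale).

The whole network runs on a small NumPy reverse-mode autodiff engine
(`facnet.nn`) whose every primitive is gradient-checked in the test suite;
see `docs/methods.md` for the scientific and numerical details.

## Worked example

```python
from facnet import ModelConfig, TrainConfig, SynthConfig
from facnet import generate, train, evaluate

samples = generate(SynthConfig(n_images=260, image_size=64, seed=1, contrast=0.5))
tr, va, te = samples[:200], samples[200:210], samples[210:]

cfg = TrainConfig(model=ModelConfig(use_ffb=True, use_amb=True, base_width=16),
                  learning_rate=1e-3, batch_size=12, epochs=30, seed=1,
                  early_stop_ja=0.9)
model, history = train(cfg, tr, va, verbose=True)
mean_report, pooled, per_image = evaluate(model, te)
print(f"test JA={100*mean_report.JA:.2f}%  DC={100*mean_report.DC:.2f}%")
```

prints (after six epochs of per-epoch progress lines):

```
epoch=5  train_loss=0.3154  seconds=5.85  val_JA=0.9036  val_DC=0.9490
test JA=89.48%  DC=94.41%
```

i.e. on held-out synthetic lesions the trained network overlaps the ground
truth at Jaccard ≈ 0.89 / Dice ≈ 0.94, versus Jaccard ≈ 0.15 for the
untrained initialisation. The same workflow runs from the shell:

```
facnet synth --out data/ --n 260 --size 64 --seed 1
facnet split --data data/ --out split.tsv
facnet train --data data/ --manifest split.tsv --config cfg.yaml \
             --size 64 --checkpoint model.npz
facnet eval  --data data/ --manifest split.tsv --checkpoint model.npz --size 64
facnet ablate --data data/ --manifest split.tsv --config cfg.yaml --size 64
facnet predict --checkpoint model.npz --out masks/ image1.jpg image2.jpg
```

`facnet ablate` trains the four module combinations (backbone, +FFB, +AMB,
full) — or, with `--grid sam_stats`, the five spatial-statistic
combinations (Mode, Mode+Avg, Mode+Max, Max+Avg, Mode+Max+Avg) — under
identical seeds and emits the standard six-column percentage table.

Real data uses the same commands: point `--data` at an ISIC-layout folder
(`images/*.jpg`, `masks/*_segmentation.png`) and pick the matching
`--dataset` split protocol (`isic2018` 70/10/20, `isbi2017`/`isbi2016`
train pool + 1:4 val:test from the test pool).

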