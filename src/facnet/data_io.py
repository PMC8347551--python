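"""Reading ISIC-style dermoscopy folders and building the train/val/test
splits used by the three challenge datasets.

Expected layout (the ISIC convention)::

    <root>/images/<id>.jpg
    <root>/masks/<id>_segmentation.png

Images are resized bilinearly to a common resolution (256 x 256 by
default) and scaled to [0,1]; masks are resized by nearest neighbour (so
they stay binary) and thresholded at 128/255.

Split protocol:

* ``isic2018`` — the 2594 annotated training images are shuffled and
  partitioned 70/10/20 % into train/val/test.
* ``isbi2017`` — the 2000 training images form the training set; the 600
  test images are shuffled and split 1:4 into val:test.
* ``isbi2016`` — the 900 training images form the training set; the 379
  test images are split 1:4 into val:test.

Earlier partitions are rounded down; the remainder goes to the last.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import ConfigurationError

DATASET_SIZES = {
    "isic2018": {"train_pool": 2594},
    "isbi2017": {"train_pool": 2000, "test_pool": 600},
    "isbi2016": {"train_pool": 900, "test_pool": 379},
}


@dataclass
class SegmentationSample:
    """A paired image (3,S,S in [0,1]) and binary mask (1,S,S in {0,1})."""

    image: np.ndarray
    mask: np.ndarray
    identifier: str = ""


@dataclass
class DatasetSplit:
    train: list[str] = field(default_factory=list)
    val: list[str] = field(default_factory=list)
    test: list[str] = field(default_factory=list)
    seed: int = 42

    def partitions(self):
        return {"train": self.train, "val": self.val, "test": self.test}


def load_sample(image_path, mask_path, size: int = 256) -> SegmentationSample:
    """Load one image/mask pair, resized to ``size`` x ``size``."""
    image_path, mask_path = Path(image_path), Path(mask_path)
    for p, what in ((image_path, "image"), (mask_path, "mask")):
        if not p.exists():
            raise FileNotFoundError(f"{what} file not found: {p}")
    try:
        img = Image.open(image_path).convert("RGB")
    except UnidentifiedImageError as e:
        raise ValueError(f"cannot decode image {image_path}: {e}") from e
    try:
        msk = Image.open(mask_path).convert("L")
    except UnidentifiedImageError as e:
        raise ValueError(f"cannot decode mask {mask_path}: {e}") from e
    img = img.resize((size, size), Image.BILINEAR)
    msk = msk.resize((size, size), Image.NEAREST)
    image = np.asarray(img, dtype=np.float32).transpose(2, 0, 1) / 255.0
    mask = (np.asarray(msk) >= 128).astype(np.uint8)[None]
    return SegmentationSample(image=image, mask=mask,
                              identifier=image_path.stem)


def discover_pairs(root) -> list[tuple[Path, Path]]:
    """List (image, mask) path pairs under an ISIC-style folder."""
    root = Path(root)
    pairs = []
    for img in sorted((root / "images").glob("*.jpg")):
        mask = root / "masks" / f"{img.stem}_segmentation.png"
        if not mask.exists():
            raise FileNotFoundError(f"missing mask for {img}: expected {mask}")
        pairs.append((img, mask))
    return pairs


def load_folder(root, size: int = 256) -> list[SegmentationSample]:
    return [load_sample(i, m, size=size) for i, m in discover_pairs(root)]


def _floor_split(ids: list[str], fracs: list[float]) -> list[list[str]]:
    n = len(ids)
    sizes = [int(np.floor(f * n)) for f in fracs[:-1]]
    sizes.append(n - sum(sizes))
    parts, start = [], 0
    for s in sizes:
        parts.append(list(ids[start:start + s]))
        start += s
    return parts


def make_split(dataset_name: str, identifiers, seed: int = 42,
               test_identifiers=None) -> DatasetSplit:
    """Partition sample identifiers according to a dataset's protocol.

    For ``isic2018`` pass the training-pool identifiers; for the ISBI
    datasets pass the training pool as ``identifiers`` and the test pool as
    ``test_identifiers``.  A count differing from the published dataset size
    triggers a warning (datasets have been re-released over time), not an
    error.
    """
    if dataset_name not in DATASET_SIZES:
        raise ConfigurationError(
            f"unknown dataset {dataset_name!r}; expected one of "
            f"{sorted(DATASET_SIZES)}")
    rng = np.random.default_rng(seed)
    identifiers = list(identifiers)
    expected = DATASET_SIZES[dataset_name]
    if len(identifiers) != expected["train_pool"]:
        warnings.warn(
            f"{dataset_name}: {len(identifiers)} training identifiers, "
            f"published count is {expected['train_pool']}", stacklevel=2)
    if dataset_name == "isic2018":
        shuffled = list(rng.permutation(identifiers))
        train, val, test = _floor_split(shuffled, [0.7, 0.1, 0.2])
    else:
        if test_identifiers is None:
            raise ConfigurationError(
                f"{dataset_name} needs test_identifiers (its val/test come "
                "from the challenge test pool)")
        test_identifiers = list(test_identifiers)
        if len(test_identifiers) != expected["test_pool"]:
            warnings.warn(
                f"{dataset_name}: {len(test_identifiers)} test identifiers, "
                f"published count is {expected['test_pool']}", stacklevel=2)
        train = identifiers
        shuffled = list(rng.permutation(test_identifiers))
        val, test = _floor_split(shuffled, [0.2, 0.8])
    return DatasetSplit(train=train, val=val, test=test, seed=seed)


def write_manifest(split: DatasetSplit, path) -> None:
    """Write the split as a two-column TSV (identifier, partition)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# seed={split.seed}\n")
        for part, ids in split.partitions().items():
            for i in ids:
                fh.write(f"{i}\t{part}\n")


def read_manifest(path) -> DatasetSplit:
    split = DatasetSplit()
    for line in Path(path).read_text().splitlines():
        if line.startswith("# seed="):
            split.seed = int(line.split("=", 1)[1])
            continue
        if not line.strip():
            continue
        ident, part = line.rsplit("\t", 1)
        getattr(split, part).append(ident)
    return split
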