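"""Automatic cutting of detections into labelled crops and dataset assembly.

Each detection rectangle is expanded by a margin, clamped to the image,
extracted and resized to exactly 255 x 255 x 3. Stage labels are encoded
0 (VE), 1 (VC), 2 (V1). Five augmentation operators — brightness,
horizontal flip, saturation, random cropping and scaling — expand the
originals; classes are balanced by augmentation multiplicity and split
3:1 into train/test, stratified per class with a seeded shuffle.

The dataset manifest stores augmentation *recipes* (source crop, operator,
seed), not pixels, so large layouts can be planned and audited cheaply and
materialised deterministically on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from PIL import Image

from .detect import Detection, FieldImage

__all__ = [
    "CROP_SIZE",
    "AUG_OPS",
    "SeedlingCrop",
    "ManifestEntry",
    "DatasetManifest",
    "cut_crop",
    "augment",
    "build_dataset",
    "materialize_entry",
    "manifest_arrays",
]

CROP_SIZE = 255
AUG_OPS = ("brightness", "hflip", "saturation", "random_crop", "scale")

# documented parameter ranges for the seeded augmentation draws
BRIGHTNESS_RANGE = (0.7, 1.3)
SATURATION_RANGE = (0.7, 1.3)
RANDOM_CROP_MIN_AREA = 0.80
SCALE_RANGE = (0.8, 1.2)


@dataclass
class SeedlingCrop:
    pixels: np.ndarray  # exactly (255, 255, 3) uint8
    label: int          # 0=VE, 1=VC, 2=V1
    source: Optional[str] = None
    detection_index: Optional[int] = None
    augmentation: Optional[str] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.shape != (CROP_SIZE, CROP_SIZE, 3):
            raise ValueError(
                f"crop must be {CROP_SIZE}x{CROP_SIZE}x3, got {self.pixels.shape}")
        if self.label not in (0, 1, 2):
            raise ValueError(f"label must be 0, 1 or 2, got {self.label}")


def _resize(pixels: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Bilinear resize via PIL; identity when already at the target size."""
    if pixels.shape[:2] == (size[1], size[0]):
        return pixels.copy()
    im = Image.fromarray(pixels).resize(size, Image.BILINEAR)
    return np.asarray(im)


def cut_crop(image: FieldImage, detection: Detection,
             margin: Union[int, float] = 0.10,
             label: int = 0) -> SeedlingCrop:
    """Cut one detection into a 255x255 crop.

    ``margin`` is either absolute pixels (int) or a fraction of the rect size
    (float < 1, default 10%). The window is clamped to the image bounds and
    resized bilinearly; a window already at 255x255 passes through untouched.
    """
    h, w = image.shape
    x0, y0, rw, rh = detection.rect
    if isinstance(margin, float) and margin < 1:
        mx, my = int(round(margin * rw)), int(round(margin * rh))
    else:
        mx = my = int(margin)
    xa, ya = max(x0 - mx, 0), max(y0 - my, 0)
    xb, yb = min(x0 + rw + mx, w), min(y0 + rh + my, h)
    if xa >= xb or ya >= yb:
        raise ValueError("detection window does not intersect the image")
    window = image.pixels[ya:yb, xa:xb]
    pixels = _resize(window, (CROP_SIZE, CROP_SIZE))
    return SeedlingCrop(pixels=pixels, label=label, source=image.source,
                        detection_index=detection.index)


def _luminance(px: np.ndarray) -> np.ndarray:
    return (0.299 * px[..., 0] + 0.587 * px[..., 1] + 0.114 * px[..., 2])[..., None]


def augment(crop: SeedlingCrop, op: str, params: Optional[dict] = None,
            seed: int = 0) -> SeedlingCrop:
    """Apply one augmentation operator; label preserved, 255x255x3 out.

    Unspecified parameters are drawn deterministically from the documented
    ranges using ``seed``. ``brightness`` with gain 1.0 and ``saturation``
    with factor 1.0 are exact identities; ``hflip`` is an involution.
    """
    if op not in AUG_OPS:
        raise ValueError(f"unknown augmentation op {op!r}; expected one of {AUG_OPS}")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    px = crop.pixels.astype(np.float64)

    if op == "brightness":
        gain = params.get("gain", rng.uniform(*BRIGHTNESS_RANGE))
        if not (0.1 <= gain <= 3.0):
            raise ValueError(f"brightness gain {gain} out of range")
        out = px * gain
    elif op == "hflip":
        out = px[:, ::-1, :]
    elif op == "saturation":
        factor = params.get("factor", rng.uniform(*SATURATION_RANGE))
        if not (0.0 <= factor <= 3.0):
            raise ValueError(f"saturation factor {factor} out of range")
        gray = _luminance(px)
        out = gray + factor * (px - gray)
    elif op == "random_crop":
        frac = params.get("area_fraction", rng.uniform(RANDOM_CROP_MIN_AREA, 1.0))
        if not (RANDOM_CROP_MIN_AREA <= frac <= 1.0):
            raise ValueError(f"random_crop area fraction {frac} out of range")
        side = max(1, int(round(CROP_SIZE * np.sqrt(frac))))
        ox = int(rng.integers(0, CROP_SIZE - side + 1))
        oy = int(rng.integers(0, CROP_SIZE - side + 1))
        window = crop.pixels[oy:oy + side, ox:ox + side]
        return replace(crop, pixels=_resize(window, (CROP_SIZE, CROP_SIZE)),
                       augmentation=op)
    else:  # scale
        factor = params.get("factor", rng.uniform(*SCALE_RANGE))
        if not (0.5 <= factor <= 2.0):
            raise ValueError(f"scale factor {factor} out of range")
        new = max(1, int(round(CROP_SIZE * factor)))
        resized = _resize(crop.pixels, (new, new))
        if new >= CROP_SIZE:  # center crop back to 255
            o = (new - CROP_SIZE) // 2
            out_px = resized[o:o + CROP_SIZE, o:o + CROP_SIZE]
        else:  # edge-replicate pad back to 255
            pad = CROP_SIZE - new
            before, after = pad // 2, pad - pad // 2
            out_px = np.pad(resized, ((before, after), (before, after), (0, 0)),
                            mode="edge")
        return replace(crop, pixels=out_px, augmentation=op)

    out_px = np.clip(np.round(out), 0, 255).astype(np.uint8)
    return replace(crop, pixels=out_px, augmentation=op)


@dataclass
class ManifestEntry:
    source_index: int          # index into the original crop list
    label: int
    split: str                 # "train" or "test"
    augmented: bool
    aug_op: Optional[str] = None
    aug_seed: Optional[int] = None
    path: Optional[str] = None


@dataclass
class DatasetManifest:
    entries: list[ManifestEntry]
    seed: int

    def per_class_counts(self, split: Optional[str] = None) -> dict[int, int]:
        counts: dict[int, int] = {}
        for e in self.entries:
            if split is None or e.split == split:
                counts[e.label] = counts.get(e.label, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "source_index": e.source_index, "label": e.label, "split": e.split,
            "augmented": e.augmented, "aug_op": e.aug_op or "",
            "aug_seed": -1 if e.aug_seed is None else e.aug_seed,
            "path": e.path or "",
        } for e in self.entries])

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, seed: int = 0) -> "DatasetManifest":
        frame = pd.read_csv(path, keep_default_na=False)
        entries = [ManifestEntry(
            source_index=int(r.source_index), label=int(r.label), split=str(r.split),
            augmented=bool(r.augmented),
            aug_op=str(r.aug_op) or None,
            aug_seed=None if int(r.aug_seed) < 0 else int(r.aug_seed),
            path=str(r.path) or None,
        ) for r in frame.itertuples()]
        return cls(entries=entries, seed=seed)


def build_dataset(crops_or_labels: Sequence,
                  augment_per_original: int = 2,
                  split_ratio: tuple[int, int] = (3, 1),
                  seed: int = 0,
                  balance: bool = True) -> DatasetManifest:
    """Plan the augmented, balanced, stratified dataset.

    Accepts the original crops (or just their labels) and emits a manifest:
    every original spawns ``augment_per_original`` augmented copies with
    operators cycled through the five-op set and seeded draws; smaller
    classes are topped up with extra augmented copies until all classes are
    equal; each class is then shuffled (seeded) and split train:test by
    ``split_ratio`` with the test share floored.
    """
    if len(crops_or_labels) == 0:
        raise ValueError("no crops given")
    labels = [c.label if isinstance(c, SeedlingCrop) else int(c)
              for c in crops_or_labels]
    by_class: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        if lab not in (0, 1, 2):
            raise ValueError(f"label must be 0, 1 or 2, got {lab}")
        by_class.setdefault(lab, []).append(i)
    missing = {0, 1, 2} - set(by_class)
    if missing:
        raise ValueError(f"every stage class needs at least one crop; missing {sorted(missing)}")
    tr, te = split_ratio
    if tr <= 0 or te <= 0:
        raise ValueError("split ratio parts must be positive")

    rng = np.random.default_rng(seed)
    per_class_entries: dict[int, list[ManifestEntry]] = {}
    for lab, idxs in sorted(by_class.items()):
        entries = [ManifestEntry(source_index=i, label=lab, split="train",
                                 augmented=False) for i in idxs]
        for j, i in enumerate(idxs):
            for a in range(augment_per_original):
                op = AUG_OPS[(j * augment_per_original + a) % len(AUG_OPS)]
                entries.append(ManifestEntry(
                    source_index=i, label=lab, split="train", augmented=True,
                    aug_op=op, aug_seed=int(rng.integers(0, 2 ** 31))))
        per_class_entries[lab] = entries

    if balance and len(per_class_entries) > 1:
        target = max(len(v) for v in per_class_entries.values())
        for lab, entries in sorted(per_class_entries.items()):
            while len(entries) < target:
                i = int(rng.choice(by_class[lab]))
                op = AUG_OPS[int(rng.integers(0, len(AUG_OPS)))]
                entries.append(ManifestEntry(
                    source_index=i, label=lab, split="train", augmented=True,
                    aug_op=op, aug_seed=int(rng.integers(0, 2 ** 31))))

    all_entries: list[ManifestEntry] = []
    for lab, entries in sorted(per_class_entries.items()):
        order = rng.permutation(len(entries))
        n_test = (len(entries) * te) // (tr + te)  # floor on the test side
        for rank, j in enumerate(order):
            entries[j].split = "test" if rank < n_test else "train"
        all_entries.extend(entries)
    return DatasetManifest(entries=all_entries, seed=seed)


def materialize_entry(entry: ManifestEntry,
                      originals: Sequence[SeedlingCrop]) -> SeedlingCrop:
    """Reproduce the pixels of one manifest entry from the original crops."""
    crop = originals[entry.source_index]
    if not entry.augmented:
        return crop
    return augment(crop, entry.aug_op, seed=entry.aug_seed)


def manifest_arrays(manifest: DatasetManifest, originals: Sequence[SeedlingCrop],
                    split: str) -> tuple[np.ndarray, np.ndarray]:
    """Materialise one split as (X, y) arrays for training/evaluation."""
    entries = [e for e in manifest.entries if e.split == split]
    if not entries:
        raise ValueError(f"split {split!r} is empty")
    X = np.stack([materialize_entry(e, originals).pixels for e in entries])
    y = np.array([e.label for e in entries], dtype=np.int64)
    return X, y


def write_crops(manifest: DatasetManifest, originals: Sequence[SeedlingCrop],
                out_dir: str | Path) -> DatasetManifest:
    """Write every manifest entry as a PNG under per-class directories."""
    out = Path(out_dir)
    for lab in sorted({e.label for e in manifest.entries}):
        (out / str(lab)).mkdir(parents=True, exist_ok=True)
    for i, e in enumerate(manifest.entries):
        crop = materialize_entry(e, originals)
        path = out / str(e.label) / f"crop_{i:05d}.png"
        Image.fromarray(crop.pixels).save(str(path))
        e.path = str(path)
    return manifest
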