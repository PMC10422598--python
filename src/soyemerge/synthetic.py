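"""Synthetic ridge-and-row field scenes with exact ground truth.

Renders nadir views of soybean seedlings as green-dominant blobs on brown
soil, with per-plant growth-stage morphology (VE: one compact cotyledon blob,
VC: two opposed cotyledon lobes, V1: cotyledons plus a leaf/node cluster), an
illumination gradient, optional plant overlap, and bright stalk-like
distractors whose excess-green stays below the vegetation threshold. Every
rendered plant and distractor footprint is recorded exactly, so detection,
cutting, classification and reporting can all be verified offline.

Default geometry mimics low-altitude UAV acquisition over ridge planting:
rows 225 mm apart, plants ~71 mm apart along the row, 2 mm/px ground
sampling (so one plant spacing is ~35 px).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image

from .detect import FieldImage

__all__ = ["SceneConfig", "GroundTruth", "PlantTruth", "generate_scene",
           "scene_to_count_truth", "write_scene", "generate_batch"]

STAGE_NAMES = ("VE", "VC", "V1")

# stage-dependent foliage colour (R, G, B): VE cotyledons are yellow-green,
# V1 true leaves darker; the shade shift is mild and secondary to morphology.
_STAGE_COLOR = {
    0: (80, 150, 55),
    1: (62, 142, 48),
    2: (48, 128, 42),
}

_SOIL = (118, 88, 60)          # brown base; excess-green ~ 0
_DISTRACTOR = (205, 198, 168)  # bright stalk; 2G-R-B = 23, below vegetation


@dataclass
class SceneConfig:
    """Parameters of one synthetic scene.

    ``stage_mix`` gives the probability of a plant being at VE/VC/V1.
    ``n_plants`` optionally fixes the exact number of plants; otherwise the
    row geometry fills the frame. Distances are in mm and converted through
    ``ground_sampling`` (mm per pixel).
    """

    image_size: tuple[int, int] = (640, 480)  # (width, height) px
    ground_sampling: float = 2.0              # mm / px
    row_spacing: float = 225.0                # mm, rows 22.5 cm apart
    plant_spacing_mean: float = 71.0          # mm along the row
    plant_spacing_jitter: float = 8.0         # mm, uniform +-
    n_rows: int = 4
    n_plants: Optional[int] = None
    stage_mix: tuple[float, float, float] = (1.0, 0.0, 0.0)
    overlap_prob: float = 0.0
    distractor_density: float = 0.0           # stalks per image
    illumination_gain: float = 1.0
    illumination_gradient: float = 0.0        # relative gain change across x
    soil_noise: float = 7.0                   # per-channel sd on soil
    contrast_margin: float = 60.0             # min plant-vs-soil excess-green gap
    seed: int = 0

    def validate(self) -> None:
        w, h = self.image_size
        if w <= 0 or h <= 0:
            raise ValueError("image_size must be positive")
        if abs(sum(self.stage_mix) - 1.0) > 1e-9:
            raise ValueError(f"stage_mix must sum to 1, got {self.stage_mix}")
        if min(self.stage_mix) < 0:
            raise ValueError("stage_mix probabilities must be non-negative")
        for name in ("ground_sampling", "row_spacing", "plant_spacing_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.plant_spacing_jitter < 0 or self.distractor_density < 0:
            raise ValueError("jitter and densities must be non-negative")


@dataclass
class PlantTruth:
    x: int
    y: int
    stage: int  # 0=VE, 1=VC, 2=V1
    footprint: np.ndarray  # (n, 2) of (x, y)

    @property
    def area(self) -> int:
        return len(self.footprint)


@dataclass
class GroundTruth:
    plants: list[PlantTruth]
    distractors: list[np.ndarray]  # footprints, (n, 2) of (x, y)

    def __len__(self) -> int:
        return len(self.plants)


def scene_to_count_truth(truth: GroundTruth) -> tuple[tuple[int, int, int], int]:
    """Per-stage plant counts and the total; the oracle for detected counts."""
    counts = [0, 0, 0]
    for p in truth.plants:
        counts[p.stage] += 1
    return (counts[0], counts[1], counts[2]), len(truth.plants)


def _stamp_blob(mask: np.ndarray, cx: float, cy: float, rx: float, ry: float,
                angle: float) -> None:
    """Rasterise a filled rotated ellipse into a boolean mask (in place)."""
    h, w = mask.shape
    rmax = int(np.ceil(max(rx, ry))) + 1
    x0, x1 = max(int(cx) - rmax, 0), min(int(cx) + rmax + 1, w)
    y0, y1 = max(int(cy) - rmax, 0), min(int(cy) + rmax + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx, dy = xs - cx, ys - cy
    c, s = np.cos(angle), np.sin(angle)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    mask[y0:y1, x0:x1] |= (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _plant_footprint(stage: int, rng: np.random.Generator,
                     shape: tuple[int, int], cx: float, cy: float) -> np.ndarray:
    """Boolean footprint of one plant; lobe count and size encode the stage."""
    mask = np.zeros(shape, dtype=bool)
    if stage == 0:  # VE: single compact cotyledon blob
        r = rng.uniform(3.2, 4.5)
        _stamp_blob(mask, cx, cy, r, r * rng.uniform(0.8, 1.0), rng.uniform(0, np.pi))
    elif stage == 1:  # VC: two opposed cotyledon lobes
        theta = rng.uniform(0, np.pi)
        sep = rng.uniform(3.5, 5.0)
        for sgn in (-1, 1):
            lx = cx + sgn * sep * np.cos(theta)
            ly = cy + sgn * sep * np.sin(theta)
            _stamp_blob(mask, lx, ly, rng.uniform(3.0, 4.2), rng.uniform(2.2, 3.2), theta)
        _stamp_blob(mask, cx, cy, sep, 1.6, theta)  # hypocotyl bridge keeps it connected
    else:  # V1: cotyledons plus a leaf/node cluster
        theta = rng.uniform(0, np.pi)
        sep = rng.uniform(4.0, 5.5)
        for sgn in (-1, 1):
            lx = cx + sgn * sep * np.cos(theta)
            ly = cy + sgn * sep * np.sin(theta)
            _stamp_blob(mask, lx, ly, rng.uniform(3.2, 4.4), rng.uniform(2.4, 3.4), theta)
        _stamp_blob(mask, cx, cy, sep, 1.8, theta)
        phi = theta + np.pi / 2
        for k in (-1, 0, 1):  # trifoliolate cluster off the node
            lx = cx + (4.5 + 2.0 * abs(k)) * np.cos(phi + 0.5 * k)
            ly = cy + (4.5 + 2.0 * abs(k)) * np.sin(phi + 0.5 * k)
            _stamp_blob(mask, lx, ly, rng.uniform(2.8, 3.8), rng.uniform(2.2, 3.0), phi)
    return mask


def _mask_to_points(mask: np.ndarray) -> np.ndarray:
    ys, xs = np.nonzero(mask)
    return np.column_stack([xs, ys]).astype(np.int64)


def generate_scene(config: SceneConfig) -> tuple[FieldImage, GroundTruth]:
    """Render one scene; deterministic for a fixed config (incl. its seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    w, h = config.image_size

    # soil background with noise and a horizontal illumination ramp
    soil = np.empty((h, w, 3), dtype=np.float64)
    for c, base in enumerate(_SOIL):
        soil[..., c] = base + rng.normal(0.0, config.soil_noise, size=(h, w))
    gain = config.illumination_gain * (
        1.0 + config.illumination_gradient * (np.arange(w) / max(w - 1, 1) - 0.5))
    img = soil * gain[None, :, None]

    # candidate plant positions on the row grid
    row_px = config.row_spacing / config.ground_sampling
    space_px = config.plant_spacing_mean / config.ground_sampling
    jitter_px = config.plant_spacing_jitter / config.ground_sampling
    margin = 14  # keeps footprints inside the frame
    row_ys = [h / 2 + (i - (config.n_rows - 1) / 2) * row_px for i in range(config.n_rows)]
    row_ys = [y for y in row_ys if margin <= y <= h - margin]
    positions: list[tuple[float, float]] = []
    for ry in row_ys:
        x = margin + rng.uniform(0, space_px / 2)
        while x <= w - margin:
            positions.append((x, ry + rng.normal(0, 1.5)))
            x += space_px + rng.uniform(-jitter_px, jitter_px)

    n_req = config.n_plants
    if n_req is not None:
        if n_req > len(positions):
            raise ValueError(
                f"requested {n_req} plants but the geometry fits only {len(positions)}")
        idx = np.sort(rng.choice(len(positions), size=n_req, replace=False))
        positions = [positions[i] for i in idx]

    stages = rng.choice(3, size=len(positions), p=np.asarray(config.stage_mix))

    occupied = np.zeros((h, w), dtype=bool)
    plants: list[PlantTruth] = []
    plant_mask_total = np.zeros((h, w), dtype=bool)
    for (cx, cy), stage in zip(positions, stages):
        overlap_ok = rng.random() < config.overlap_prob
        placed = None
        for attempt in range(8):
            fp = _plant_footprint(int(stage), rng, (h, w), cx, cy)
            dil = np.zeros_like(fp)  # 1-px dilation enforces an 8-connectivity gap
            ys, xs = np.nonzero(fp)
            if len(xs) == 0:
                break
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    dil[np.clip(ys + dy, 0, h - 1), np.clip(xs + dx, 0, w - 1)] = True
            if overlap_ok or not (dil & plant_mask_total).any():
                placed = fp
                break
            cx += rng.uniform(-3, 3)  # nudge and retry
            cy += rng.uniform(-3, 3)
        if placed is None:
            continue
        plant_mask_total |= placed
        color = np.array(_STAGE_COLOR[int(stage)], dtype=np.float64)
        color = color + rng.normal(0, 6, size=3)
        ys, xs = np.nonzero(placed)
        img[ys, xs] = color[None, :] * gain[xs, None] \
            + rng.normal(0, 4, size=(len(xs), 3))
        plants.append(PlantTruth(x=int(round(cx)), y=int(round(cy)),
                                 stage=int(stage), footprint=_mask_to_points(placed)))

    # bright stalk-like distractors: elongated, low excess-green
    distractors: list[np.ndarray] = []
    n_dis = int(round(config.distractor_density))
    for _ in range(n_dis):
        for attempt in range(12):
            cx = rng.uniform(margin, w - margin)
            cy = rng.uniform(margin, h - margin)
            angle = rng.uniform(0, np.pi)
            length = rng.uniform(12, 24)
            fp = np.zeros((h, w), dtype=bool)
            _stamp_blob(fp, cx, cy, length, rng.uniform(1.2, 2.0), angle)
            if not (fp & plant_mask_total).any() and fp.any():
                color = np.array(_DISTRACTOR, dtype=np.float64) + rng.normal(0, 3, size=3)
                ys, xs = np.nonzero(fp)
                img[ys, xs] = color[None, :] * gain[xs, None]
                distractors.append(_mask_to_points(fp))
                break

    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return FieldImage(pixels), GroundTruth(plants=plants, distractors=distractors)


def write_scene(image: FieldImage, truth: GroundTruth, image_path: str | Path,
                truth_path: str | Path) -> None:
    """Write the scene PNG and its ground-truth JSON sidecar."""
    Image.fromarray(image.pixels).save(str(image_path))
    payload = {
        "plants": [{"x": p.x, "y": p.y, "stage": p.stage, "area": p.area}
                   for p in truth.plants],
        "distractors": [{"area": int(len(d))} for d in truth.distractors],
    }
    Path(truth_path).write_text(json.dumps(payload, indent=1))


def generate_batch(base_config: SceneConfig, n_images: int, seed: int,
                   out_dir: str | Path) -> "pd.DataFrame":
    """Generate n scenes with seeds derived from ``seed``; writes a manifest CSV."""
    import pandas as pd
    from dataclasses import replace

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_images):
        scene_seed = (seed * 100003 + i) % (2 ** 31)
        cfg = replace(base_config, seed=scene_seed)
        image, truth = generate_scene(cfg)
        img_path = out / f"scene_{i:04d}.png"
        truth_path = out / f"scene_{i:04d}.truth.json"
        write_scene(image, truth, img_path, truth_path)
        rows.append({"image_path": str(img_path), "truth_path": str(truth_path),
                     "seed": scene_seed, "n_plants": len(truth)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
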