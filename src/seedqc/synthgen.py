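"""Synthetic seed-tray scenes with per-seed ground truth.

Renders tray-style images that emulate the imaging conditions of a seed
phenotyping rig: a dark uniform background with bright, roughly ellipsoidal
seed bodies in two appearance classes — ``good`` (smooth intact ellipse) and
``defective`` (ellipse carrying a boundary notch and/or a dark surface
patch).  Every scene comes with exact per-seed masks, bounding boxes and
class labels, so the segmentation and classification stages can be tested
against known truth.

Geometry conventions: pixel coordinates are 0-based; bounding boxes are
half-open ``[x0, x1) x [y0, y1)``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage as ndi

logger = logging.getLogger(__name__)

GOOD = "good"
DEFECTIVE = "defective"
CLASSES = (GOOD, DEFECTIVE)

#: rejection-sampling cap when placing one seed
_MAX_PLACEMENT_ATTEMPTS = 1000


class PlacementError(RuntimeError):
    """Raised when seeds cannot be placed without violating ``min_separation``."""


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box, 0-based, half-open in both axes."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"degenerate bbox {self!r}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    def clip(self, width: int, height: int) -> "BBox":
        return BBox(
            max(0, self.x0), max(0, self.y0), min(width, self.x1), min(height, self.y1)
        )

    def iou(self, other: "BBox") -> float:
        ix0, iy0 = max(self.x0, other.x0), max(self.y0, other.y0)
        ix1, iy1 = min(self.x1, other.x1), min(self.y1, other.y1)
        if ix0 >= ix1 or iy0 >= iy1:
            return 0.0
        inter = (ix1 - ix0) * (iy1 - iy0)
        return inter / float(self.area + other.area - inter)

    def as_list(self) -> list[int]:
        return [self.x0, self.y0, self.x1, self.y1]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic tray scene.

    ``min_separation`` is the clearance in pixels between seed *boundaries*
    (approximated through major semi-axes); a negative value permits
    touching or overlapping pairs.
    """

    image_width: int = 512
    image_height: int = 512
    n_seeds: int = 10
    defect_fraction: float = 0.5
    seed_axis_range: tuple[float, float] = (10.0, 22.0)
    min_separation: float = 30.0
    background_level: int = 30
    noise_sigma: float = 4.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seeds < 0:
            raise ValueError("n_seeds must be >= 0")
        if not 0.0 <= self.defect_fraction <= 1.0:
            raise ValueError("defect_fraction must lie in [0, 1]")
        lo, hi = self.seed_axis_range
        if not (0 < lo <= hi):
            raise ValueError("seed_axis_range must satisfy 0 < min <= max")
        if not 0 <= self.background_level <= 255:
            raise ValueError("background_level must be an 8-bit grey level")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class GroundTruthSeed:
    bbox: BBox
    class_label: str
    mask: np.ndarray  # bool, aligned to bbox

    def __post_init__(self) -> None:
        if self.class_label not in CLASSES:
            raise ValueError(f"unknown class {self.class_label!r}")
        if self.mask.sum() == 0:
            raise ValueError("empty ground-truth mask")


@dataclass
class LabeledScene:
    image: np.ndarray  # H x W x 3 uint8
    seeds: list[GroundTruthSeed]
    spec: SceneSpec

    def full_mask(self, index: int) -> np.ndarray:
        """Seed mask placed on a full-frame canvas."""
        out = np.zeros(self.image.shape[:2], dtype=bool)
        s = self.seeds[index]
        out[s.bbox.y0 : s.bbox.y1, s.bbox.x0 : s.bbox.x1] = s.mask
        return out


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------

# channel multipliers giving the yellowish cast of maize kernels
_SEED_TINT = np.array([1.0, 0.82, 0.45])


def _elliptical_radius2(
    xx: np.ndarray, yy: np.ndarray, cx: float, cy: float, a: float, b: float, theta: float
) -> np.ndarray:
    """Squared normalised elliptical radius (<= 1 inside the ellipse)."""
    dx, dy = xx - cx, yy - cy
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / a) ** 2 + (v / b) ** 2


def _sample_geometry(rng: np.random.Generator, spec: SceneSpec):
    lo, hi = spec.seed_axis_range
    a = rng.uniform(0.75 * lo + 0.25 * hi, hi)  # major semi-axis
    b = rng.uniform(max(lo, 0.5 * a), a)  # minor semi-axis; aspect <= 2:1
    theta = rng.uniform(0.0, math.pi)
    return a, b, theta


def _paint_seed(
    image: np.ndarray,
    rng: np.random.Generator,
    spec: SceneSpec,
    cx: float,
    cy: float,
    a: float,
    b: float,
    theta: float,
    defective: bool,
) -> np.ndarray:
    """Paint one seed in place; return its full-frame boolean mask."""
    h, w = image.shape[:2]
    pad = int(math.ceil(a)) + 3
    x0w, x1w = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
    y0w, y1w = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
    yy, xx = np.mgrid[y0w:y1w, x0w:x1w]
    r2 = _elliptical_radius2(xx, yy, cx, cy, a, b, theta)
    body = r2 <= 1.0
    body_area = body.sum()

    base = rng.uniform(165.0, 220.0)
    tint = _SEED_TINT * rng.uniform(0.95, 1.05, size=3)
    tint_map = np.broadcast_to(tint, r2.shape + (3,)).copy()
    # mild centre-to-edge shading plus per-pixel speckle texture
    shading = 1.0 - 0.22 * np.clip(r2, 0.0, 1.0)
    speckle = rng.normal(0.0, 5.0, size=r2.shape)
    intensity = base * shading + speckle

    if defective:
        kind = rng.choice(["notch", "patch", "both"])

        def bite_tip() -> tuple[np.ndarray, np.ndarray]:
            # bite a circle out of a *tip* of the kernel (within ~30 degrees
            # of the major axis), growing it until it removes >= 12% of the
            # body: a clearly broken silhouette that truncates the seed
            # without pinching its waist into two lobes.  Returns the bite
            # and the fracture band just inside it, where the break exposes
            # pale endosperm.
            phi = rng.choice([0.0, math.pi]) + rng.uniform(-0.5, 0.5)
            ct, st = math.cos(theta), math.sin(theta)
            ex = cx + a * math.cos(phi) * ct - b * math.sin(phi) * st
            ey = cy + a * math.cos(phi) * st + b * math.sin(phi) * ct
            radius = 0.45 * b
            while True:
                d2 = (xx - ex) ** 2 + (yy - ey) ** 2
                notch = d2 <= radius**2
                if (body & notch).sum() >= 0.12 * body_area or radius > 0.9 * b:
                    band = (d2 <= (radius + 3.5) ** 2) & ~notch
                    return notch, band

                radius *= 1.2

        def apply_bite() -> None:
            nonlocal body, intensity
            notch, band = bite_tip()
            body = body & ~notch
            fracture = band & body
            # exposed starchy endosperm: brighter and much less yellow than
            # the pericarp
            intensity = np.where(fracture, np.maximum(intensity * 1.1, 225.0), intensity)
            tint_map[fracture] = np.array([0.98, 0.95, 0.82]) * rng.uniform(0.97, 1.03)

        if kind in ("notch", "both"):
            apply_bite()
        if kind in ("patch", "both"):
            # dark blemish covering >= 10% of the body, restricted to pixels
            # at least 6 px inside the (post-notch) body so an unbroken
            # bright rim always encloses it: thresholding then sees an
            # interior hole, never a split or crescent seed
            eligible = ndi.distance_transform_edt(body) >= 6.0
            if eligible.any():
                eys, exs = np.nonzero(eligible)
                pcy = eys.mean() + y0w + rng.uniform(-2, 2)
                pcx = exs.mean() + x0w + rng.uniform(-2, 2)
                pa = rng.uniform(0.45, 0.6) * a
                pb = rng.uniform(0.45, 0.6) * b
                patch = eligible & (
                    _elliptical_radius2(xx, yy, pcx, pcy, pa, pb, theta) <= 1.0
                )
                if patch.sum() < 0.10 * body.sum():
                    patch = eligible
                factor = rng.uniform(0.35, 0.5)
                intensity = np.where(patch, intensity * factor, intensity)
            elif kind == "patch":
                # seed too small to host an interior patch: break it instead
                apply_bite()

    # keep every painted pixel clearly above the background mode
    floor = spec.background_level + 3.0 * spec.noise_sigma + 8.0
    pixels = intensity[body][:, None] * tint_map[body]
    pixels = np.maximum(pixels, floor)
    window = image[y0w:y1w, x0w:x1w]
    window[body] = np.clip(pixels, 0.0, 255.0)

    mask = np.zeros((h, w), dtype=bool)
    mask[y0w:y1w, x0w:x1w] = body
    return mask


def n_defective(spec: SceneSpec) -> int:
    """Number of defective seeds implied by the spec (round-half-up)."""
    return int(math.floor(spec.n_seeds * spec.defect_fraction + 0.5))


def render_scene(spec: SceneSpec) -> LabeledScene:
    """Render one scene deterministically from ``spec.rng_seed``.

    Raises :class:`PlacementError` when rejection sampling cannot place all
    seeds under the requested ``min_separation``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.image_height, spec.image_width

    image = np.full((h, w, 3), float(spec.background_level))

    geoms: list[tuple[float, float, float, float, float]] = []  # cx, cy, a, b, theta
    for k in range(spec.n_seeds):
        a, b, theta = _sample_geometry(rng, spec)
        margin = a + 3.0
        if 2 * margin >= min(w, h):
            raise PlacementError(f"seed axis {a:.1f} does not fit a {w}x{h} image")
        placed = False
        for _ in range(_MAX_PLACEMENT_ATTEMPTS):
            cx = rng.uniform(margin, w - margin)
            cy = rng.uniform(margin, h - margin)
            ok = all(
                math.hypot(cx - ox, cy - oy) >= a + oa + spec.min_separation
                for ox, oy, oa, _, _ in geoms
            )
            if ok:
                geoms.append((cx, cy, a, b, theta))
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place seed {k + 1}/{spec.n_seeds} within "
                f"{_MAX_PLACEMENT_ATTEMPTS} attempts (min_separation="
                f"{spec.min_separation})"
            )

    labels = np.array([DEFECTIVE] * n_defective(spec) + [GOOD] * (spec.n_seeds - n_defective(spec)))
    labels = labels[rng.permutation(spec.n_seeds)] if spec.n_seeds else labels

    seeds: list[GroundTruthSeed] = []
    for (cx, cy, a, b, theta), label in zip(geoms, labels):
        mask = _paint_seed(image, rng, spec, cx, cy, a, b, theta, label == DEFECTIVE)
        ys, xs = np.nonzero(mask)
        bbox = BBox(int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)
        seeds.append(
            GroundTruthSeed(
                bbox=bbox,
                class_label=str(label),
                mask=mask[bbox.y0 : bbox.y1, bbox.x0 : bbox.x1].copy(),
            )
        )

    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return LabeledScene(image=image, seeds=seeds, spec=spec)


# ---------------------------------------------------------------------------
# dataset construction
# ---------------------------------------------------------------------------


def render_touching_pair(
    rng_seed: int,
    overlap_fraction: float = 0.2,
    image_size: int = 192,
    axis_range: tuple[float, float] = (14.0, 22.0),
) -> LabeledScene:
    """Render exactly two good seeds whose bodies touch/overlap.

    The centre distance is ``a1 + a2 - overlap_fraction * min(a1, a2)``
    along a random direction, so the pair forms one connected blob with
    two distinct distance-transform peaks — the configuration the
    watershed stage must split.
    """
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1)")
    spec = SceneSpec(
        image_width=image_size,
        image_height=image_size,
        n_seeds=2,
        defect_fraction=0.0,
        seed_axis_range=axis_range,
        min_separation=-overlap_fraction * axis_range[1],
        rng_seed=rng_seed,
    )
    rng = np.random.default_rng(rng_seed)
    image = np.full((image_size, image_size, 3), float(spec.background_level))
    # near-circular bodies: touching roundish seeds always leave a clear
    # distance-transform saddle at the waist (the configuration of interest)
    a1 = rng.uniform(*axis_range)
    a2 = rng.uniform(*axis_range)
    b1, b2 = a1 * rng.uniform(0.85, 1.0), a2 * rng.uniform(0.85, 1.0)
    th1, th2 = rng.uniform(0.0, math.pi, size=2)
    d = a1 + a2 - overlap_fraction * min(a1, a2)
    direction = rng.uniform(0.0, 2 * math.pi)
    c0 = image_size / 2.0
    cx1 = c0 - 0.5 * d * math.cos(direction)
    cy1 = c0 - 0.5 * d * math.sin(direction)
    cx2 = c0 + 0.5 * d * math.cos(direction)
    cy2 = c0 + 0.5 * d * math.sin(direction)
    seeds = []
    for cx, cy, a, b, th in ((cx1, cy1, a1, b1, th1), (cx2, cy2, a2, b2, th2)):
        mask = _paint_seed(image, rng, spec, cx, cy, a, b, th, defective=False)
        ys, xs = np.nonzero(mask)
        bbox = BBox(int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)
        seeds.append(
            GroundTruthSeed(
                bbox=bbox,
                class_label=GOOD,
                mask=mask[bbox.y0 : bbox.y1, bbox.x0 : bbox.x1].copy(),
            )
        )
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
    return LabeledScene(
        image=np.clip(np.rint(image), 0, 255).astype(np.uint8), seeds=seeds, spec=spec
    )


def scene_seed(rng_seed: int, scene_index: int) -> int:
    """Child seed for scene ``scene_index``, independent across scenes."""
    ss = np.random.SeedSequence([int(rng_seed), int(scene_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def _crop_with_margin(image: np.ndarray, bbox: BBox, margin: int = 4) -> np.ndarray:
    h, w = image.shape[:2]
    b = BBox(bbox.x0 - margin, bbox.y0 - margin, bbox.x1 + margin, bbox.y1 + margin).clip(w, h)
    return image[b.y0 : b.y1, b.x0 : b.x1]


def save_scene(scene: LabeledScene, out_dir: Path, stem: str) -> tuple[Path, Path]:
    """Write the scene PNG and its ground-truth JSON; return both paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    png = out_dir / f"{stem}.png"
    Image.fromarray(scene.image).save(png)
    gt = {
        "seeds": [
            {"bbox": s.bbox.as_list(), "class": s.class_label} for s in scene.seeds
        ]
    }
    js = out_dir / f"{stem}.json"
    js.write_text(json.dumps(gt, indent=1))
    return png, js


def make_dataset(
    spec_template: SceneSpec,
    n_scenes: int,
    out_dir: str | Path,
    split_ratio: float = 0.8,
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render ``n_scenes`` scenes, write per-seed crops, split at scene level.

    The split is a disjoint partition of *scenes* (no seed of one scene ends
    up in both halves); the default 0.8 ratio reproduces a 4:1 train:test
    division.  Returns the (train, test) crop manifests, also written as
    ``train.csv`` / ``test.csv`` with columns
    ``path,label,scene,seed_index,x0,y0,x1,y1``.
    """
    if n_scenes < 2:
        raise ValueError("need at least 2 scenes to populate both splits")
    if not 0.0 < split_ratio < 1.0:
        raise ValueError("split_ratio must lie strictly between 0 and 1")
    n_train = min(max(int(round(n_scenes * split_ratio)), 1), n_scenes - 1)

    out_dir = Path(out_dir)
    scenes_dir = out_dir / "scenes"
    crops_dir = out_dir / "crops"
    crops_dir.mkdir(parents=True, exist_ok=True)

    order = np.random.default_rng(rng_seed).permutation(n_scenes)
    train_scenes = set(order[:n_train].tolist())

    rows: dict[str, list[dict]] = {"train": [], "test": []}
    for i in range(n_scenes):
        spec = replace(spec_template, rng_seed=scene_seed(rng_seed, i))
        scene = render_scene(spec)
        stem = f"scene_{i:04d}"
        scene_png, _ = save_scene(scene, scenes_dir, stem)
        part = "train" if i in train_scenes else "test"
        for j, seed in enumerate(scene.seeds):
            crop = _crop_with_margin(scene.image, seed.bbox)
            crop_path = crops_dir / f"{stem}_seed{j}.png"
            Image.fromarray(crop).save(crop_path)
            rows[part].append(
                {
                    "path": str(crop_path),
                    "label": seed.class_label,
                    "scene": str(scene_png),
                    "seed_index": j,
                    "x0": seed.bbox.x0,
                    "y0": seed.bbox.y0,
                    "x1": seed.bbox.x1,
                    "y1": seed.bbox.y1,
                }
            )

    cols = ["path", "label", "scene", "seed_index", "x0", "y0", "x1", "y1"]
    train = pd.DataFrame(rows["train"], columns=cols)
    test = pd.DataFrame(rows["test"], columns=cols)
    train.to_csv(out_dir / "train.csv", index=False)
    test.to_csv(out_dir / "test.csv", index=False)
    logger.info(
        "dataset: %d scenes -> %d train / %d test crops", n_scenes, len(train), len(test)
    )
    return train, test


def make_crop_dataset(
    n_per_class: int,
    crop_size: int = 64,
    rng_seed: int = 0,
    noise_sigma: float = 4.0,
    background_level: int = 30,
) -> tuple[np.ndarray, np.ndarray]:
    """Directly render balanced single-seed crops as arrays.

    Returns ``(X, y)`` where ``X`` is ``(2*n_per_class, crop, crop, 3)``
    uint8 and ``y`` holds class names.  Convenient for classifier tests that
    do not need full tray scenes.
    """
    rng = np.random.default_rng(rng_seed)
    spec = SceneSpec(
        image_width=crop_size,
        image_height=crop_size,
        n_seeds=1,
        background_level=background_level,
        noise_sigma=noise_sigma,
    )
    n = 2 * n_per_class
    X = np.empty((n, crop_size, crop_size, 3), dtype=np.uint8)
    y = np.array([GOOD, DEFECTIVE] * n_per_class)
    # seed sized to roughly fill the crop
    lo, hi = 0.26 * crop_size, 0.42 * crop_size
    for i, label in enumerate(y):
        image = np.full((crop_size, crop_size, 3), float(background_level))
        a = rng.uniform(0.6 * hi + 0.4 * lo, hi)
        b = rng.uniform(lo, a)
        theta = rng.uniform(0.0, math.pi)
        cx = crop_size / 2 + rng.uniform(-3, 3)
        cy = crop_size / 2 + rng.uniform(-3, 3)
        _paint_seed(image, rng, spec, cx, cy, a, b, theta, label == DEFECTIVE)
        if noise_sigma > 0:
            image = image + rng.normal(0.0, noise_sigma, size=image.shape)
        X[i] = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    perm = rng.permutation(n)
    return X[perm], y[perm]


def write_crop_manifest(
    X: np.ndarray, y: Sequence[str], out_dir: str | Path, name: str = "crops"
) -> pd.DataFrame:
    """Write crop arrays as PNGs plus a ``path,label`` CSV manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, label) in enumerate(zip(X, y)):
        p = out_dir / f"{name}_{i:05d}.png"
        Image.fromarray(img).save(p)
        rows.append({"path": str(p), "label": label})
    df = pd.DataFrame(rows, columns=["path", "label"])
    df.to_csv(out_dir / f"{name}.csv", index=False)
    return df
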