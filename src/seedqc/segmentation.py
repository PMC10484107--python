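"""Marker-controlled watershed segmentation of multi-seed tray images.

The pipeline follows the classic recipe for splitting touching bright
objects on a dark background: grayscale conversion, global (Otsu) or
adaptive-Gaussian thresholding, morphological opening to remove white
noise, dilation to delimit sure background, a Euclidean distance transform
whose thresholded peaks give one marker per seed, and watershed flooding
that assigns the remaining "unknown" band to seeds or background.  Each
labelled region is finally cut out as a per-seed crop with its tight
bounding box.

Label convention in :class:`MarkerMap`: ``0`` = unknown / watershed line,
``1`` = background, ``k >= 2`` = seed ``k - 1``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage as ndi
from skimage.filters import threshold_local, threshold_otsu
from skimage.segmentation import watershed as _watershed

from .synthgen import BBox

logger = logging.getLogger(__name__)

#: Rec. 601 luminance weights used for grayscale conversion
_LUMA = np.array([0.299, 0.587, 0.114])

#: 8-connectivity structuring element for component labelling
_CONN8 = np.ones((3, 3), dtype=bool)

#: minimum d-prime between foreground and background grey levels for a
#: threshold to count as a real bimodal split (below this the image is
#: treated as background-only)
_MIN_BIMODAL_DPRIME = 4.0


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable parameters of the watershed pipeline.

    Defaults implement the canonical marker-controlled recipe: a 3x3
    opening repeated twice, three dilation iterations to carve out sure
    background, and markers where the distance transform reaches half of
    its (per-component) maximum.
    """

    opening_kernel: int = 3
    opening_iterations: int = 2
    closing_iterations: int = 0
    fill_holes: bool = True
    dilation_iterations: int = 3
    distance_threshold_fraction: float = 0.5
    min_region_area: int = 50
    threshold_method: str = "otsu"  # or "adaptive_gaussian"
    adaptive_block_size: int = 51
    #: grey levels added to the local mean; keeps uniform background (whose
    #: noise straddles its own local mean) out of the foreground
    adaptive_offset: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 < self.distance_threshold_fraction < 1.0:
            raise ValueError("distance_threshold_fraction must lie in (0, 1)")
        if self.min_region_area < 1:
            raise ValueError("min_region_area must be >= 1")
        if self.opening_kernel < 3 or self.opening_kernel % 2 == 0:
            raise ValueError("opening_kernel must be odd and >= 3")
        if self.threshold_method not in ("otsu", "adaptive_gaussian"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")


@dataclass
class MarkerMap:
    """Integer label image (0 unknown, 1 background, >=2 seeds).

    ``foreground`` and ``distance`` cache the cleaned binary mask and its
    distance transform so the watershed stage can reuse them.
    """

    labels: np.ndarray
    foreground: np.ndarray | None = None
    distance: np.ndarray | None = None

    @property
    def seed_labels(self) -> np.ndarray:
        vals = np.unique(self.labels)
        return vals[vals >= 2]

    @property
    def n_seeds(self) -> int:
        return int(self.seed_labels.size)


@dataclass
class SeedCrop:
    image: np.ndarray
    bbox: BBox
    source_label: int
    area: int


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luminance grayscale (float) of an RGB array."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 image")
    return image.astype(float) @ _LUMA


def binarize(image: np.ndarray, config: SegmentationConfig | None = None) -> np.ndarray:
    """Threshold an RGB scene into a boolean foreground (seed) mask.

    Polarity is auto-corrected: after thresholding, the minority class is
    taken as foreground, so scenes with dark seeds on a bright background
    binarize to the same mask as their inverted counterparts.

    A scene whose two grey-level classes are not genuinely separated
    (d-prime below 4, e.g. pure background noise) raises ``ValueError``
    rather than returning a speckle mask.
    """
    config = config or SegmentationConfig()
    gray = to_grayscale(image)
    if gray.size == 0:
        raise ValueError("empty image")
    if np.ptp(gray) == 0:
        raise ValueError("constant image: no threshold separates the classes")
    if config.threshold_method == "otsu":
        fg = gray > threshold_otsu(gray)
    else:
        block = config.adaptive_block_size | 1
        local = threshold_local(gray, block_size=block, method="gaussian")
        fg = gray > local + config.adaptive_offset
    if fg.sum() > fg.size - fg.sum():
        fg = ~fg
    if not fg.any():
        raise ValueError("empty foreground: image appears to be background only")
    spread = float(np.sqrt((gray[fg].var() + gray[~fg].var()) / 2.0))
    separation = abs(float(gray[fg].mean()) - float(gray[~fg].mean()))
    if spread > 0 and separation / spread < _MIN_BIMODAL_DPRIME:
        raise ValueError(
            "no bimodal foreground/background separation "
            f"(d-prime {separation / spread:.2f})"
        )
    return fg


def extract_markers(
    binary: np.ndarray, config: SegmentationConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, MarkerMap]:
    """Derive sure-background / sure-foreground / unknown regions and markers.

    The binary mask is hole-filled (so dark blemishes inside a seed do not
    fragment it), opened to drop white noise, optionally closed, then dilated:
    everything outside the dilation is sure background.  The Euclidean distance
    transform of the opened mask, normalised within each connected
    component, yields sure foreground where it reaches
    ``distance_threshold_fraction``; the dilated band minus the sure
    foreground is the unknown region handed to the watershed.  Marker
    labels come from connected components of the sure foreground.

    Normalising the distance per component (rather than globally) keeps
    small seeds from losing their marker next to large ones.
    """
    config = config or SegmentationConfig()
    if binary.size == 0:
        raise ValueError("empty binary image")
    binary = binary.astype(bool)

    k = np.ones((config.opening_kernel, config.opening_kernel), dtype=bool)
    opened = binary
    if config.fill_holes and opened.any():
        # dark blemishes inside a seed threshold out as interior holes; fill
        # them before any erosion can breach the surrounding bright rim
        opened = ndi.binary_fill_holes(opened)
    if config.opening_iterations > 0 and opened.any():
        opened = ndi.binary_opening(opened, structure=k, iterations=config.opening_iterations)
    if config.closing_iterations > 0 and opened.any():
        opened = ndi.binary_closing(opened, structure=k, iterations=config.closing_iterations)
    dilated = opened
    if config.dilation_iterations > 0 and opened.any():
        dilated = ndi.binary_dilation(opened, structure=k, iterations=config.dilation_iterations)

    sure_background = ~dilated
    distance = ndi.distance_transform_edt(opened)

    sure_foreground = np.zeros_like(opened)
    comp, n_comp = ndi.label(opened, structure=_CONN8)
    for c in range(1, n_comp + 1):
        region = comp == c
        dmax = distance[region].max()
        if dmax > 0:
            sure_foreground |= region & (
                distance >= config.distance_threshold_fraction * dmax
            )

    unknown = dilated & ~sure_foreground

    markers, n_markers = ndi.label(sure_foreground, structure=_CONN8)
    labels = np.ones_like(markers)
    labels[unknown] = 0
    labels[sure_foreground] = markers[sure_foreground] + 1
    logger.debug("extract_markers: %d markers", n_markers)
    return sure_background, sure_foreground, unknown, MarkerMap(
        labels=labels, foreground=opened, distance=distance
    )


def watershed_split(image: np.ndarray, markers: MarkerMap) -> MarkerMap:
    """Flood the unknown band from the markers, splitting touching seeds.

    The negated distance transform serves as the elevation map and the
    flood is confined to the cleaned foreground, so each seed marker fills
    its own basin and meets its neighbour at the distance-transform saddle;
    everything outside the foreground is background.  Single-pixel
    watershed lines (label 0) separate touching regions.
    """
    if markers.distance is None or markers.foreground is None:
        raise ValueError("markers must come from extract_markers")
    if markers.n_seeds == 0:
        labels = np.ones_like(markers.labels)
        return MarkerMap(labels=labels, foreground=markers.foreground, distance=markers.distance)
    seed_markers = np.where(markers.labels >= 2, markers.labels, 0)
    ws = _watershed(
        -markers.distance,
        markers=seed_markers,
        mask=markers.foreground,
        watershed_line=True,
    )
    labels = ws.astype(np.int32)
    labels[~markers.foreground] = 1
    return MarkerMap(labels=labels, foreground=markers.foreground, distance=markers.distance)


def extract_crops(
    image: np.ndarray, labels: MarkerMap, config: SegmentationConfig | None = None
) -> list[SeedCrop]:
    """Cut one crop per seed label, dropping regions below ``min_region_area``.

    Crops are returned sorted by ``(y0, x0)`` of their tight bounding box;
    boxes are clipped to the image bounds and use 0-based half-open
    coordinates.
    """
    config = config or SegmentationConfig()
    h, w = labels.labels.shape
    crops: list[SeedCrop] = []
    n_filtered = 0
    for lab in labels.seed_labels:
        region = labels.labels == lab
        area = int(region.sum())
        if area < config.min_region_area:
            n_filtered += 1
            continue
        ys, xs = np.nonzero(region)
        bbox = BBox(int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1).clip(w, h)
        crops.append(
            SeedCrop(
                image=image[bbox.y0 : bbox.y1, bbox.x0 : bbox.x1].copy(),
                bbox=bbox,
                source_label=int(lab),
                area=area,
            )
        )
    if n_filtered:
        logger.info("extract_crops: filtered %d region(s) below min area", n_filtered)
    crops.sort(key=lambda c: (c.bbox.y0, c.bbox.x0))
    return crops


def segment_scene(
    image: np.ndarray, config: SegmentationConfig | None = None
) -> tuple[list[SeedCrop], MarkerMap]:
    """Full pipeline: binarize, extract markers, watershed, crop.

    An all-background scene (thresholding fails or no markers) yields an
    empty crop list rather than an error.
    """
    config = config or SegmentationConfig()
    try:
        binary = binarize(image, config)
    except ValueError:
        logger.warning("segment_scene: no foreground found (degenerate image)")
        empty = MarkerMap(labels=np.ones(image.shape[:2], dtype=np.int32))
        return [], empty
    _, _, _, markers = extract_markers(binary, config)
    ws = watershed_split(image, markers)
    return extract_crops(image, ws, config), ws


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG/TIFF image as an H x W x 3 uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_crops(
    crops: list[SeedCrop], out_dir: str | Path, stem: str
) -> Path:
    """Write crops as ``<stem>_seed<k>.png`` plus a JSON summary; return JSON path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for k, crop in enumerate(crops):
        p = out_dir / f"{stem}_seed{k}.png"
        Image.fromarray(crop.image.astype(np.uint8)).save(p)
        records.append({"bbox": crop.bbox.as_list(), "area": crop.area, "path": str(p)})
    js = out_dir / f"{stem}_crops.json"
    js.write_text(json.dumps({"crops": records}, indent=1))
    return js
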