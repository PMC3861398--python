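"""Segmentation of cytokeratin-stained tumor nests from RGB core images.

The pipeline mirrors the classical four-step recipe for DAB/hematoxylin
brightfield images:

1. ``preprocess``        — stain separation (H-DAB color deconvolution) plus
                           median de-noising and linear contrast stretch,
2. ``binarize_otsu``     — global Otsu threshold on the DAB channel,
3. ``morphological_open``— disk opening to smooth silhouettes and detach
                           thinly connected neighbours,
4. ``fill_holes``        — flood-fill of enclosed background,

followed by an optional non-interactive mask override (the stand-in for
expert correction), connected-component labeling and Moore boundary tracing.

Conventions (used consistently across the package):

* foreground is 8-connected, background 4-connected;
* raster coordinates are 0-based ``(row, col)``, origin top-left;
* the boundary map is the inner 4-neighbour boundary: foreground pixels with
  at least one background 4-neighbour, pixels outside the raster counting as
  background (so a full-raster foreground has the raster rim as boundary);
* per-nest contours are closed Moore traces through boundary-pixel centers;
  their chain-code length (axial step 1, diagonal step sqrt(2)) is the
  perimeter definition used by the feature layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2hed
from skimage.filters import threshold_otsu
from skimage.morphology import disk, opening

__all__ = [
    "CoreImage",
    "StainChannel",
    "NestSegmentation",
    "SegmentationParams",
    "preprocess",
    "binarize_otsu",
    "morphological_open",
    "fill_holes",
    "extract_boundaries",
    "apply_overrides",
    "label_nests",
    "segment_core",
    "trace_moore_contour",
    "contour_chain_length",
    "read_core_image",
    "write_label_mask",
    "read_label_mask",
]

# override raster codes
OVERRIDE_KEEP = 0
OVERRIDE_ADD = 1
OVERRIDE_REMOVE = 2

_STRUCT8 = np.ones((3, 3), bool)
_STRUCT4 = ndi.generate_binary_structure(2, 1)


@dataclass
class CoreImage:
    """One RGB tissue-core raster with its identifiers."""

    pixels: np.ndarray  # H x W x 3, uint8
    core_id: str = ""
    patient_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("CoreImage.pixels must be an H x W x 3 raster")
        if px.shape[0] < 32 or px.shape[1] < 32:
            raise ValueError("CoreImage must be at least 32 x 32 pixels")
        self.pixels = px.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class StainChannel:
    """Scalar DAB-positivity raster; higher means more stained."""

    values: np.ndarray
    provenance: str = "deconvolution"  # {"deconvolution", "luminance"}
    degenerate: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("StainChannel values must be finite")
        self.values = v


@dataclass
class SegmentationParams:
    denoise_radius: int = 2
    opening_radius: int = 2
    min_size: int = 50

    def validate(self) -> None:
        if self.denoise_radius < 0 or self.opening_radius < 0:
            raise ValueError("radii must be non-negative")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")

    def to_dict(self) -> dict:
        return {
            "denoise_radius": int(self.denoise_radius),
            "opening_radius": int(self.opening_radius),
            "min_size": int(self.min_size),
        }


@dataclass
class NestSegmentation:
    """Labeled tumor nests of one core.

    ``label_mask`` holds 0 for background and 1..n for nests, numbered in
    raster-scan order of each nest's first pixel.  ``contours`` maps label to
    a closed (first == last vertex) Moore contour of ``(row, col)`` pixel
    centers.  ``border_labels`` flags nests touching the raster rim (kept,
    since a tissue core is a circular field with no exclusion rule).
    """

    label_mask: np.ndarray
    contours: dict[int, np.ndarray]
    boundary_map: np.ndarray
    params_used: dict = field(default_factory=dict)
    border_labels: frozenset[int] = frozenset()

    @property
    def n_nests(self) -> int:
        return len(self.contours)

    def params_json(self) -> str:
        return json.dumps(self.params_used, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# step 1: stain channel
# ---------------------------------------------------------------------------

def preprocess(image: CoreImage, denoise_radius: int = 2) -> StainChannel:
    """DAB stain channel via H-DAB color deconvolution, de-noised and stretched.

    Uses the published standard H-DAB stain matrix (Ruifrok & Johnston) as
    shipped with scikit-image, then a median filter with a disk footprint of
    ``denoise_radius`` (0 disables it) and a linear stretch to [0, 1].  An
    all-constant channel cannot be stretched; it is returned unchanged with
    ``degenerate=True``.
    """
    if denoise_radius < 0:
        raise ValueError("denoise_radius must be non-negative")
    dab = rgb2hed(image.pixels)[..., 2]
    if denoise_radius > 0:
        dab = ndi.median_filter(dab, footprint=disk(denoise_radius))
    lo, hi = float(dab.min()), float(dab.max())
    if hi == lo:
        return StainChannel(values=dab, degenerate=True)
    return StainChannel(values=(dab - lo) / (hi - lo))


# ---------------------------------------------------------------------------
# step 2: Otsu binarization
# ---------------------------------------------------------------------------

def binarize_otsu(channel: StainChannel) -> tuple[np.ndarray, float]:
    """Global Otsu threshold (256-bin histogram); foreground is above it.

    Returns ``(mask, threshold)``.  Raises on a degenerate (single-valued)
    histogram, where between-class variance is undefined.
    """
    v = channel.values
    if channel.degenerate or np.unique(v).size < 2:
        raise ValueError("degenerate histogram: channel has < 2 distinct values")
    thr = float(threshold_otsu(v, nbins=256))
    return v > thr, thr


# ---------------------------------------------------------------------------
# steps 3-4: morphology
# ---------------------------------------------------------------------------

def morphological_open(mask: np.ndarray, radius: int = 2) -> np.ndarray:
    """Binary opening (erosion then dilation) with a disk of ``radius``."""
    mask = np.asarray(mask, bool)
    if radius <= 0:
        return mask.copy()
    return opening(mask, disk(radius)).astype(bool)


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background components not 4-connected to the raster border."""
    return ndi.binary_fill_holes(np.asarray(mask, bool), structure=_STRUCT4)


# ---------------------------------------------------------------------------
# expert-correction stand-in
# ---------------------------------------------------------------------------

def apply_overrides(mask: np.ndarray, override: np.ndarray) -> np.ndarray:
    """Apply a {keep=0, add=1, remove=2} override raster to a binary mask."""
    mask = np.asarray(mask, bool)
    override = np.asarray(override)
    if override.shape != mask.shape:
        raise ValueError(
            f"override shape {override.shape} does not match mask shape {mask.shape}"
        )
    bad = ~np.isin(override, (OVERRIDE_KEEP, OVERRIDE_ADD, OVERRIDE_REMOVE))
    if bad.any():
        raise ValueError("override raster may only contain codes {0, 1, 2}")
    out = mask.copy()
    out[override == OVERRIDE_ADD] = True
    out[override == OVERRIDE_REMOVE] = False
    return out


# ---------------------------------------------------------------------------
# boundary extraction and contour tracing
# ---------------------------------------------------------------------------

def _inner_boundary(mask: np.ndarray) -> np.ndarray:
    # 4-neighbour inner boundary; outside the raster counts as background
    eroded = ndi.binary_erosion(mask, structure=_STRUCT4, border_value=0)
    return mask & ~eroded


# clockwise Moore neighbourhood, starting West, rows growing downward
_MOORE = ((0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1))
_MOORE_INDEX = {off: i for i, off in enumerate(_MOORE)}


def trace_moore_contour(mask: np.ndarray) -> np.ndarray:
    """Closed Moore contour of the foreground component in ``mask``.

    Starts at the topmost-leftmost foreground pixel and walks the boundary
    clockwise, backtracking through the background; the walk stops when its
    (pixel, backtrack) state repeats, which traverses the complete boundary
    cycle exactly once even when the trace must pass through a pixel twice
    (one-pixel-wide spurs trace out and back).  Returns an (m, 2) array of
    ``(row, col)`` vertices with first == last; a single isolated pixel
    yields the one-vertex degenerate contour.
    """
    mask = np.asarray(mask, bool)
    rs, cs = np.nonzero(mask)
    if rs.size == 0:
        return np.empty((0, 2), dtype=np.intp)
    i = np.lexsort((cs, rs))[0]
    start = (int(rs[i]), int(cs[i]))
    H, W = mask.shape

    def fg(r: int, c: int) -> bool:
        return 0 <= r < H and 0 <= c < W and mask[r, c]

    if not any(fg(start[0] + dr, start[1] + dc) for dr, dc in _MOORE):
        return np.array([start], dtype=np.intp)

    contour = [start]
    cur = start
    back = (start[0], start[1] - 1)
    seen: set[tuple[tuple[int, int], tuple[int, int]]] = {(cur, back)}
    limit = 8 * mask.size
    while True:
        k0 = _MOORE_INDEX[(back[0] - cur[0], back[1] - cur[1])]
        nxt = None
        for j in range(1, 9):
            k = (k0 + j) % 8
            cand = (cur[0] + _MOORE[k][0], cur[1] + _MOORE[k][1])
            if fg(*cand):
                nxt = cand
                break
            back = cand
        assert nxt is not None  # component has >= 2 pixels
        state = (nxt, back)
        if state in seen:
            break
        seen.add(state)
        contour.append(nxt)
        cur = nxt
        if len(contour) > limit:  # pragma: no cover - defensive
            raise RuntimeError("contour trace failed to terminate")
    if contour[0] != contour[-1]:
        contour.append(contour[0])
    return np.asarray(contour, dtype=np.intp)


def contour_chain_length(contour: np.ndarray) -> float:
    """Chain-code length of a closed contour: axial 1, diagonal sqrt(2).

    The degenerate single-pixel contour gets length 1 by convention so that
    perimeters stay positive.
    """
    if len(contour) < 2:
        return 1.0 if len(contour) == 1 else 0.0
    d = np.abs(np.diff(np.asarray(contour, dtype=np.intp), axis=0))
    axial = (d.sum(axis=1) == 1).sum()
    diag = ((d[:, 0] == 1) & (d[:, 1] == 1)).sum()
    return float(axial + np.sqrt(2.0) * diag)


def extract_boundaries(mask: np.ndarray) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Boundary map and per-component closed contours of a binary mask.

    The boundary map marks foreground pixels with a background 4-neighbour
    (the inner boundary a gradient operator run on the binary raster
    highlights); contours are clockwise Moore traces, one per 8-connected
    component, keyed by the component's raster-scan label.
    """
    mask = np.asarray(mask, bool)
    boundary = _inner_boundary(mask)
    labels, n = ndi.label(mask, structure=_STRUCT8)
    contours: dict[int, np.ndarray] = {}
    for lab in range(1, n + 1):
        contours[lab] = trace_moore_contour(labels == lab)
    return boundary, contours


# ---------------------------------------------------------------------------
# labeling
# ---------------------------------------------------------------------------

def label_nests(mask: np.ndarray, min_size: int = 50,
                params: Mapping | None = None) -> NestSegmentation:
    """8-connected component labeling with a minimum-size filter.

    Components below ``min_size`` pixels are discarded (the automated proxy
    for expert deletion of noise signals); survivors are renumbered 1..n in
    raster-scan order of their first pixel.  Zero nests is a valid result.
    """
    mask = np.asarray(mask, bool)
    labels, n = ndi.label(mask, structure=_STRUCT8)
    keep_mask = np.zeros_like(mask)
    contours: dict[int, np.ndarray] = {}
    border: set[int] = set()
    new_lab = 0
    H, W = mask.shape
    for lab in range(1, n + 1):
        comp = labels == lab
        if int(comp.sum()) < min_size:
            continue
        new_lab += 1
        keep_mask |= comp
        contours[new_lab] = trace_moore_contour(comp)
        rs, cs = np.nonzero(comp)
        if rs.min() == 0 or cs.min() == 0 or rs.max() == H - 1 or cs.max() == W - 1:
            border.add(new_lab)
    out = np.zeros(mask.shape, dtype=np.int32)
    # relabel survivors consecutively, preserving raster-scan order
    relabeled, _ = ndi.label(keep_mask, structure=_STRUCT8)
    out[:] = relabeled
    boundary = _inner_boundary(keep_mask)
    used = dict(params or {})
    used["min_size"] = int(min_size)
    return NestSegmentation(
        label_mask=out,
        contours=contours,
        boundary_map=boundary,
        params_used=used,
        border_labels=frozenset(border),
    )


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def segment_core(image: CoreImage, params: SegmentationParams | None = None,
                 override: np.ndarray | None = None) -> NestSegmentation:
    """Run the full four-step segmentation on one core image."""
    params = params or SegmentationParams()
    params.validate()
    channel = preprocess(image, denoise_radius=params.denoise_radius)
    mask, thr = binarize_otsu(channel)
    mask = morphological_open(mask, radius=params.opening_radius)
    mask = fill_holes(mask)
    if override is not None:
        mask = apply_overrides(mask, override)
    used = params.to_dict()
    used["otsu_threshold"] = thr
    used["core_id"] = image.core_id
    seg = label_nests(mask, min_size=params.min_size, params=used)
    return seg


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------

def read_core_image(path: str | Path, core_id: str = "",
                    patient_id: str = "") -> CoreImage:
    """Read an RGB BMP/PNG/TIFF core image from disk."""
    import imageio.v3 as iio

    px = np.asarray(iio.imread(path))
    if px.ndim == 2:
        px = np.stack([px] * 3, axis=-1)
    if px.shape[-1] == 4:  # drop alpha
        px = px[..., :3]
    if not core_id:
        core_id = Path(path).stem
    return CoreImage(pixels=px, core_id=core_id, patient_id=patient_id)


def write_label_mask(path: str | Path, label_mask: np.ndarray) -> None:
    """Write an integer label mask as single-channel 16-bit PNG/TIFF."""
    import imageio.v3 as iio

    lab = np.asarray(label_mask)
    if lab.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("label mask exceeds 16-bit range")
    iio.imwrite(Path(path), lab.astype(np.uint16))


def read_label_mask(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    return np.asarray(iio.imread(path)).astype(np.int32)
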