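"""Synthetic 8-bit IHC-like images with ground truth known by construction.

Two field types mirror the study's two quantification problems:

* optical-density fields — a known fraction of ROI pixels is "positive"
  (immunolabelled); positive pixels are rendered BRIGHT, background dark.
  Real DAB staining is dark-positive; the quantification stage exposes an
  ``invert`` flag to accommodate either polarity under one convention.
* spheroid fields — bright radially-decaying blobs (APP-positive axonal
  swellings) placed by a Poisson point process of known intensity
  (objects per mm²) inside the ROI.

Ground truth (realized positive fraction, or placed-object count and
centroids) is recorded exactly, making downstream thresholding and
counting testable without real slides.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import BlobOverlapWarning, ClassOverlapWarning

__all__ = [
    "ImageSpec",
    "ODFieldSpec",
    "SpheroidFieldSpec",
    "GroundTruth",
    "LabeledImage",
    "make_od_image",
    "make_spheroid_image",
    "DEFAULT_BACKGROUND_LAW",
    "DEFAULT_FOREGROUND_LAW",
]

#: default intensity laws (mean, sd) on the 8-bit scale; chosen well
#: separated (16 background SDs between modes) so the two-class structure
#: is unambiguous
DEFAULT_BACKGROUND_LAW = (40.0, 10.0)
DEFAULT_FOREGROUND_LAW = (200.0, 12.0)


def _resolve_roi(
    roi: np.ndarray | tuple[int, int, int, int] | None, shape: tuple[int, int]
) -> np.ndarray:
    """Accept a boolean mask, a (row, col, height, width) rectangle, or None."""
    if roi is None:
        return np.ones(shape, dtype=bool)
    if isinstance(roi, tuple):
        r, c, h, w = roi
        if h < 1 or w < 1 or r < 0 or c < 0 or r + h > shape[0] or c + w > shape[1]:
            raise ValueError("ROI rectangle outside image bounds or empty")
        mask = np.zeros(shape, dtype=bool)
        mask[r : r + h, c : c + w] = True
        return mask
    mask = np.asarray(roi, dtype=bool)
    if mask.shape != shape:
        raise ValueError("ROI mask shape must match image shape")
    if not mask.any():
        raise ValueError("ROI mask is empty")
    return mask


@dataclass
class ImageSpec:
    """Geometry of a synthetic field."""

    width: int = 256
    height: int = 256
    pixel_size: float = 1.0  # micrometers per pixel edge
    roi: np.ndarray | tuple[int, int, int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def roi_mask(self) -> np.ndarray:
        return _resolve_roi(self.roi, self.shape)


@dataclass
class ODFieldSpec(ImageSpec):
    """Optical-density field: a known fraction of ROI pixels is positive."""

    true_fraction: float = 0.5
    background_law: tuple[float, float] = DEFAULT_BACKGROUND_LAW
    foreground_law: tuple[float, float] = DEFAULT_FOREGROUND_LAW

    def __post_init__(self) -> None:
        super().__post_init__()
        if not 0.0 <= self.true_fraction <= 1.0:
            raise ValueError("true_fraction must be in [0, 1]")
        if not self.foreground_law[0] > self.background_law[0]:
            raise ValueError("foreground mean must exceed background mean")


@dataclass
class SpheroidFieldSpec(ImageSpec):
    """Spheroid field: Poisson-placed bright blobs of known density."""

    true_density: float = 0.0  # objects per mm^2
    blob_radius: float = 3.0  # micrometers
    blob_peak: float = 200.0  # added intensity at blob center
    background_law: tuple[float, float] = DEFAULT_BACKGROUND_LAW

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.true_density < 0:
            raise ValueError("true_density must be non-negative")
        if self.blob_radius <= 0:
            raise ValueError("blob_radius must be positive")


@dataclass(frozen=True)
class GroundTruth:
    fraction: float | None = None
    count: int | None = None
    centroids: tuple[tuple[float, float], ...] | None = None


@dataclass
class LabeledImage:
    """8-bit pixel grid + ROI mask + construction ground truth."""

    pixels: np.ndarray
    roi_mask: np.ndarray
    ground_truth: GroundTruth
    pixel_size: float = 1.0

    @property
    def roi_area_mm2(self) -> float:
        return float(self.roi_mask.sum()) * self.pixel_size**2 / 1e6

    def save(self, stem: str | Path) -> dict:
        """Write <stem>.tif and <stem>_mask.tif; return a sidecar record."""
        stem = Path(stem)
        stem.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(stem.with_suffix(".tif"), self.pixels)
        tifffile.imwrite(
            stem.parent / f"{stem.name}_mask.tif",
            (self.roi_mask.astype(np.uint8) * 255),
        )
        return {
            "image": str(stem.with_suffix(".tif")),
            "mask": str(stem.parent / f"{stem.name}_mask.tif"),
            "true_fraction": self.ground_truth.fraction,
            "true_count": self.ground_truth.count,
            "roi_area_mm2": self.roi_area_mm2,
        }


def _sample_intensities(
    rng: np.random.Generator, law: tuple[float, float], n: int
) -> np.ndarray:
    mean, sd = law
    vals = rng.normal(mean, sd, size=n)
    return np.clip(np.rint(vals), 0, 255).astype(np.uint8)


def make_od_image(spec: ODFieldSpec) -> LabeledImage:
    """Render an optical-density field with an exact positive-pixel count.

    Exactly ``round(true_fraction * |roi|)`` ROI pixels (uniformly chosen)
    receive foreground intensities; all other pixels get background.  The
    recorded ground-truth fraction is the realized one, which by
    construction equals round(f*|roi|)/|roi|.
    """
    fg_mean, fg_sd = spec.foreground_law
    bg_mean, bg_sd = spec.background_law
    if fg_mean - bg_mean < 2.0 * (fg_sd + bg_sd):
        warnings.warn(
            "foreground and background intensity laws overlap heavily; "
            "two-class structure may be destroyed",
            ClassOverlapWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed)
    mask = spec.roi_mask()
    roi_idx = np.flatnonzero(mask.ravel())
    n_fg = int(round(spec.true_fraction * roi_idx.size))
    fg_idx = rng.choice(roi_idx, size=n_fg, replace=False)

    img = np.empty(spec.shape, dtype=np.uint8)
    img.ravel()[:] = _sample_intensities(rng, spec.background_law, img.size)
    img.ravel()[fg_idx] = _sample_intensities(rng, spec.foreground_law, n_fg)
    return LabeledImage(
        pixels=img,
        roi_mask=mask,
        ground_truth=GroundTruth(fraction=n_fg / roi_idx.size),
        pixel_size=spec.pixel_size,
    )


def make_spheroid_image(
    spec: SpheroidFieldSpec,
    centers: np.ndarray | None = None,
) -> LabeledImage:
    """Render a spheroid field; ground-truth count = number of placed centers.

    The object count is Poisson with mean ``true_density * roi_area_mm2``
    and centers fall uniformly on ROI pixels; pass ``centers`` (an (n, 2)
    array of row/col coordinates) to force a deterministic layout instead.
    Each object is an additive Gaussian-profile blob (sigma = radius/2)
    saturating at 255.
    """
    rng = np.random.default_rng(spec.seed)
    mask = spec.roi_mask()
    area_mm2 = float(mask.sum()) * spec.pixel_size**2 / 1e6

    radius_um = spec.blob_radius
    density_per_um2 = spec.true_density / 1e6
    expected_overlap = 1.0 - math.exp(-density_per_um2 * math.pi * (2 * radius_um) ** 2)
    if expected_overlap > 0.5:
        warnings.warn(
            "expected blob overlap exceeds 50%; connected-component counting "
            "is ill-posed at this density/radius",
            BlobOverlapWarning,
            stacklevel=2,
        )

    if centers is None:
        n = int(rng.poisson(spec.true_density * area_mm2))
        roi_idx = np.flatnonzero(mask.ravel())
        picks = rng.choice(roi_idx, size=n, replace=True)
        rows = picks // spec.width + rng.uniform(-0.5, 0.5, size=n)
        cols = picks % spec.width + rng.uniform(-0.5, 0.5, size=n)
        centers = np.column_stack([rows, cols]) if n else np.empty((0, 2))
    else:
        centers = np.asarray(centers, dtype=float).reshape(-1, 2)
        n = len(centers)

    field = np.zeros(spec.shape, dtype=np.float64)
    sigma_px = (spec.blob_radius / spec.pixel_size) / 2.0
    reach = max(int(math.ceil(3.0 * sigma_px)), 1)
    H, W = spec.shape
    for r0, c0 in centers:
        r_lo, r_hi = max(int(r0) - reach, 0), min(int(r0) + reach + 1, H)
        c_lo, c_hi = max(int(c0) - reach, 0), min(int(c0) + reach + 1, W)
        rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        field[r_lo:r_hi, c_lo:c_hi] += spec.blob_peak * np.exp(
            -d2 / (2.0 * sigma_px**2)
        )

    bg = rng.normal(*spec.background_law, size=spec.shape)
    img = np.clip(np.rint(bg + field), 0, 255).astype(np.uint8)
    return LabeledImage(
        pixels=img,
        roi_mask=mask,
        ground_truth=GroundTruth(
            count=n, centroids=tuple(map(tuple, np.asarray(centers)))
        ),
        pixel_size=spec.pixel_size,
    )
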