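"""Standardization of EM images and masks to the analysis resolution,
intensity normalization, patch extraction and the RoI coverage filter.

The analysis standard is 1,024 x 1,024-pixel patches at 10 nm/px. Training
uses a sliding window with a 512-px step; inference draws 5 random patches
per image. In tissue mode a patch is analyzed only if the annotated cell
territory (RoI) covers strictly more than 15% of its area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from skimage import filters as _sk_filters
from skimage import transform as _sk_transform

from ._errors import ConfigError, ShapeMismatchError, TooSmallError

__all__ = [
    "PreprocessConfig",
    "PatchSpec",
    "AugmentParams",
    "resample_to_standard",
    "normalize_intensity",
    "sliding_patches",
    "random_patches",
    "extract_patch",
    "draw_augment_params",
    "apply_augmentation",
    "augment_patch",
    "roi_coverage_filter",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters.

    target_pixel_nm : analysis resolution in nm per pixel (default 10).
    patch_size : square patch edge in pixels at the target resolution.
    sliding_step : stride of the training sliding window in pixels.
    n_random_patches : patches drawn per image at inference.
    roi_min_coverage : tissue-mode retention threshold; a patch is kept iff
        its RoI coverage fraction is strictly greater than this value.
    """

    target_pixel_nm: float = 10.0
    patch_size: int = 1024
    sliding_step: int = 512
    n_random_patches: int = 5
    roi_min_coverage: float = 0.15
    rng_seed: int = 0

    def __post_init__(self):
        if not self.target_pixel_nm > 0:
            raise ConfigError("target_pixel_nm must be positive")
        if not 0 < self.sliding_step <= self.patch_size:
            raise ConfigError("sliding_step must satisfy 0 < step <= patch_size")
        if not 0 <= self.roi_min_coverage <= 1:
            raise ConfigError("roi_min_coverage must lie in [0, 1]")
        if self.n_random_patches < 1:
            raise ConfigError("n_random_patches must be >= 1")


@dataclass(frozen=True)
class PatchSpec:
    """A patch location: top-left origin (row, col) and size, fully in-bounds."""

    image_id: str
    origin: tuple
    size: tuple
    roi_coverage: Optional[float] = None


def _shape_of(image_or_shape) -> tuple:
    if hasattr(image_or_shape, "shape"):
        return tuple(image_or_shape.shape[:2])
    return tuple(image_or_shape)[:2]


def resample_to_standard(image_or_mask: np.ndarray, native_nm: float, target_nm: float,
                         is_mask: Optional[bool] = None,
                         min_size: Optional[int] = None) -> np.ndarray:
    """Resample a raster from its native resolution to the target resolution.

    Output dimensions are round(dim * native_nm / target_nm). Integer and
    boolean grids are resampled by nearest neighbor (labels preserved);
    float grids by bilinear interpolation. When ``min_size`` is given (the
    patch size), an output dimension below it raises TooSmallError naming
    the offending axis.
    """
    if not native_nm > 0 or not target_nm > 0:
        raise ConfigError("pixel sizes must be positive")
    arr = np.asarray(image_or_mask)
    scale = native_nm / target_nm
    H, W = arr.shape[:2]
    out_h = int(round(H * scale))
    out_w = int(round(W * scale))
    if min_size is not None:
        if out_h < min_size:
            raise TooSmallError("row", out_h, min_size)
        if out_w < min_size:
            raise TooSmallError("col", out_w, min_size)
    if (out_h, out_w) == (H, W):
        return arr.copy()
    if is_mask is None:
        is_mask = arr.dtype == bool or np.issubdtype(arr.dtype, np.integer)
    if is_mask:
        out = _sk_transform.resize(arr, (out_h, out_w), order=0,
                                   preserve_range=True, anti_aliasing=False)
        return out.astype(arr.dtype)
    out = _sk_transform.resize(arr.astype(float), (out_h, out_w), order=1,
                               preserve_range=True, anti_aliasing=scale < 1)
    return out


def normalize_intensity(image: np.ndarray) -> np.ndarray:
    """Robust min-max normalization to [0, 1].

    Intensities are clipped at the 1st and 99th percentiles, then linearly
    rescaled; a constant image maps to all zeros.
    """
    arr = np.asarray(image, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot normalize an empty image")
    lo, hi = np.percentile(arr, [1.0, 99.0])
    if hi <= lo:
        return np.zeros_like(arr)
    return (np.clip(arr, lo, hi) - lo) / (hi - lo)


def _stride_starts(extent: int, patch: int, step: int) -> list:
    starts = list(range(0, extent - patch + 1, step))
    if starts[-1] != extent - patch:
        starts.append(extent - patch)  # flush to the far border, no padding
    return starts


def sliding_patches(image_or_shape, patch_size: int, step: int,
                    image_id: str = "image") -> list:
    """Sliding-window patch origins at multiples of ``step``.

    If the stride does not land exactly on the far border, one final patch
    is anchored flush to that border, so the image is fully covered without
    padding and without duplicate origins.
    """
    H, W = _shape_of(image_or_shape)
    if H < patch_size:
        raise TooSmallError("row", H, patch_size)
    if W < patch_size:
        raise TooSmallError("col", W, patch_size)
    return [
        PatchSpec(image_id=image_id, origin=(r, c), size=(patch_size, patch_size))
        for r in _stride_starts(H, patch_size, step)
        for c in _stride_starts(W, patch_size, step)
    ]


def random_patches(image_or_shape, n: int, rng_seed: int,
                   patch_size: int = 1024, image_id: str = "image") -> list:
    """``n`` patch origins drawn uniformly over all valid positions.

    Patches may overlap; the draw is reproducible for a given seed.
    """
    H, W = _shape_of(image_or_shape)
    if H < patch_size:
        raise TooSmallError("row", H, patch_size)
    if W < patch_size:
        raise TooSmallError("col", W, patch_size)
    rng = np.random.default_rng(rng_seed)
    rows = rng.integers(0, H - patch_size + 1, size=n)
    cols = rng.integers(0, W - patch_size + 1, size=n)
    return [
        PatchSpec(image_id=image_id, origin=(int(r), int(c)),
                  size=(patch_size, patch_size))
        for r, c in zip(rows, cols)
    ]


def extract_patch(array: np.ndarray, spec: PatchSpec) -> np.ndarray:
    """Slice the patch described by ``spec`` out of a standardized array."""
    r, c = spec.origin
    h, w = spec.size
    if r < 0 or c < 0 or r + h > array.shape[0] or c + w > array.shape[1]:
        raise ShapeMismatchError(f"patch {spec.origin}+{spec.size} exceeds array {array.shape}")
    return array[r:r + h, c:c + w]


@dataclass(frozen=True)
class AugmentParams:
    """Geometric + blur augmentation parameters for one training patch."""

    flip_h: bool = False
    flip_v: bool = False
    rot90: int = 0            # quarter turns, 0..3
    scale: float = 1.0        # affine jitter, drawn in [0.95, 1.05]
    rotation_deg: float = 0.0  # affine jitter, drawn in [-5, 5]
    blur_sigma: float = 0.0   # Gaussian blur sigma in px, drawn in [0, 1.5]


def draw_augment_params(rng_seed: int) -> AugmentParams:
    rng = np.random.default_rng(rng_seed)
    return AugmentParams(
        flip_h=bool(rng.integers(0, 2)),
        flip_v=bool(rng.integers(0, 2)),
        rot90=int(rng.integers(0, 4)),
        scale=float(rng.uniform(0.95, 1.05)),
        rotation_deg=float(rng.uniform(-5.0, 5.0)),
        blur_sigma=float(rng.uniform(0.0, 1.5)),
    )


def apply_augmentation(patch: np.ndarray, params: AugmentParams,
                       is_mask: bool = False) -> np.ndarray:
    """Apply one augmentation; masks get the identical geometric transform
    with nearest-neighbor interpolation and no blur."""
    arr = np.asarray(patch)
    out = arr
    if params.flip_h:
        out = out[:, ::-1]
    if params.flip_v:
        out = out[::-1, :]
    if params.rot90 % 4:
        out = np.rot90(out, params.rot90 % 4)
    if params.scale != 1.0 or params.rotation_deg != 0.0:
        center = np.array([(out.shape[1] - 1) / 2.0, (out.shape[0] - 1) / 2.0])
        tform = (_sk_transform.AffineTransform(translation=-center)
                 + _sk_transform.AffineTransform(scale=params.scale,
                                                 rotation=math.radians(params.rotation_deg))
                 + _sk_transform.AffineTransform(translation=center))
        out = _sk_transform.warp(out.astype(float), tform.inverse,
                                 order=0 if is_mask else 1, preserve_range=True)
        if is_mask:
            out = out.astype(arr.dtype)
    else:
        out = out.copy()
    if not is_mask and params.blur_sigma > 0:
        out = _sk_filters.gaussian(np.asarray(out, dtype=float), sigma=params.blur_sigma,
                                   preserve_range=True)
    return out


def augment_patch(patch: np.ndarray, rng_seed: int,
                  masks: Sequence[np.ndarray] = ()) -> tuple:
    """Seeded random augmentation of a patch and its masks.

    Returns (augmented_patch, [augmented_masks...], params). The draw is a
    random horizontal/vertical flip, a quarter-turn rotation, small affine
    jitter (scale within 5%, rotation within 5 degrees) and Gaussian blur
    with sigma in [0, 1.5] px (blur applied to the image only).
    """
    params = draw_augment_params(rng_seed)
    out = apply_augmentation(patch, params, is_mask=False)
    out_masks = [apply_augmentation(m, params, is_mask=True) for m in masks]
    return out, out_masks, params


def roi_coverage_filter(patches: Iterable[PatchSpec], roi_mask: np.ndarray,
                        min_coverage: float) -> list:
    """Retain patches whose RoI coverage is strictly above ``min_coverage``.

    Coverage is the fraction of patch pixels inside the RoI (the annotated
    cell territory), the quantity the tissue workflow thresholds at 0.15.
    Returned specs carry their coverage value.
    """
    roi = np.asarray(roi_mask).astype(bool)
    retained = []
    for spec in patches:
        r, c = spec.origin
        h, w = spec.size
        if r + h > roi.shape[0] or c + w > roi.shape[1]:
            raise ShapeMismatchError(
                f"patch {spec.origin}+{spec.size} exceeds RoI mask {roi.shape}")
        coverage = float(roi[r:r + h, c:c + w].sum()) / float(h * w)
        if coverage > min_coverage:
            retained.append(replace(spec, roi_coverage=coverage))
    return retained
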