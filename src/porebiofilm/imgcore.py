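"""Time-lapse loading, background correction, and biomass segmentation.

Frames are transmitted-light intensity rasters recorded at fixed intervals;
the first frame (no biofilm) is the reference background.  Correction is
the per-pixel absolute difference to that reference, after which biomass
stands out as high "darkening" values.  Binarisation is Otsu by default
(the threshold is recorded in the mask provenance), with a fixed-threshold
override for reproducibility; grain interiors are excluded and components
below a minimum area are discarded as noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import tifffile
from scipy import ndimage
from skimage import filters

from .synthgen import DeviceGeometry

__all__ = ["ImageStack", "BiomassMasks", "background_subtract", "binarize"]

MIN_COMPONENT_PX = 16


def remove_small_components(mask: np.ndarray, min_size: int) -> np.ndarray:
    """Drop 8-connected components with fewer than ``min_size`` pixels."""
    if min_size <= 1 or not mask.any():
        return mask
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), int))
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return keep[labels]


@dataclass(frozen=True)
class ImageStack:
    """A (frames, H, W) intensity stack with acquisition times in hours."""

    frames: np.ndarray
    times_h: np.ndarray
    pixel_size_um: float

    def __post_init__(self):
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (t, y, x) array")
        if len(self.times_h) != len(self.frames):
            raise ValueError("one acquisition time per frame required")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @classmethod
    def from_tiff(cls, path, times_h, pixel_size_um: float) -> "ImageStack":
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        return cls(frames, np.asarray(times_h, float), pixel_size_um)

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, self.frames)


@dataclass(frozen=True)
class BiomassMasks:
    """Binary biomass rasters per frame with thresholding provenance."""

    masks: np.ndarray  # (frames, H, W) bool
    times_h: np.ndarray
    pixel_size_um: float
    method: str
    thresholds: np.ndarray

    def __len__(self) -> int:
        return len(self.masks)

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, self.masks.astype(np.uint8) * 255, compression="zlib")


def background_subtract(stack: ImageStack) -> ImageStack:
    """Absolute difference of each frame to frame 0.

    The output's frame 0 is all-zero; values are clipped to the input's
    valid intensity range.
    """
    if len(stack) < 2:
        raise ValueError("background subtraction needs at least 2 frames")
    ref = stack.frames[0].astype(np.int64 if np.issubdtype(stack.frames.dtype, np.integer) else float)
    corrected = np.abs(stack.frames.astype(ref.dtype) - ref)
    if np.issubdtype(stack.frames.dtype, np.integer):
        info = np.iinfo(stack.frames.dtype)
        corrected = np.clip(corrected, 0, info.max).astype(stack.frames.dtype)
    return ImageStack(corrected, stack.times_h, stack.pixel_size_um)


def binarize(
    corrected: ImageStack,
    geometry: DeviceGeometry | None = None,
    method: str = "otsu",
    fixed_value: float | None = None,
    min_size: int = MIN_COMPONENT_PX,
    min_contrast: float = 8.0,
) -> BiomassMasks:
    """Per-frame binary biomass masks from a background-corrected stack.

    Grain interiors (dilated 1 px) are always removed; 8-connected
    components smaller than ``min_size`` pixels are discarded as noise.
    A constant-intensity frame under Otsu yields an empty mask with a
    warning rather than an error, as does a frame whose Otsu split
    separates the classes by less than ``min_contrast`` intensity counts —
    such a split partitions shot noise, not biomass.
    """
    if method not in ("otsu", "fixed"):
        raise ValueError(f"unknown binarisation method {method!r}")
    if method == "fixed" and fixed_value is None:
        raise ValueError("fixed binarisation requires fixed_value")
    grain_excl = geometry.grain_mask(dilate_px=1.0) if geometry is not None else None
    masks = np.zeros(corrected.frames.shape, dtype=bool)
    thresholds = np.full(len(corrected), np.nan)
    for i, frame in enumerate(corrected.frames):
        if method == "fixed":
            thr = float(fixed_value)
        else:
            if np.ptp(frame) == 0:
                warnings.warn(
                    f"frame {i} has constant intensity; emitting empty mask", stacklevel=2
                )
                continue
            thr = float(filters.threshold_otsu(frame))
            fg = frame > thr
            contrast = float(frame[fg].mean() - frame[~fg].mean()) if fg.any() else 0.0
            if contrast < min_contrast:
                warnings.warn(
                    f"frame {i}: Otsu split separates classes by only "
                    f"{contrast:.1f} counts (noise); emitting empty mask",
                    stacklevel=2,
                )
                continue
        m = frame > thr
        if grain_excl is not None:
            m &= ~grain_excl
        m = remove_small_components(m, min_size)
        masks[i] = m
        thresholds[i] = thr
    return BiomassMasks(
        masks=masks,
        times_h=corrected.times_h,
        pixel_size_um=corrected.pixel_size_um,
        method=method,
        thresholds=thresholds,
    )
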