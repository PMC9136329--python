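"""Threshold-based foreground segmentation of depth images.

A person in front of a depth sensor is closer to the camera than the scene
behind them, so a global depth threshold separates the body from the
background: a pixel is foreground when its depth d(x, y) falls strictly
below a threshold lambda_depth = K * d_max, where d_max is the maximum
valid depth measured in the image and K (default 0.75) is a dimensionless
constant.

Pixels on the boundary d(x, y) == lambda_depth are classified as background
(strict inequality), and unmeasured (sentinel) pixels are always background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_K = 0.75


@dataclass(frozen=True)
class DepthImage:
    """A 2-D grid of per-pixel depth measurements in millimetres.

    ``invalid_value`` marks unmeasured pixels (depth sensors report 0 for
    pixels where no return was received); those pixels are excluded from
    the maximum-depth statistic and never become foreground.
    """

    depth: np.ndarray
    invalid_value: float | None = 0.0

    def __post_init__(self):
        depth = np.asarray(self.depth, dtype=float)
        if depth.ndim != 2 or depth.size == 0:
            raise ValueError(f"depth must be a non-empty 2-D array, got {depth.shape}")
        valid = self.valid_mask_of(depth)
        if np.any(depth[valid] < 0):
            raise ValueError("valid depths must be non-negative")
        object.__setattr__(self, "depth", depth)

    def valid_mask_of(self, depth: np.ndarray) -> np.ndarray:
        mask = np.isfinite(depth)
        if self.invalid_value is not None:
            mask &= depth != self.invalid_value
        return mask

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of measured pixels."""
        return self.valid_mask_of(self.depth)

    @property
    def width(self) -> int:
        return self.depth.shape[1]

    @property
    def height(self) -> int:
        return self.depth.shape[0]


@dataclass(frozen=True)
class ForegroundMask:
    """Binary foreground flags f(x, y), same grid as the source image."""

    flags: np.ndarray

    def __post_init__(self):
        flags = np.asarray(self.flags)
        if flags.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not np.isin(flags, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        object.__setattr__(self, "flags", flags.astype(np.uint8))

    @property
    def width(self) -> int:
        return self.flags.shape[1]

    @property
    def height(self) -> int:
        return self.flags.shape[0]

    @property
    def foreground_count(self) -> int:
        return int(self.flags.sum())


def compute_threshold(image: DepthImage, K: float = DEFAULT_K) -> float:
    """Return the segmentation threshold lambda_depth = K * d_max in mm.

    Parameters
    ----------
    image : DepthImage
        Must contain at least one valid pixel.
    K : float
        Dimensionless constant in (0, 1], default 0.75.
    """
    if not 0 < K <= 1:
        raise ValueError(f"K must be in (0, 1], got {K}")
    valid = image.valid_mask
    if not valid.any():
        raise ValueError("image has no measurable depth (all pixels invalid)")
    d_max = float(image.depth[valid].max())
    return d_max * K


def segment_foreground(image: DepthImage, threshold: float) -> ForegroundMask:
    """Binary foreground mask: f(x, y) = 1 iff d(x, y) < threshold.

    Boundary pixels (d == threshold) and invalid pixels are background.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    flags = (image.depth < threshold) & image.valid_mask
    return ForegroundMask(flags=flags.astype(np.uint8))


def segment(image: DepthImage, K: float = DEFAULT_K) -> ForegroundMask:
    """Convenience wrapper: compute the threshold, then segment."""
    return segment_foreground(image, compute_threshold(image, K))
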