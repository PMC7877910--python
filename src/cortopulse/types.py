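"""Core containers shared across the pipeline.

Conventions: images are ``(T, Y, X)`` float arrays, origin at the top-left
pixel, y increasing downward, 0-based indices; pixel centers sit at
``(index + 0.5) * pixel_size_um`` in physical coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageStack", "RegionMask"]


@dataclass
class ImageStack:
    """A time-lapse fluorescence stack with physical calibration.

    Parameters
    ----------
    data
        ``(T, Y, X)`` intensity array. A single frame may be stored as
        ``(1, Y, X)``.
    pixel_size_um
        Lateral pixel size in micrometres.
    frame_interval_s
        Time between consecutive frames in seconds.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("ImageStack data must be (T, Y, X)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def duration_min(self) -> float:
        return self.n_frames * self.frame_interval_s / 60.0

    @property
    def extent_um(self) -> tuple[float, float]:
        """Physical (width, height) of a frame in micrometres."""
        ny, nx = self.frame_shape
        return nx * self.pixel_size_um, ny * self.pixel_size_um


@dataclass
class RegionMask:
    """Boolean pixel mask with the same geometry conventions as ImageStack."""

    mask: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("RegionMask must be 2D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size_um**2

    def __and__(self, other: "RegionMask") -> "RegionMask":
        return RegionMask(self.mask & other.mask, self.pixel_size_um)

    def __invert__(self) -> "RegionMask":
        return RegionMask(~self.mask, self.pixel_size_um)

    def minus(self, other: "RegionMask") -> "RegionMask":
        return RegionMask(self.mask & ~other.mask, self.pixel_size_um)

    def pixel_centers_um(self) -> np.ndarray:
        """``(N, 2)`` array of (x, y) centers of the True pixels."""
        iy, ix = np.nonzero(self.mask)
        return np.column_stack(((ix + 0.5), (iy + 0.5))) * self.pixel_size_um

    def contains_points(self, xy_um: np.ndarray) -> np.ndarray:
        """Vectorized point-in-mask lookup for (x, y) µm coordinates."""
        xy = np.atleast_2d(np.asarray(xy_um, dtype=float))
        j = np.floor(xy[:, 0] / self.pixel_size_um).astype(int)
        i = np.floor(xy[:, 1] / self.pixel_size_um).astype(int)
        ny, nx = self.mask.shape
        inside = (i >= 0) & (i < ny) & (j >= 0) & (j < nx)
        out = np.zeros(len(xy), dtype=bool)
        out[inside] = self.mask[i[inside], j[inside]]
        return out


def ellipse_mask(
    shape: tuple[int, int],
    pixel_size_um: float,
    center_um: tuple[float, float],
    semi_axes_um: tuple[float, float],
    angle_deg: float = 0.0,
) -> RegionMask:
    """Rasterize an ellipse to a boolean mask (pixel-center inclusion test)."""
    ny, nx = shape
    a, b = semi_axes_um
    if a <= 0 or b <= 0:
        raise ValueError("ellipse semi-axes must be positive")
    x = (np.arange(nx) + 0.5) * pixel_size_um - center_um[0]
    y = (np.arange(ny) + 0.5) * pixel_size_um - center_um[1]
    xx, yy = np.meshgrid(x, y)
    th = np.deg2rad(angle_deg)
    xr = xx * np.cos(th) + yy * np.sin(th)
    yr = -xx * np.sin(th) + yy * np.cos(th)
    return RegionMask((xr / a) ** 2 + (yr / b) ** 2 <= 1.0, pixel_size_um)
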