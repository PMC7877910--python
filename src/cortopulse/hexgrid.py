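"""Hexagonal tessellation of a region of interest.

The ventral-cortex movies are binned into a pointy-top hexagonal lattice in
axial coordinates (q, r).  A hexagon of circumradius ``R`` (center-to-vertex,
µm) has center::

    x = sqrt(3) * R * (q + r / 2)
    y = 1.5 * R * r

Pixels are assigned to the hexagon whose center is nearest (exact cube
rounding), so the included hexagons partition the ROI without overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import RegionMask

__all__ = ["HexGrid", "build_hex_grid"]

_SQRT3 = np.sqrt(3.0)

# axial neighbor offsets of a pointy-top hexagon
NEIGHBOR_OFFSETS = ((+1, 0), (+1, -1), (0, -1), (-1, 0), (-1, +1), (0, +1))


@dataclass
class HexGrid:
    """Hexagonal binning of an ROI.

    Attributes
    ----------
    hex_radius_um
        Circumradius (center-to-vertex) of each hexagon, µm.
    centers_um
        ``(n_hex, 2)`` array of (x, y) hexagon centers, µm.
    axial
        ``(n_hex, 2)`` integer axial indices (q, r).
    adjacency
        Tuple of neighbor index tuples, one per hexagon (≤ 6 entries each,
        symmetric).
    labels
        2D int array over the ROI raster: pixel -> hexagon index, or -1 for
        pixels outside the ROI or in excluded boundary hexagons.
    pixel_size_um
        Raster pixel size, µm.
    """

    hex_radius_um: float
    centers_um: np.ndarray
    axial: np.ndarray
    adjacency: tuple[tuple[int, ...], ...]
    labels: np.ndarray
    pixel_size_um: float

    @property
    def n_hex(self) -> int:
        return len(self.centers_um)

    @property
    def hex_area_um2(self) -> float:
        return 1.5 * _SQRT3 * self.hex_radius_um**2

    def pixel_counts(self) -> np.ndarray:
        valid = self.labels[self.labels >= 0]
        return np.bincount(valid, minlength=self.n_hex)


def _axial_round(qf: np.ndarray, rf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Round fractional axial coordinates to the nearest hexagon (cube round)."""
    xf, zf = qf, rf
    yf = -xf - zf
    rx, ry, rz = np.round(xf), np.round(yf), np.round(zf)
    dx, dy, dz = np.abs(rx - xf), np.abs(ry - yf), np.abs(rz - zf)
    fix_x = (dx > dy) & (dx > dz)
    fix_z = ~fix_x & (dz > dy)
    rx = np.where(fix_x, -ry - rz, rx)
    rz = np.where(fix_z, -rx - ry, rz)
    return rx.astype(int), rz.astype(int)


def pixel_to_axial(
    x_um: np.ndarray, y_um: np.ndarray, hex_radius_um: float
) -> tuple[np.ndarray, np.ndarray]:
    """Fractional-axial transform followed by exact rounding."""
    qf = (_SQRT3 / 3.0 * x_um - y_um / 3.0) / hex_radius_um
    rf = (2.0 / 3.0 * y_um) / hex_radius_um
    return _axial_round(np.asarray(qf, float), np.asarray(rf, float))


def axial_center(q: np.ndarray, r: np.ndarray, hex_radius_um: float) -> np.ndarray:
    x = _SQRT3 * hex_radius_um * (np.asarray(q, float) + np.asarray(r, float) / 2.0)
    y = 1.5 * hex_radius_um * np.asarray(r, float)
    return np.column_stack((x, y))


def build_hex_grid(
    roi: RegionMask, hex_radius_um: float, pixel_size_um: float | None = None
) -> HexGrid:
    """Tile an ROI with pointy-top hexagons.

    Only hexagons whose *center* falls inside the ROI are included; ROI
    pixels belonging to excluded boundary hexagons are left unassigned
    (label -1).

    Raises
    ------
    ValueError
        If the ROI is empty or the hexagon radius spans fewer than two
        pixels (binning degenerate).
    """
    px = pixel_size_um if pixel_size_um is not None else roi.pixel_size_um
    if not np.any(roi.mask):
        raise ValueError("ROI mask is empty")
    if hex_radius_um < 2.0 * px:
        raise ValueError(
            f"hex_radius_um={hex_radius_um} spans fewer than 2 pixels "
            f"(pixel size {px} um); binning degenerate"
        )

    ny, nx = roi.mask.shape
    iy, ix = np.nonzero(roi.mask)
    xc = (ix + 0.5) * px
    yc = (iy + 0.5) * px
    q, r = pixel_to_axial(xc, yc, hex_radius_um)

    # candidate hexagons: any hexagon that owns at least one ROI pixel
    cand = np.unique(np.column_stack((q, r)), axis=0)
    centers = axial_center(cand[:, 0], cand[:, 1], hex_radius_um)
    keep = roi.contains_points(centers)
    cand, centers = cand[keep], centers[keep]

    index = {(int(a), int(b)): i for i, (a, b) in enumerate(cand)}
    labels = np.full((ny, nx), -1, dtype=int)
    hex_ids = np.array([index.get((int(a), int(b)), -1) for a, b in zip(q, r)])
    labels[iy, ix] = hex_ids

    adjacency = []
    for a, b in cand:
        nbrs = []
        for dq, dr in NEIGHBOR_OFFSETS:
            j = index.get((int(a) + dq, int(b) + dr))
            if j is not None:
                nbrs.append(j)
        adjacency.append(tuple(nbrs))

    return HexGrid(
        hex_radius_um=float(hex_radius_um),
        centers_um=centers,
        axial=cand,
        adjacency=tuple(adjacency),
        labels=labels,
        pixel_size_um=px,
    )
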