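"""Cortical stress-fiber classification, kinetics, flow and kymographs.

The classifier consumes track tables (one row per fiber; columns documented
in :func:`classify_fibers`) rather than raw movies, mirroring manual
blind scoring.  Live-cell inclusion rules: end-to-end length at most 10 µm,
persistence of at least 2 min, a focal adhesion at both ends (a shared
adhesion counts for each fiber using it), and — for the under-nucleus label
— at least one adhesion inside the nucleus footprint.  Fixed-cell rules:
adhesion at both ends, at least partial overlap with the nucleus footprint,
and length smaller than the nucleus diameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import ImageStack, RegionMask

__all__ = [
    "ClassificationCriteria",
    "classify_fibers",
    "fraction_under_nucleus",
    "lifetime_stats",
    "track_focus_speed",
    "build_kymograph",
]


@dataclass
class ClassificationCriteria:
    """Inclusion rules for cortical stress fibers.

    ``mode='live'`` applies the time-lapse rules (length, persistence,
    adhesions at both ends); ``mode='fixed'`` the snapshot rules (length
    below the nucleus diameter, adhesions at both ends, partial nucleus
    overlap).
    """

    mode: str = "live"
    max_length_um: float = 10.0
    min_persistence_min: float = 2.0
    require_fa_both_ends: bool = True
    shared_fa_allowed: bool = True
    nucleus_diameter_um: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("live", "fixed"):
            raise ValueError("mode must be 'live' or 'fixed'")
        if self.max_length_um <= 0 or self.min_persistence_min <= 0:
            raise ValueError("criteria thresholds must be positive")
        if self.mode == "fixed" and self.nucleus_diameter_um is None:
            raise ValueError("fixed mode needs nucleus_diameter_um")


_REQUIRED = ("length_um", "n_adhesions")


def classify_fibers(
    table: pd.DataFrame, criteria: ClassificationCriteria | None = None
) -> pd.DataFrame:
    """Apply the inclusion rules to a fiber track table.

    Expects columns ``length_um``, ``n_adhesions``,
    ``adh1_under_nucleus`` / ``adh2_under_nucleus`` (booleans), and, for
    live mode, ``lifetime_min``; ``nucleus_overlap`` is required in fixed
    mode.  Adds ``is_cortical``, ``under_nucleus``, ``unclassifiable`` and a
    semicolon-joined ``exclusion_reason``.  Records with missing adhesion
    data are flagged unclassifiable, never dropped.
    """
    crit = criteria or ClassificationCriteria()
    for col in _REQUIRED:
        if col not in table.columns:
            raise ValueError(f"missing required column {col!r}")
    if crit.mode == "live" and "lifetime_min" not in table.columns:
        raise ValueError("live mode needs a lifetime_min column")
    if crit.mode == "fixed" and "nucleus_overlap" not in table.columns:
        raise ValueError("fixed mode needs a nucleus_overlap column")

    out = table.copy()
    is_cortical = np.ones(len(out), dtype=bool)
    under = np.zeros(len(out), dtype=bool)
    unclassifiable = np.zeros(len(out), dtype=bool)
    reasons: list[list[str]] = [[] for _ in range(len(out))]

    n_adh = out["n_adhesions"].to_numpy()
    missing_adh = pd.isna(out["n_adhesions"]).to_numpy()
    length = out["length_um"].to_numpy(dtype=float)

    if crit.mode == "live":
        max_len = crit.max_length_um
    else:
        max_len = crit.nucleus_diameter_um

    for i in range(len(out)):
        if missing_adh[i] and crit.require_fa_both_ends:
            unclassifiable[i] = True
            is_cortical[i] = False
            reasons[i].append("missing_adhesion_data")
            continue
        too_long = (
            length[i] > max_len if crit.mode == "live" else length[i] >= max_len
        )
        if too_long:
            is_cortical[i] = False
            reasons[i].append("too_long")
        if crit.mode == "live":
            lt = float(out["lifetime_min"].iloc[i])
            if lt < crit.min_persistence_min:
                is_cortical[i] = False
                reasons[i].append("too_short_lived")
        if crit.require_fa_both_ends and n_adh[i] < 2:
            is_cortical[i] = False
            reasons[i].append("missing_end_adhesion")
        if crit.mode == "fixed" and not bool(out["nucleus_overlap"].iloc[i]):
            is_cortical[i] = False
            reasons[i].append("no_nucleus_overlap")
        if is_cortical[i]:
            if crit.mode == "live":
                a1 = bool(out.get("adh1_under_nucleus", pd.Series(False, index=out.index)).iloc[i])
                a2 = bool(out.get("adh2_under_nucleus", pd.Series(False, index=out.index)).iloc[i])
                under[i] = a1 or a2
            else:
                under[i] = bool(out["nucleus_overlap"].iloc[i])

    out["is_cortical"] = is_cortical
    out["under_nucleus"] = under
    out["unclassifiable"] = unclassifiable
    out["exclusion_reason"] = [";".join(r) for r in reasons]
    return out


def fraction_under_nucleus(
    labeled: pd.DataFrame, per_cell: bool = True
) -> tuple[float, float, int]:
    """Percentage of cortical fibers assembled under the nucleus.

    With ``per_cell=True`` (default) the percentage is computed per cell and
    averaged, and the SEM is taken over cells — matching a cohort-level
    mean ± SEM report.  With ``per_cell=False`` fibers are pooled.  Returns
    ``(percent, sem, n)`` where ``n`` is the number of cells (or fibers).
    """
    cortical = labeled[labeled["is_cortical"]]
    if len(cortical) == 0:
        raise ValueError("no cortical fibers to summarize")
    if per_cell:
        if "cell_id" not in cortical.columns:
            raise ValueError("per-cell mode needs a cell_id column")
        pct = cortical.groupby("cell_id")["under_nucleus"].mean() * 100.0
        n = len(pct)
        sem = float(pct.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        return float(pct.mean()), sem, n
    frac = float(cortical["under_nucleus"].mean()) * 100.0
    n = len(cortical)
    sem = float(np.sqrt(frac / 100.0 * (1 - frac / 100.0) / n) * 100.0)
    return frac, sem, n


def lifetime_stats(labeled: pd.DataFrame) -> dict:
    """Median lifetime (the half-life summary), IQR and range, in minutes.

    Rows with a truthy ``censored`` column are excluded from the median and
    reported separately under ``n_censored``.
    """
    sub = labeled[labeled["is_cortical"]] if "is_cortical" in labeled.columns else labeled
    censored = (
        sub["censored"].astype(bool)
        if "censored" in sub.columns
        else pd.Series(False, index=sub.index)
    )
    observed = sub.loc[~censored, "lifetime_min"].to_numpy(dtype=float)
    if len(observed) == 0:
        raise ValueError("no uncensored lifetimes")
    q1, med, q3 = np.percentile(observed, [25, 50, 75])
    return {
        "median_min": float(med),
        "iqr_min": float(q3 - q1),
        "range_min": (float(observed.min()), float(observed.max())),
        "n": int(len(observed)),
        "n_censored": int(censored.sum()),
    }


def track_focus_speed(
    stack: ImageStack,
    roi: RegionMask | tuple[slice, slice] | None = None,
    t_range: tuple[int, int] | None = None,
) -> float:
    """Speed of a photoactivated focus in µm/min.

    Tracks the background-subtracted intensity-weighted centroid inside the
    ROI frame by frame and fits least-squares lines to x(t) and y(t); the
    speed is the magnitude of the fitted velocity vector.  Raises when the
    focus contrast is below twice the local background.
    """
    data = stack.data
    if t_range is not None:
        data = data[t_range[0] : t_range[1]]
    if data.shape[0] < 2:
        raise ValueError("need at least two frames")
    if roi is None:
        mask = np.ones(data.shape[1:], dtype=bool)
    elif isinstance(roi, RegionMask):
        mask = roi.mask
    else:
        mask = np.zeros(data.shape[1:], dtype=bool)
        mask[roi] = True
    if not mask.any():
        raise ValueError("empty ROI")

    iy, ix = np.nonzero(mask)
    px = stack.pixel_size_um
    pos = np.empty((data.shape[0], 2))
    for t in range(data.shape[0]):
        vals = data[t][iy, ix]
        bg = float(np.median(vals))
        if vals.max() < 2.0 * bg:
            raise ValueError("focus below the contrast floor (max < 2x background)")
        # weight only clearly supra-background pixels: rectified noise over
        # the whole ROI would otherwise drag the centroid toward the ROI
        # center and compress the measured motion
        w = np.clip(vals - bg - 0.25 * (vals.max() - bg), 0.0, None)
        pos[t, 0] = np.average((ix + 0.5) * px, weights=w)
        pos[t, 1] = np.average((iy + 0.5) * px, weights=w)
    t_min = np.arange(data.shape[0]) * stack.frame_interval_s / 60.0
    vx = np.polyfit(t_min, pos[:, 0], 1)[0]
    vy = np.polyfit(t_min, pos[:, 1], 1)[0]
    return float(np.hypot(vx, vy))


def build_kymograph(
    stack: ImageStack,
    polyline_um: np.ndarray,
    line_width_px: int = 1,
    reduce: str = "max",
) -> tuple[np.ndarray, np.ndarray]:
    """Distance-versus-time intensity map along a polyline.

    The polyline (``(N, 2)`` (x, y) µm vertices) is resampled at pixel
    pitch; each kymograph column is one frame, each row one position along
    the line, reduced across ``line_width_px`` perpendicular offsets by max
    (default) or mean.  Width 1 is direct line sampling.  Returns
    ``(kymograph, distances_um)`` with shape ``(n_positions, n_frames)``.
    """
    if reduce not in ("max", "mean"):
        raise ValueError("reduce must be 'max' or 'mean'")
    if line_width_px < 1:
        raise ValueError("line_width_px must be >= 1")
    verts = np.atleast_2d(np.asarray(polyline_um, dtype=float))
    if len(verts) < 2:
        raise ValueError("polyline needs at least two vertices")
    px = stack.pixel_size_um
    ny, nx = stack.frame_shape
    if (
        verts[:, 0].min() < 0 or verts[:, 0].max() > nx * px
        or verts[:, 1].min() < 0 or verts[:, 1].max() > ny * px
    ):
        raise ValueError("polyline outside image bounds")

    # resample at pixel pitch
    seg = np.diff(verts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    n_samples = max(int(np.floor(total / px)) + 1, 2)
    s = np.linspace(0.0, total, n_samples)
    xs = np.interp(s, cum, verts[:, 0])
    ys = np.interp(s, cum, verts[:, 1])
    # unit tangents and normals per sample
    tx = np.gradient(xs, s)
    ty = np.gradient(ys, s)
    norm = np.hypot(tx, ty)
    norm[norm == 0] = 1.0
    nxv, nyv = -ty / norm, tx / norm

    offsets = (np.arange(line_width_px) - (line_width_px - 1) / 2.0) * px
    kymo = np.empty((n_samples, stack.n_frames))
    cols_i = (ys[:, None] + np.outer(nyv, offsets)) / px - 0.5
    cols_j = (xs[:, None] + np.outer(nxv, offsets)) / px - 0.5
    for t in range(stack.n_frames):
        samples = ndimage.map_coordinates(
            stack.data[t], [cols_i.ravel(), cols_j.ravel()], order=1, mode="nearest"
        ).reshape(n_samples, line_width_px)
        kymo[:, t] = samples.max(axis=1) if reduce == "max" else samples.mean(axis=1)
    return kymo, s
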