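"""NMII pulse detection on a hexagonal tessellation of the ventral cortex.

The detector mirrors the hexagon-based pulse bookkeeping used for cortical
myosin dynamics: per-hexagon mean intensity traces are normalized to a
pulse-insensitive background estimate, thresholded at a signal/background
ratio (default 1.3), cleaned of connected components smaller than three
hexagons per frame, linked across consecutive frames by hexagon overlap, and
finally filtered to events persisting more than three frames and starting
within the analysis window (default the first 30 min).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.restoration import rolling_ball

from .hexgrid import HexGrid
from .types import ImageStack, RegionMask

__all__ = [
    "HexSeries",
    "PulseEvent",
    "subtract_background_rolling_ball",
    "compute_hex_series",
    "detect_pulses",
    "assign_region",
]


def subtract_background_rolling_ball(stack: ImageStack, radius_px: int = 50) -> ImageStack:
    """Rolling-ball background subtraction, frame by frame.

    Removes large-scale background while preserving small bright features;
    output is clipped to be non-negative.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    ny, nx = stack.frame_shape
    if radius_px > max(ny, nx):
        raise ValueError("rolling-ball radius exceeds the image size")
    out = np.empty_like(stack.data)
    for t in range(stack.n_frames):
        bg = rolling_ball(stack.data[t], radius=radius_px)
        out[t] = np.clip(stack.data[t] - bg, 0.0, None)
    return ImageStack(out, stack.pixel_size_um, stack.frame_interval_s)


@dataclass
class HexSeries:
    """Per-hexagon intensity traces and their background-normalized ratios.

    ``intensity`` is (n_hex, n_frames) mean pixel intensity; ``baseline`` the
    per-hexagon background estimate; ``ratio = intensity / baseline`` is the
    operand of the pulse threshold.
    """

    intensity: np.ndarray
    baseline: np.ndarray
    frame_interval_s: float = 0.0

    def __post_init__(self) -> None:
        if np.any(self.baseline <= 0):
            raise ValueError("baseline must be positive for every hexagon")
        self.ratio = self.intensity / self.baseline[:, None]
        if not np.all(np.isfinite(self.ratio)):
            raise ValueError("non-finite intensity ratios")

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[1]


def compute_hex_series(
    stack: ImageStack,
    grid: HexGrid,
    baseline: str = "hex_median",
    window_frames: int | None = None,
) -> HexSeries:
    """Mean intensity per hexagon per frame, normalized to a background.

    ``baseline='hex_median'`` (default) uses each hexagon's temporal median
    over the analysis window — robust to static spatial heterogeneity and
    insensitive to sparse pulses.  ``baseline='roi_median'`` uses a single
    global median over all hexagons and window frames.
    """
    labels = grid.labels
    valid = labels >= 0
    flat_labels = labels[valid]
    counts = np.bincount(flat_labels, minlength=grid.n_hex).astype(float)
    if np.any(counts == 0):
        raise ValueError("hexagon without assigned pixels; grid inconsistent")
    inten = np.empty((grid.n_hex, stack.n_frames))
    for t in range(stack.n_frames):
        sums = np.bincount(flat_labels, weights=stack.data[t][valid], minlength=grid.n_hex)
        inten[:, t] = sums / counts
    w = stack.n_frames if window_frames is None else min(window_frames, stack.n_frames)
    if baseline == "hex_median":
        base = np.median(inten[:, :w], axis=1)
    elif baseline == "roi_median":
        base = np.full(grid.n_hex, np.median(inten[:, :w]))
    else:
        raise ValueError(f"unknown baseline mode {baseline!r}")
    return HexSeries(inten, base, stack.frame_interval_s)


@dataclass
class PulseEvent:
    """One linked pulse: contiguous frames, per-frame active hexagon sets."""

    event_id: int
    active_hexagons: dict[int, frozenset[int]]
    peak_ratio: float
    peak_frame: int
    region_label: str | None = None

    @property
    def start_frame(self) -> int:
        return min(self.active_hexagons)

    @property
    def end_frame(self) -> int:
        return max(self.active_hexagons)

    @property
    def duration_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    def max_area_um2(self, grid: HexGrid) -> float:
        return max(len(s) for s in self.active_hexagons.values()) * grid.hex_area_um2

    def centroid_um(self, grid: HexGrid, frame: int | None = None) -> np.ndarray:
        f = self.peak_frame if frame is None else frame
        idx = sorted(self.active_hexagons[f])
        return grid.centers_um[idx].mean(axis=0)


def _frame_components(
    active: np.ndarray, adjacency: tuple[tuple[int, ...], ...]
) -> list[set[int]]:
    """Connected components (hexagon 6-adjacency) of the active set."""
    todo = set(np.nonzero(active)[0].tolist())
    comps: list[set[int]] = []
    while todo:
        seed = min(todo)
        comp = {seed}
        stack = [seed]
        todo.discard(seed)
        while stack:
            h = stack.pop()
            for nb in adjacency[h]:
                if nb in todo:
                    todo.discard(nb)
                    comp.add(nb)
                    stack.append(nb)
        comps.append(comp)
    comps.sort(key=min)
    return comps


def detect_pulses(
    series: HexSeries,
    grid: HexGrid,
    threshold_ratio: float = 1.3,
    min_component_size: int = 3,
    min_duration_frames: int = 4,
    window_frames: int | None = None,
) -> list[PulseEvent]:
    """Threshold, component-filter, link, and duration/window-filter pulses.

    Per frame, a hexagon is active when its ratio >= ``threshold_ratio``;
    connected components with fewer than ``min_component_size`` hexagons are
    discarded (removing isolated bright puncta).  Components in consecutive
    frames sharing at least one hexagon belong to the same event; a component
    overlapping several open events merges them (deterministically into the
    lowest event id; same-frame components are processed in order of their
    smallest hexagon index).  Events shorter than ``min_duration_frames``
    frames (default 4, i.e. persisting *more than* three frames) or starting
    at/after ``window_frames`` are dropped.
    """
    if threshold_ratio <= 0 or min_component_size < 1 or min_duration_frames < 1:
        raise ValueError("thresholds must be positive")
    if grid.n_hex != series.intensity.shape[0]:
        raise ValueError("series and grid are inconsistent")
    n_frames = series.n_frames
    if window_frames is not None and window_frames > n_frames:
        warnings.warn(
            "analysis window exceeds the stack length; clipping to the movie",
            stacklevel=2,
        )
        window_frames = n_frames

    events: dict[int, dict[int, set[int]]] = {}
    open_prev: dict[int, set[int]] = {}  # event id -> active set at frame t-1
    next_id = 0
    for t in range(n_frames):
        active = series.ratio[:, t] >= threshold_ratio
        comps = [
            c for c in _frame_components(active, grid.adjacency)
            if len(c) >= min_component_size
        ]
        open_now: dict[int, set[int]] = {}
        for comp in comps:
            touching = sorted(
                eid for eid, prev in open_prev.items() if prev & comp
            )
            if not touching:
                eid = next_id
                next_id += 1
                events[eid] = {}
            else:
                eid = min(touching)
                for other in touching:
                    if other == eid:
                        continue
                    # merge: union frame-wise activity into the lowest id
                    for f, s in events[other].items():
                        events[eid].setdefault(f, set()).update(s)
                    events.pop(other)
                    if other in open_prev:
                        open_prev[eid] = open_prev.get(eid, set()) | open_prev.pop(other)
                    if other in open_now:
                        open_now[eid] = open_now.get(eid, set()) | open_now.pop(other)
            events[eid].setdefault(t, set()).update(comp)
            open_now[eid] = open_now.get(eid, set()) | comp
        open_prev = open_now

    out: list[PulseEvent] = []
    for eid in sorted(events):
        frames = events[eid]
        start = min(frames)
        dur = max(frames) - start + 1
        if dur < min_duration_frames:
            continue
        if window_frames is not None and start >= window_frames:
            continue
        peak_frame, peak_ratio = start, -np.inf
        for f, s in frames.items():
            r = float(series.ratio[sorted(s), f].max())
            if r > peak_ratio:
                peak_ratio, peak_frame = r, f
        out.append(
            PulseEvent(
                event_id=eid,
                active_hexagons={f: frozenset(s) for f, s in sorted(frames.items())},
                peak_ratio=peak_ratio,
                peak_frame=peak_frame,
            )
        )
    out.sort(key=lambda e: (e.start_frame, e.event_id))
    for new_id, ev in enumerate(out):
        ev.event_id = new_id
    return out


def assign_region(
    events: list[PulseEvent], nucleus_mask: RegionMask, grid: HexGrid
) -> list[PulseEvent]:
    """Label each event by where it peaks.

    An event is ``under_nucleus`` when the strict majority of its peak-frame
    active-hexagon centers fall inside the nucleus footprint, else
    ``outside``.  Events are labeled in place and returned.
    """
    for ev in events:
        hexes = sorted(ev.active_hexagons[ev.peak_frame])
        inside = nucleus_mask.contains_points(grid.centers_um[hexes])
        ev.region_label = (
            "under_nucleus" if 2 * int(inside.sum()) > len(hexes) else "outside"
        )
    return events
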