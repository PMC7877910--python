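"""Synthetic ground-truth data for every pipeline stage.

The generator emulates TIRF movies of the ventral actin cortex: a flat
cortical background plus stochastic, spatially localized non-muscle myosin II
(NMII) pulses whose rate differs under the nucleus footprint and outside it;
elastic-substrate bead images driven by a forward Boussinesq model; and
tabular stress-fiber track records.  All randomness flows through a single
integer seed so each output is bit-reproducible.

Pulse model
-----------
Each pulse is a separable product of a spatial Gaussian (sd
``pulse_sigma_um``) and a temporal raised-cosine envelope.  The *duration*
parameter is the envelope's full width at half maximum (FWHM) in frames; the
full support is twice that.  At its spatiotemporal peak a pulse raises the
local intensity to ``amplitude_ratio x baseline`` before noise.  Pulse counts
per region are Poisson with mean ``rate x region area x movie duration``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely import affinity
from shapely.geometry import LineString, Point

from .types import ImageStack, RegionMask, ellipse_mask

__all__ = [
    "PulseSimParams",
    "PulseRecord",
    "PulseSimOutput",
    "FiberSimParams",
    "generate_pulse_stack",
    "sample_pulse_events",
    "generate_fiber_table",
    "generate_focus_stack",
]


@dataclass
class PulseSimParams:
    """Parameters of the cortical NMII pulse movie simulator.

    Defaults describe a 30 min TIRF acquisition of a migrating-cell ventral
    cortex: 0.08 µm pixels, 10 s frame interval, a nucleus footprint of
    ~151 µm² (<30% of the 720 µm² field), and pulses that peak at twice the
    cortical background.  ``pulse_rate_in`` / ``pulse_rate_out`` are event
    rates in events / µm² / min under the nucleus and outside it.
    """

    field_size_um: tuple[float, float] = (42.0, 30.0)
    pixel_size_um: float = 0.08
    frame_interval_s: float = 10.0
    n_frames: int = 180
    nucleus_ellipse: tuple[tuple[float, float], tuple[float, float], float] = (
        (21.0, 15.0),
        (12.0, 9.0),
        0.0,
    )
    baseline_intensity: float = 100.0
    pulse_rate_in: float = 0.0015
    pulse_rate_out: float = 0.00075
    amplitude_ratio: float = 2.0
    pulse_sigma_um: float = 1.2
    # (mean, sd, min) of the envelope FWHM in frames
    pulse_duration_frames: tuple[float, float, float] = (6.0, 1.0, 5.0)
    noise_gaussian_sd: float = 5.0
    noise_poisson: bool = True
    edge_margin_um: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        w, h = self.field_size_um
        (cx, cy), (a, b), ang = self.nucleus_ellipse
        if self.pulse_rate_in < 0 or self.pulse_rate_out < 0:
            raise ValueError("pulse rates must be >= 0")
        if self.amplitude_ratio < 1:
            raise ValueError("amplitude_ratio must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel size and frame interval must be positive")
        th = math.radians(ang)
        half_w = math.hypot(a * math.cos(th), b * math.sin(th))
        half_h = math.hypot(a * math.sin(th), b * math.cos(th))
        if cx - half_w < 0 or cx + half_w > w or cy - half_h < 0 or cy + half_h > h:
            raise ValueError("nucleus ellipse does not fit inside the field")

    @property
    def shape(self) -> tuple[int, int]:
        w, h = self.field_size_um
        return int(round(h / self.pixel_size_um)), int(round(w / self.pixel_size_um))

    @property
    def duration_min(self) -> float:
        return self.n_frames * self.frame_interval_s / 60.0


@dataclass
class PulseRecord:
    """Ground truth for one simulated pulse.

    ``start_frame`` / ``end_frame`` delimit the FWHM span of the temporal
    envelope (the frames on which the pulse runs at >= half its peak
    amplitude); the rendered support extends one FWHM on either side of
    ``peak_frame``.
    """

    center_um: tuple[float, float]
    peak_frame: float
    fwhm_frames: float
    peak_ratio: float
    region_label: str  # "under_nucleus" | "outside"

    @property
    def start_frame(self) -> int:
        return int(math.ceil(self.peak_frame - self.fwhm_frames / 2.0))

    @property
    def end_frame(self) -> int:
        return int(math.floor(self.peak_frame + self.fwhm_frames / 2.0))

    def envelope(self, frames: np.ndarray) -> np.ndarray:
        """Raised-cosine temporal envelope, 1 at the peak, FWHM as stated."""
        tau = (np.asarray(frames, float) - self.peak_frame) / self.fwhm_frames
        env = 0.5 * (1.0 + np.cos(np.pi * tau))
        return np.where(np.abs(tau) <= 1.0, env, 0.0)


@dataclass
class PulseSimOutput:
    stack: ImageStack
    roi_mask: RegionMask
    nucleus_mask: RegionMask
    ground_truth: list[PulseRecord]

    def __iter__(self):
        return iter((self.stack, self.roi_mask, self.nucleus_mask, self.ground_truth))


def _roi_and_nucleus(params: PulseSimParams) -> tuple[RegionMask, RegionMask]:
    """Analysis ROI (field minus an edge margin, emulating the exclusion of
    cell edges from the analyzed cortex) and the nucleus footprint."""
    shape = params.shape
    px = params.pixel_size_um
    ny, nx = shape
    m = np.zeros(shape, dtype=bool)
    k = int(round(params.edge_margin_um / px))
    if 2 * k >= min(ny, nx):
        raise ValueError("edge margin leaves no ROI")
    m[k : ny - k, k : nx - k] = True
    roi = RegionMask(m, px)
    (c, ax, ang) = params.nucleus_ellipse
    nuc = ellipse_mask(shape, px, c, ax, ang)
    nuc.mask &= roi.mask
    return roi, nuc


def sample_pulse_events(
    params: PulseSimParams, rng: np.random.Generator | None = None
) -> list[PulseRecord]:
    """Draw the ground-truth pulse events without rendering any pixels.

    Counts per region are Poisson(rate x mask area x movie minutes); centers
    are uniform over the respective region; peak times are uniform over the
    frames at which the full envelope support fits inside the movie.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    roi, nuc = _roi_and_nucleus(params)
    outside = roi.minus(nuc)
    t_min = params.duration_min
    mu, sd, dmin = params.pulse_duration_frames

    events: list[PulseRecord] = []
    for label, region, rate in (
        ("under_nucleus", nuc, params.pulse_rate_in),
        ("outside", outside, params.pulse_rate_out),
    ):
        lam = rate * region.area_um2 * t_min
        n = int(rng.poisson(lam)) if lam > 0 else 0
        if n == 0:
            continue
        centers = region.pixel_centers_um()
        idx = rng.integers(0, len(centers), size=n)
        # jitter within the chosen pixel so centers are continuous
        jit = (rng.random((n, 2)) - 0.5) * params.pixel_size_um
        pos = centers[idx] + jit
        durs = np.maximum(rng.normal(mu, sd, size=n), dmin)
        durs = np.minimum(durs, (params.n_frames - 1) / 2.0)
        lo, hi = durs, params.n_frames - 1 - durs
        peaks = lo + (hi - lo) * rng.random(n)
        for (x, y), tp, d in zip(pos, peaks, durs):
            events.append(
                PulseRecord(
                    center_um=(float(x), float(y)),
                    peak_frame=float(tp),
                    fwhm_frames=float(d),
                    peak_ratio=params.amplitude_ratio,
                    region_label=label,
                )
            )
    events.sort(key=lambda e: (e.peak_frame, e.center_um))
    return events


def generate_pulse_stack(params: PulseSimParams) -> PulseSimOutput:
    """Render a pulse movie with ground truth.

    Returns the stack, the analysis ROI mask, the nucleus footprint mask and
    the list of ground-truth :class:`PulseRecord`.  With both rates zero the
    stack is baseline plus noise only.  Identical parameters (including
    seed) give bit-identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    roi, nuc = _roi_and_nucleus(params)
    events = sample_pulse_events(params, rng)

    ny, nx = params.shape
    px = params.pixel_size_um
    data = np.full((params.n_frames, ny, nx), params.baseline_intensity, dtype=float)

    amp = params.baseline_intensity * (params.amplitude_ratio - 1.0)
    sig = params.pulse_sigma_um
    half_px = int(math.ceil(4.0 * sig / px))
    for ev in events:
        cx, cy = ev.center_um
        jc, ic = int(cx / px), int(cy / px)
        j0, j1 = max(jc - half_px, 0), min(jc + half_px + 1, nx)
        i0, i1 = max(ic - half_px, 0), min(ic + half_px + 1, ny)
        xs = (np.arange(j0, j1) + 0.5) * px - cx
        ys = (np.arange(i0, i1) + 0.5) * px - cy
        g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2.0 * sig**2))
        t0 = max(int(math.ceil(ev.peak_frame - ev.fwhm_frames)), 0)
        t1 = min(int(math.floor(ev.peak_frame + ev.fwhm_frames)), params.n_frames - 1)
        frames = np.arange(t0, t1 + 1)
        env = ev.envelope(frames)
        data[t0 : t1 + 1, i0:i1, j0:j1] += amp * env[:, None, None] * g[None]

    if params.noise_poisson:
        data = rng.poisson(np.clip(data, 0, None)).astype(float)
    if params.noise_gaussian_sd > 0:
        data += rng.normal(0.0, params.noise_gaussian_sd, size=data.shape)

    stack = ImageStack(data, px, params.frame_interval_s)
    return PulseSimOutput(stack, roi, nuc, events)


# ---------------------------------------------------------------------------
# stress-fiber track tables


@dataclass
class FiberSimParams:
    """Simulated cohort of stress-fiber track records.

    Emulates a cohort of ~19 cells with ~5 tracked fibers each.  Lengths are
    log-normal around ~5 µm, lifetimes exponential with a 25 min median, and
    a fiber acquires at least one adhesion under the nucleus footprint with
    probability ``fraction_under_nucleus``.
    """

    n_fibers: int = 101
    n_cells: int = 19
    length_um: tuple[float, float] = (5.0, 0.4)  # log-normal: median, sigma(log)
    lifetime_median_min: float = 25.0
    adhesion_count: int = 2
    fraction_under_nucleus: float = 0.8
    # probability of a record violating one inclusion rule, exercising the
    # classifier's exclusion bookkeeping (0 = all generated fibers valid)
    invalid_fraction: float = 0.0
    field_size_um: tuple[float, float] = (30.0, 24.0)
    nucleus_ellipse: tuple[tuple[float, float], tuple[float, float], float] = (
        (15.0, 12.0),
        (8.0, 6.0),
        0.0,
    )
    frame_interval_s: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_fibers <= 0:
            raise ValueError("n_fibers must be positive")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if not 0.0 <= self.fraction_under_nucleus <= 1.0:
            raise ValueError("fraction_under_nucleus must be in [0, 1]")
        if not 0.0 <= self.invalid_fraction <= 1.0:
            raise ValueError("invalid_fraction must be in [0, 1]")
        if self.length_um[0] <= 0:
            raise ValueError("median length must be positive")


def _nucleus_polygon(params: FiberSimParams):
    (cx, cy), (a, b), ang = params.nucleus_ellipse
    circ = Point(0.0, 0.0).buffer(1.0, quad_segs=64)
    ell = affinity.scale(circ, a, b)
    ell = affinity.rotate(ell, ang)
    return affinity.translate(ell, cx, cy)


def generate_fiber_table(params: FiberSimParams) -> pd.DataFrame:
    """Sample a fiber track table with ground-truth class labels.

    Each record carries endpoint coordinates, length, lifetime, per-adhesion
    nucleus flags, a segment/nucleus overlap flag, and the generative labels
    ``true_cortical`` / ``true_under_nucleus`` that the live-cell
    classification rules should recover.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    nuc = _nucleus_polygon(params)
    w, h = params.field_size_um
    (cx, cy), (a, b), ang = params.nucleus_ellipse

    cells = np.sort(rng.integers(0, params.n_cells, size=params.n_fibers))
    med_len, sig_len = params.length_um
    rows = []
    for fid in range(params.n_fibers):
        length = float(np.exp(rng.normal(np.log(med_len), sig_len)))
        length = min(length, 0.45 * min(w, h))
        lifetime = float(rng.exponential(params.lifetime_median_min / np.log(2.0)))
        under = bool(rng.random() < params.fraction_under_nucleus)
        n_adh = int(params.adhesion_count)
        if params.invalid_fraction > 0 and rng.random() < params.invalid_fraction:
            # break exactly one inclusion rule at random
            kind = rng.integers(0, 3)
            if kind == 0:
                length = float(10.5 + 5.0 * rng.random())
            elif kind == 1:
                lifetime = float(1.9 * rng.random())
            else:
                n_adh = 1

        for _ in range(1000):
            th = 2.0 * np.pi * rng.random()
            if under:
                # first adhesion uniform inside the nucleus footprint
                while True:
                    p = np.array([cx + (2 * rng.random() - 1) * a,
                                  cy + (2 * rng.random() - 1) * b])
                    if nuc.contains(Point(*p)):
                        break
            else:
                while True:
                    p = rng.random(2) * (w, h)
                    if not nuc.contains(Point(*p)):
                        break
            q = p + length * np.array([np.cos(th), np.sin(th)])
            if not (0 < q[0] < w and 0 < q[1] < h):
                continue
            if not under and nuc.contains(Point(*q)):
                continue
            break
        seg = LineString([p, q])
        adh1_under = bool(nuc.contains(Point(*p)))
        adh2_under = bool(n_adh >= 2 and nuc.contains(Point(*q)))
        overlap = bool(seg.intersects(nuc))
        cortical = (
            length <= 10.0 and lifetime >= 2.0 and n_adh >= 2
        )
        rows.append(
            dict(
                cell_id=int(cells[fid]),
                fiber_id=fid,
                x1_um=float(p[0]),
                y1_um=float(p[1]),
                x2_um=float(q[0]),
                y2_um=float(q[1]),
                length_um=length,
                lifetime_min=lifetime,
                n_adhesions=n_adh,
                adh1_under_nucleus=adh1_under,
                adh2_under_nucleus=adh2_under,
                nucleus_overlap=overlap,
                true_cortical=cortical,
                true_under_nucleus=bool(cortical and (adh1_under or adh2_under)),
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# photoactivated-focus movies (flow assay simulant)


def generate_focus_stack(
    speed_um_per_min: float,
    direction_deg: float = 0.0,
    n_frames: int = 30,
    frame_interval_s: float = 10.0,
    pixel_size_um: float = 0.08,
    field_um: float = 8.0,
    focus_sigma_um: float = 0.4,
    amplitude: float = 200.0,
    baseline: float = 20.0,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> tuple[ImageStack, np.ndarray]:
    """Render a photoactivated focus translating at a constant speed.

    Returns the stack and the ``(T, 2)`` ground-truth (x, y) µm positions.
    """
    rng = np.random.default_rng(seed)
    n_px = int(round(field_um / pixel_size_um))
    t_min = np.arange(n_frames) * frame_interval_s / 60.0
    th = math.radians(direction_deg)
    start = np.array([field_um / 2.0, field_um / 2.0])
    total = speed_um_per_min * t_min[-1] if n_frames > 1 else 0.0
    start -= 0.5 * total * np.array([math.cos(th), math.sin(th)])
    pos = start[None, :] + speed_um_per_min * t_min[:, None] * np.array(
        [math.cos(th), math.sin(th)]
    )
    xs = (np.arange(n_px) + 0.5) * pixel_size_um
    data = np.empty((n_frames, n_px, n_px))
    for t in range(n_frames):
        g = np.exp(
            -((xs[None, :] - pos[t, 0]) ** 2 + (xs[:, None] - pos[t, 1]) ** 2)
            / (2.0 * focus_sigma_um**2)
        )
        data[t] = baseline + amplitude * g
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=data.shape)
    return ImageStack(data, pixel_size_um, frame_interval_s), pos
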