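"""Ground-truth evaluation of the detector and cohort-level simulations.

These helpers close the loop between the synthetic generator and the
analysis stages: matching detected events to simulated pulses, measuring
sensitivity and false-event rates, and building per-cell pulse-frequency
cohorts either through the full image pipeline or directly at the
event-count level (for large replicate counts where rendering every movie
would add nothing).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .detection import assign_region, compute_hex_series, detect_pulses
from .hexgrid import build_hex_grid
from .stats import CellPulseSummary, summarize_cell
from .synthetic import PulseSimParams, generate_pulse_stack, sample_pulse_events

__all__ = [
    "match_events",
    "run_detection",
    "detection_performance",
    "simulate_cohort",
    "count_level_cohort",
]


def match_events(events, ground_truth, grid, max_dist_um: float = 2.5):
    """Coverage matching of detected events against true pulses.

    A true pulse is recovered when some event is active during its FWHM span
    with at least one active hexagon center within ``max_dist_um`` of the
    pulse center; one merged event may explain several adjacent pulses (two
    overlapping pulses link into a single component, as in manual kymograph
    scoring).  An event is *explained* if it recovers at least one pulse.
    Returns ``(matched_truth_flags, explained_event_flags)``.
    """
    t_matched = np.zeros(len(ground_truth), dtype=bool)
    e_matched = np.zeros(len(events), dtype=bool)
    for ei, ev in enumerate(events):
        for ti, tr in enumerate(ground_truth):
            frames = [
                f for f in ev.active_hexagons
                if tr.start_frame <= f <= tr.end_frame
            ]
            if not frames:
                continue
            cx, cy = tr.center_um
            for f in frames:
                idx = sorted(ev.active_hexagons[f])
                d = np.hypot(
                    grid.centers_um[idx, 0] - cx, grid.centers_um[idx, 1] - cy
                )
                if d.min() <= max_dist_um:
                    t_matched[ti] = True
                    e_matched[ei] = True
                    break
    return t_matched, e_matched


def run_detection(
    params: PulseSimParams,
    hex_radius_um: float = 1.0,
    threshold_ratio: float = 1.3,
    min_component_size: int = 3,
    min_duration_frames: int = 4,
    window_frames: int | None = None,
):
    """Simulate one movie and run the full detection chain on it.

    Returns ``(events, grid, sim)`` with events region-labeled.
    """
    sim = generate_pulse_stack(params)
    grid = build_hex_grid(sim.roi_mask, hex_radius_um)
    series = compute_hex_series(sim.stack, grid, window_frames=window_frames)
    events = detect_pulses(
        series,
        grid,
        threshold_ratio=threshold_ratio,
        min_component_size=min_component_size,
        min_duration_frames=min_duration_frames,
        window_frames=window_frames,
    )
    assign_region(events, sim.nucleus_mask, grid)
    return events, grid, sim


def detection_performance(
    params: PulseSimParams, max_dist_um: float = 2.5, **detect_kwargs
) -> dict:
    """Sensitivity and false-event count of the detector on one movie."""
    events, grid, sim = run_detection(params, **detect_kwargs)
    t_matched, e_matched = match_events(
        events, sim.ground_truth, grid, max_dist_um=max_dist_um
    )
    n_true = len(sim.ground_truth)
    return {
        "n_true": n_true,
        "n_detected": len(events),
        "n_matched": int(t_matched.sum()),
        "sensitivity": float(t_matched.mean()) if n_true else float("nan"),
        "false_events": int((~e_matched).sum()),
    }


def simulate_cohort(
    base_params: PulseSimParams, n_cells: int, seed: int, **detect_kwargs
) -> list[CellPulseSummary]:
    """Per-cell pulse summaries from full simulate-detect runs."""
    ss = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(ss.spawn(n_cells)):
        cell_seed = int(child.generate_state(1)[0] % (2**31))
        p = replace(base_params, seed=cell_seed)
        events, grid, sim = run_detection(p, **detect_kwargs)
        out.append(
            summarize_cell(
                events,
                sim.nucleus_mask,
                sim.roi_mask,
                window_min=p.duration_min,
                cell_id=f"cell{i:02d}",
            )
        )
    return out


def count_level_cohort(
    base_params: PulseSimParams, n_cells: int, seed: int
) -> list[CellPulseSummary]:
    """Per-cell summaries from ground-truth event counts (no rendering).

    Useful for large replicate studies of the statistics stage, where the
    quantity under test is the behavior of the per-cell counts, not the
    image-level detector.
    """
    from .synthetic import _roi_and_nucleus  # shared geometry

    roi, nuc = _roi_and_nucleus(base_params)
    area_nuc = nuc.area_um2
    area_out = roi.minus(nuc).area_um2
    ss = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(ss.spawn(n_cells)):
        p = replace(base_params, seed=int(child.generate_state(1)[0] % (2**31)))
        events = sample_pulse_events(p)
        n_under = sum(e.region_label == "under_nucleus" for e in events)
        n_out = len(events) - n_under
        out.append(
            CellPulseSummary(
                cell_id=f"cell{i:02d}",
                n_pulses_under=n_under,
                n_pulses_outside=n_out,
                area_nucleus_um2=area_nuc,
                area_outside_um2=area_out,
                window_min=p.duration_min,
            )
        )
    return out
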