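"""Deliberately naive re-implementations used as independent test oracles.

These mirror the *stated rules* of the pipeline operations with plain
Python loops and sets, sharing no code with the vectorized implementations
they check.
"""

from __future__ import annotations

import numpy as np


def brute_force_pulse_events(
    ratio: np.ndarray,
    adjacency,
    threshold_ratio: float,
    min_component_size: int,
    min_duration_frames: int,
    window_frames: int | None = None,
) -> list[dict[int, frozenset[int]]]:
    """Exhaustive frame-by-frame recomputation of the pulse-detection chain.

    Threshold -> per-frame connected components (hexagon adjacency) ->
    size filter -> consecutive-frame overlap linking with lowest-id merge ->
    duration and window filters.  Returns one ``{frame: hexagon set}`` dict
    per surviving event, sorted by start frame.
    """
    n_hex, n_frames = ratio.shape
    if window_frames is not None:
        window_frames = min(window_frames, n_frames)

    def components(active: set[int]) -> list[set[int]]:
        comps = []
        left = set(active)
        while left:
            start = min(left)
            comp = {start}
            frontier = [start]
            left.remove(start)
            while frontier:
                h = frontier.pop()
                for nb in adjacency[h]:
                    if nb in left:
                        left.remove(nb)
                        comp.add(nb)
                        frontier.append(nb)
            comps.append(comp)
        return sorted(comps, key=min)

    events: dict[int, dict[int, set[int]]] = {}
    prev_open: dict[int, set[int]] = {}
    next_id = 0
    for t in range(n_frames):
        active = {h for h in range(n_hex) if ratio[h, t] >= threshold_ratio}
        comps = [c for c in components(active) if len(c) >= min_component_size]
        now_open: dict[int, set[int]] = {}
        for comp in comps:
            hit = sorted(e for e, s in prev_open.items() if s & comp)
            if not hit:
                eid = next_id
                next_id += 1
                events[eid] = {}
            else:
                eid = hit[0]
                for other in hit[1:]:
                    for f, s in events.pop(other).items():
                        events[eid].setdefault(f, set()).update(s)
                    if other in prev_open:
                        prev_open[eid] = prev_open.get(eid, set()) | prev_open.pop(other)
                    if other in now_open:
                        now_open[eid] = now_open.get(eid, set()) | now_open.pop(other)
            events[eid].setdefault(t, set()).update(comp)
            now_open[eid] = now_open.get(eid, set()) | comp
        prev_open = now_open

    survivors = []
    for eid in sorted(events):
        frames = events[eid]
        if max(frames) - min(frames) + 1 < min_duration_frames:
            continue
        if window_frames is not None and min(frames) >= window_frames:
            continue
        survivors.append({f: frozenset(s) for f, s in sorted(frames.items())})
    survivors.sort(key=lambda d: min(d))
    return survivors


def mann_whitney_exact_p(a, b) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration of labelings."""
    from itertools import combinations

    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    na = len(a)

    def u_of(sample_a, sample_b):
        return sum(1 for x in sample_a for y in sample_b if x > y) + 0.5 * sum(
            1 for x in sample_a for y in sample_b if x == y
        )

    u_obs = u_of(a, b)
    mu = na * len(b) / 2.0
    count = 0
    total = 0
    idx = range(len(pooled))
    for pick in combinations(idx, na):
        sa = [pooled[i] for i in pick]
        sb = [pooled[i] for i in idx if i not in pick]
        if abs(u_of(sa, sb) - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


def paired_t_closed_form(x, y):
    """t = mean(d) / (sd(d)/sqrt(n)) with d = x - y, computed longhand."""
    d = [float(a) - float(b) for a, b in zip(x, y)]
    n = len(d)
    m = sum(d) / n
    var = sum((v - m) ** 2 for v in d) / (n - 1)
    return m / (var**0.5 / n**0.5), n - 1
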