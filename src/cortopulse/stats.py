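"""Region-conditioned pulse frequencies and the study's statistical tests.

Pulse counts are compared *within* each cell: the under-nucleus count is
reported raw, while the outside count is rescaled by (nucleus area / outside
area) so both numbers are pulses per nucleus-equivalent area per analysis
window.  Per-cell pairs are compared with a paired t-test (after a
quantile-quantile normality check of the differences); independent samples
(e.g. RMS tractions of two stress-fiber classes) with a Mann-Whitney U-test
including outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .detection import PulseEvent
from .types import RegionMask

__all__ = [
    "CellPulseSummary",
    "summarize_cell",
    "paired_t_test",
    "mann_whitney_u",
    "qq_normality_report",
]


@dataclass
class CellPulseSummary:
    """Per-cell pulse bookkeeping.

    ``freq_under`` is the raw under-nucleus pulse count per window;
    ``freq_outside_norm`` the outside count scaled by
    (nucleus area / outside area), i.e. pulses per nucleus-equivalent area.
    """

    cell_id: str
    n_pulses_under: int
    n_pulses_outside: int
    area_nucleus_um2: float
    area_outside_um2: float
    window_min: float

    @property
    def freq_under(self) -> float:
        return float(self.n_pulses_under)

    @property
    def freq_outside_norm(self) -> float:
        return self.n_pulses_outside * self.area_nucleus_um2 / self.area_outside_um2

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "cell_id", "n_pulses_under", "n_pulses_outside",
            "area_nucleus_um2", "area_outside_um2", "window_min",
        )}
        d["freq_under"] = self.freq_under
        d["freq_outside_norm"] = self.freq_outside_norm
        return d


def summarize_cell(
    events: list[PulseEvent],
    nucleus_mask: RegionMask,
    roi_mask: RegionMask,
    window_min: float,
    cell_id: str = "cell",
) -> CellPulseSummary:
    """Partition labeled events by region and apply the area normalization."""
    if not np.any(roi_mask.mask):
        raise ValueError("empty ROI mask")
    area_nuc = (roi_mask & nucleus_mask).area_um2
    area_out = roi_mask.minus(nucleus_mask).area_um2
    if area_nuc <= 0:
        raise ValueError("nucleus area is zero within the ROI")
    if area_out <= 0:
        raise ValueError("outside area is zero; cannot normalize")
    labels = [ev.region_label for ev in events]
    if any(lab is None for lab in labels):
        raise ValueError("events must be region-labeled (run assign_region)")
    return CellPulseSummary(
        cell_id=cell_id,
        n_pulses_under=sum(lab == "under_nucleus" for lab in labels),
        n_pulses_outside=sum(lab == "outside" for lab in labels),
        area_nucleus_um2=area_nuc,
        area_outside_um2=area_out,
        window_min=window_min,
    )


def paired_t_test(x, y) -> tuple[float, float, int]:
    """Two-sided paired t-test on per-cell value pairs.

    Returns ``(t, p, df)`` with ``df = n - 1``.  Raises on fewer than two
    pairs or when every difference is zero (degenerate variance).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D and the same length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("all paired differences identical; t-test degenerate")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return float(t), float(p), n - 1


def mann_whitney_u(a, b, include_outliers: bool = True) -> tuple[float, float]:
    """Two-sided Mann-Whitney U-test.

    Uses the exact null distribution when both samples have at most eight
    tie-free observations, otherwise the normal approximation with tie
    correction and continuity correction.  ``include_outliers`` is accepted
    for interface symmetry; no trimming is ever applied.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class QQReport:
    """Ordered sample values against standard-normal quantiles (Blom)."""

    theoretical: np.ndarray
    observed: np.ndarray
    slope: float
    intercept: float
    zero_variance: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"theoretical_quantile": self.theoretical, "observed": self.observed}
        )


def qq_normality_report(differences) -> QQReport:
    """Quantile-quantile pairing of a sample against the standard normal.

    For an approximately normal sample the least-squares slope estimates the
    sample standard deviation; a slope near 1 with standard-normal data is
    the sanity check used before the paired t-test.
    """
    d = np.sort(np.asarray(differences, dtype=float))
    n = len(d)
    if n < 3:
        raise ValueError("need at least three values")
    theo = sps.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    zero_var = bool(d.std() == 0)
    if zero_var:
        slope, intercept = 0.0, float(d[0])
    else:
        slope, intercept = np.polyfit(theo, d, 1)
    return QQReport(theo, d, float(slope), float(intercept), zero_var)
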