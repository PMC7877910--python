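"""Fiber classification rules, cohort summaries, flow and kymographs."""

import numpy as np
import pandas as pd
import pytest

from cortopulse.fibers import (
    ClassificationCriteria,
    build_kymograph,
    classify_fibers,
    fraction_under_nucleus,
    lifetime_stats,
    track_focus_speed,
)
from cortopulse.synthetic import FiberSimParams, generate_fiber_table, generate_focus_stack
from cortopulse.types import ImageStack


def record(length, lifetime, n_adh, a1, a2, overlap, cell=0):
    return dict(
        cell_id=cell, length_um=length, lifetime_min=lifetime, n_adhesions=n_adh,
        adh1_under_nucleus=a1, adh2_under_nucleus=a2, nucleus_overlap=overlap,
    )


# hand-labeled fixture covering every live-cell inclusion/exclusion rule
FIXTURE = pd.DataFrame([
    record(8.0, 5.0, 2, True, False, True),     # cortical, under
    record(8.0, 5.0, 1, False, False, True),    # one adhesion -> excluded
    record(12.0, 5.0, 2, False, False, False),  # too long
    record(8.0, 1.5, 2, False, False, False),   # too short-lived
    record(9.99, 2.0, 2, False, True, False),   # boundary pass, under
    record(10.0, 5.0, 2, False, False, False),  # length == max -> included
    record(11.0, 1.0, 1, False, False, False),  # fails all three rules
    record(5.0, 30.0, 2, True, True, True),     # cortical, under
    record(5.0, 3.0, 2, False, False, True),    # overlap but no FA inside
    record(5.0, 3.0, np.nan, False, False, True),  # missing adhesion data
    record(2.0, 2.0, 2, False, False, False),   # minimal cortical, outside
    record(8.0, 120.0, 2, True, False, True),   # long-lived cortical, under
])
EXPECT_CORTICAL = [True, False, False, False, True, True, False, True, True, False, True, True]
EXPECT_UNDER = [True, False, False, False, True, False, False, True, False, False, False, True]
EXPECT_UNCLASSIFIABLE = [False] * 9 + [True, False, False]


class TestClassifier:
    def test_hand_labeled_fixture_matches_exactly(self):
        out = classify_fibers(FIXTURE)
        assert list(out["is_cortical"]) == EXPECT_CORTICAL
        assert list(out["under_nucleus"]) == EXPECT_UNDER
        assert list(out["unclassifiable"]) == EXPECT_UNCLASSIFIABLE

    def test_exclusion_reasons_recorded(self):
        out = classify_fibers(FIXTURE)
        assert out["exclusion_reason"].iloc[2] == "too_long"
        assert out["exclusion_reason"].iloc[3] == "too_short_lived"
        assert set(out["exclusion_reason"].iloc[6].split(";")) == {
            "too_long", "too_short_lived", "missing_end_adhesion",
        }
        assert out["exclusion_reason"].iloc[9] == "missing_adhesion_data"
        assert (out.loc[out["is_cortical"], "exclusion_reason"] == "").all()

    def test_agrees_with_rule_by_rule_recheck_on_generated_table(self):
        t = generate_fiber_table(FiberSimParams(n_fibers=150, invalid_fraction=0.3, seed=4))
        out = classify_fibers(t)
        for _, row in out.iterrows():
            want = (
                row.length_um <= 10.0
                and row.lifetime_min >= 2.0
                and row.n_adhesions >= 2
            )
            assert row.is_cortical == want
            assert row.under_nucleus == (
                want and (row.adh1_under_nucleus or row.adh2_under_nucleus)
            )
        # generator labels match the classifier label for label
        assert (out["is_cortical"] == out["true_cortical"]).all()
        assert (out["under_nucleus"] == out["true_under_nucleus"]).all()

    def test_fixed_mode_rules(self):
        crit = ClassificationCriteria(mode="fixed", nucleus_diameter_um=18.0)
        t = pd.DataFrame([
            record(17.0, 0.5, 2, False, False, True),   # short enough + overlap
            record(18.0, 50.0, 2, False, False, True),  # length >= diameter
            record(5.0, 50.0, 2, False, False, False),  # no overlap
            record(5.0, 50.0, 1, False, False, True),   # one adhesion
        ])
        out = classify_fibers(t, crit)
        assert list(out["is_cortical"]) == [True, False, False, False]
        assert list(out["under_nucleus"]) == [True, False, False, False]
        with pytest.raises(ValueError, match="nucleus_diameter"):
            ClassificationCriteria(mode="fixed")


class TestFraction:
    def make(self, per_cell_counts):
        rows = []
        for cell, (under, total) in enumerate(per_cell_counts):
            for k in range(total):
                rows.append(record(5.0, 10.0, 2, k < under, False, True, cell=cell))
        return classify_fibers(pd.DataFrame(rows))

    def test_all_under_is_100_percent_sem_zero(self):
        out = self.make([(5, 5), (4, 4), (3, 3)])
        pct, sem, n = fraction_under_nucleus(out)
        assert pct == 100.0 and sem == 0.0 and n == 3

    def test_four_of_five_everywhere_is_80_percent(self):
        out = self.make([(4, 5)] * 6)
        pct, sem, n = fraction_under_nucleus(out)
        assert pct == pytest.approx(80.0)
        assert sem == pytest.approx(0.0)

    def test_recovers_generator_fraction_within_3_sigma(self):
        t = generate_fiber_table(
            FiberSimParams(n_fibers=101, n_cells=19, fraction_under_nucleus=0.8, seed=1)
        )
        out = classify_fibers(t)
        pct, sem, n = fraction_under_nucleus(out)
        n_cort = int(out["is_cortical"].sum())
        assert n == 19
        assert abs(pct - 80.0) < 300.0 * np.sqrt(0.8 * 0.2 / n_cort)

    def test_invariant_to_order_and_cell_duplication(self):
        out = self.make([(4, 5), (1, 4), (3, 3)])
        shuffled = out.sample(frac=1.0, random_state=0)
        assert fraction_under_nucleus(out) == fraction_under_nucleus(shuffled)
        dup = pd.concat([out, out[out.cell_id == 1]], ignore_index=True)
        dup.loc[len(out):, "cell_id"] = 1  # duplicate one whole cell
        # duplicating a cell's records does not change its percentage
        pct, _, _ = fraction_under_nucleus(dup)
        pct0, _, _ = fraction_under_nucleus(out)
        assert pct == pytest.approx(pct0)

    def test_pooled_mode_and_errors(self):
        out = self.make([(4, 5), (0, 5)])
        pct, sem, n = fraction_under_nucleus(out, per_cell=False)
        assert pct == pytest.approx(40.0)
        assert n == 10
        empty = classify_fibers(pd.DataFrame([record(20.0, 1.0, 1, 0, 0, 0)]))
        with pytest.raises(ValueError, match="no cortical"):
            fraction_under_nucleus(empty)


class TestLifetimes:
    def test_median_and_spread(self):
        t = classify_fibers(pd.DataFrame(
            [record(5.0, lt, 2, True, False, True) for lt in (10.0, 25.0, 60.0)]
        ))
        s = lifetime_stats(t)
        assert s["median_min"] == 25.0
        assert s["range_min"] == (10.0, 60.0)

    def test_single_fiber(self):
        t = classify_fibers(pd.DataFrame([record(5.0, 33.0, 2, True, False, True)]))
        assert lifetime_stats(t)["median_min"] == 33.0

    def test_exponential_median_identity(self):
        rng = np.random.default_rng(5)
        lts = rng.exponential(30.0, size=200)
        t = classify_fibers(pd.DataFrame(
            [record(5.0, max(lt, 2.0), 2, True, False, True) for lt in lts]
        ))
        s = lifetime_stats(t)
        assert abs(s["median_min"] - 30.0 * np.log(2)) / (30.0 * np.log(2)) < 0.15

    def test_censoring(self):
        t = pd.DataFrame([record(5.0, lt, 2, True, False, True) for lt in (10.0, 25.0, 60.0)])
        t["censored"] = [False, False, True]
        s = lifetime_stats(classify_fibers(t))
        assert s["median_min"] == 17.5
        assert s["n_censored"] == 1
        t["censored"] = True
        with pytest.raises(ValueError, match="censored|uncensored"):
            lifetime_stats(classify_fibers(t))


class TestFocusSpeed:
    def test_static_focus_speed_near_zero(self):
        st, _ = generate_focus_stack(0.0, seed=8)
        assert track_focus_speed(st) < 0.01

    def test_translating_focus_recovered_within_5_percent(self):
        st, _ = generate_focus_stack(0.3, direction_deg=25.0, seed=9)
        v = track_focus_speed(st)
        assert abs(v - 0.3) / 0.3 < 0.05

    def test_contrast_floor_and_empty_roi_errors(self):
        flat = ImageStack(np.full((5, 20, 20), 50.0), 0.1, 10.0)
        with pytest.raises(ValueError, match="contrast"):
            track_focus_speed(flat)
        st, _ = generate_focus_stack(0.3, seed=0)
        with pytest.raises(ValueError, match="ROI"):
            track_focus_speed(st, (slice(0, 0), slice(0, 0)))


class TestKymograph:
    def moving_spot_stack(self, speed_um_s=0.05, n=80, T=20, px=0.1, dt=2.0, y0=4.0):
        xs = (np.arange(n) + 0.5) * px
        data = np.zeros((T, n, n))
        for t in range(T):
            cx = 1.0 + speed_um_s * t * dt
            data[t] = np.exp(
                -((xs[None, :] - cx) ** 2 + (xs[:, None] - y0) ** 2) / (2 * 0.09)
            )
        return ImageStack(data, px, dt)

    def test_static_scene_all_columns_identical(self):
        st = self.moving_spot_stack(speed_um_s=0.0)
        kymo, _ = build_kymograph(st, [(0.5, 4.0), (7.5, 4.0)], line_width_px=3)
        assert np.allclose(kymo, kymo[:, :1])
        assert np.linalg.matrix_rank(kymo, tol=1e-9) == 1

    def test_streak_slope_equals_speed(self):
        st = self.moving_spot_stack()
        kymo, s = build_kymograph(st, [(0.2, 4.0), (7.8, 4.0)], line_width_px=3)
        peaks = s[np.argmax(kymo, axis=0)]
        slope = np.polyfit(np.arange(st.n_frames) * st.frame_interval_s, peaks, 1)[0]
        assert slope == pytest.approx(0.05, rel=0.05)

    def test_width_one_is_direct_line_sampling(self):
        st = self.moving_spot_stack()
        # horizontal line exactly on a pixel-center row
        row = 35
        y = (row + 0.5) * st.pixel_size_um
        kymo, s = build_kymograph(st, [(0.05, y), (7.95, y)], line_width_px=1)
        cols = np.round((np.interp(s, [0, s[-1]], [0.05, 7.95])) / st.pixel_size_um - 0.5).astype(int)
        direct = st.data[:, row, :][:, cols].T
        assert np.allclose(kymo, direct, atol=1e-6)

    def test_polyline_outside_bounds_raises(self):
        st = self.moving_spot_stack()
        with pytest.raises(ValueError, match="outside"):
            build_kymograph(st, [(0.0, 4.0), (99.0, 4.0)])
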