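"""Bout segmentation and daily walking outcomes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arcgait import (
    Bout,
    SegmentationParams,
    build_day_table,
    day_outcomes,
    estimate_alpha,
    segment_bouts,
)
from arcgait.macrogait import steps_from_bouts

META = {
    "participant_id": "p1",
    "care_level": "high",
    "facility_id": "F01",
    "calendar_day": 1,
    "day_of_week": "Sat",
}


def brute_force_segment(times, max_rest=2.5, min_steps=3):
    """Reference segmentation: a plain scan over the gap sequence."""
    bouts, current = [], []
    for t in times:
        if current and t - current[-1] > max_rest:
            if len(current) >= min_steps:
                bouts.append(Bout(current[0], current[-1] - current[0], len(current)))
            current = []
        current.append(t)
    if len(current) >= min_steps:
        bouts.append(Bout(current[0], current[-1] - current[0], len(current)))
    return bouts


@pytest.mark.parametrize(
    "times, expected",
    [
        # a 3.0 s rest exceeds the 2.5 s threshold and splits the sequence
        ([0, 0.5, 1.0, 4.0, 4.5, 5.0, 5.5], [(0.0, 1.0, 3), (4.0, 1.5, 4)]),
        # isolated steps never reach the 3-step minimum
        ([0, 10, 20], []),
        ([], []),
        # a rest of exactly 2.5 s does not split (strictly-greater rule)
        ([0, 2.5, 5.0], [(0.0, 5.0, 3)]),
        ([0, 1, 2, 3.5], [(0.0, 3.5, 4)]),
    ],
)
def test_segmentation_examples(times, expected):
    got = [(b.start_s, b.duration_s, b.n_steps) for b in segment_bouts(np.array(times, dtype=float))]
    assert got == expected


def test_segmentation_rejects_unsorted_input():
    with pytest.raises(ValueError, match="strictly increasing"):
        segment_bouts(np.array([3.0, 1.0, 2.0]))


def test_segmentation_matches_brute_force_on_random_days():
    rng = np.random.default_rng(17)
    for _ in range(200):
        times = np.sort(rng.uniform(0, 3600, size=rng.integers(0, 1000)))
        times = np.unique(times)
        got = segment_bouts(times)
        ref = brute_force_segment(times)
        assert got == ref
        assert sum(b.n_steps for b in got) <= times.size


def test_outcomes_invariant_to_constant_time_shift():
    rng = np.random.default_rng(5)
    times = np.sort(rng.uniform(0, 2000, 400))
    a = day_outcomes(segment_bouts(times), META)
    b = day_outcomes(segment_bouts(times + 1234.5), META)
    for f in ("total_walk_time_s", "total_steps", "total_bouts", "mean_bout_length_s"):
        assert getattr(a, f) == pytest.approx(getattr(b, f))


def test_resegmenting_reconstructed_steps_is_idempotent(small_cohort):
    days, _, _ = small_cohort
    for day in days[:20]:
        bouts = segment_bouts(day)
        again = segment_bouts(steps_from_bouts(bouts))
        assert [(b.duration_s, b.n_steps) for b in again] == pytest.approx(
            [(b.duration_s, b.n_steps) for b in bouts]
        )


def test_day_outcome_arithmetic():
    bouts = [Bout(0.0, 1.0, 3), Bout(4.0, 1.5, 4)]
    out = day_outcomes(bouts, META)
    assert out.total_walk_time_s == pytest.approx(2.5)
    assert out.total_steps == 7
    assert out.total_bouts == 2
    assert out.mean_bout_length_s == pytest.approx(1.25)
    assert out.is_weekend  # Saturday
    assert math.isnan(out.alpha)  # below the 5-bout minimum
    assert out.variability_s == pytest.approx(np.std([1.0, 1.5], ddof=1))


def test_zero_bouts_yield_zero_volume_and_missing_pattern():
    out = day_outcomes([], META)
    assert (out.total_walk_time_s, out.total_steps, out.total_bouts) == (0.0, 0, 0)
    assert math.isnan(out.mean_bout_length_s)
    assert math.isnan(out.alpha)
    assert math.isnan(out.variability_s)


def test_variability_equals_independent_sample_sd():
    rng = np.random.default_rng(2)
    durs = rng.uniform(1, 30, 50)
    bouts = [Bout(float(i * 100), float(d), 5) for i, d in enumerate(durs)]
    out = day_outcomes(bouts, META)
    mean = durs.sum() / 50
    sd = math.sqrt(((durs - mean) ** 2).sum() / 49)
    assert out.variability_s == pytest.approx(sd, rel=1e-12)


class TestAlpha:
    def test_closed_form_at_e_times_xmin(self):
        # every duration e*x_min: sum of logs = n, so alpha = 1 + n/n = 2
        assert estimate_alpha([math.e * 1.5] * 10, x_min=1.5) == pytest.approx(2.0)

    def test_recovers_pareto_exponent(self):
        rng = np.random.default_rng(8)
        d = 1.5 * (1.0 + rng.pareto(1.5, size=10_000))  # exponent 2.5
        assert estimate_alpha(d, x_min=1.5) == pytest.approx(2.5, abs=0.05)

    def test_degenerate_distribution_returns_missing(self):
        assert math.isnan(estimate_alpha([1.5] * 10, x_min=1.5))

    def test_too_few_bouts_returns_missing(self):
        assert math.isnan(estimate_alpha([2.0, 3.0], x_min=1.5))

    def test_duration_below_xmin_errors(self):
        with pytest.raises(ValueError, match="below x_min"):
            estimate_alpha([0.5, 2.0, 3.0, 4.0, 5.0], x_min=1.0)

    @given(
        scale=st.floats(0.01, 100.0),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        d = 1.0 + rng.pareto(1.2, size=50)
        a1 = estimate_alpha(d, x_min=1.0)
        a2 = estimate_alpha(d * scale, x_min=scale)
        assert a1 == pytest.approx(a2, rel=1e-9)


class TestBuildDayTable:
    def test_short_recordings_are_excluded_and_logged(self, small_cohort):
        days, wear, _ = small_cohort
        result = build_day_table(days, min_full_days=3)
        recorded = {e.participant_id: e.days_recorded for e in wear}
        for pid, n in result.excluded.items():
            assert recorded[pid] < 3 and n == recorded[pid]
        included = set(result.table["participant_id"])
        assert all(recorded[p] >= 3 for p in included)
        assert not included & set(result.excluded)

    def test_row_count_conserves_included_days(self, small_cohort):
        days, wear, _ = small_cohort
        result = build_day_table(days, min_full_days=3)
        expected = sum(
            e.days_recorded for e in wear if e.days_recorded >= 3
        )
        assert len(result.table) == expected

    def test_outcomes_match_generator_truth_exactly(self, small_cohort):
        days, _, truth = small_cohort
        result = build_day_table(days, min_full_days=1)
        tmap = {
            (p["participant_id"], d["calendar_day"]): d
            for p in truth["participants"]
            for d in p["days"]
        }
        for row in result.table.itertuples():
            t = tmap[(row.participant_id, row.calendar_day)]
            assert row.total_walk_time_s == pytest.approx(t["total_walk_time_s"], abs=1e-8)
            assert row.total_steps == t["total_steps"]
            assert row.total_bouts == t["total_bouts"]
            assert row.mean_bout_length_s == pytest.approx(t["mean_bout_length_s"])
            if t["variability_s"] is not None:
                assert row.variability_s == pytest.approx(t["variability_s"])
            if t["alpha"] is not None:
                assert row.alpha == pytest.approx(t["alpha"])

    def test_rows_are_ordered_monday_first(self, small_cohort):
        days, _, _ = small_cohort
        table = build_day_table(days).table
        order = {d: i for i, d in enumerate(("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"))}
        for _, grp in table.groupby("participant_id"):
            idx = grp["day_of_week"].map(order).to_numpy()
            assert (np.diff(idx) >= 0).all()
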