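"""Statistics pipeline: standardization, signed-rank test vs brute-force
and scipy oracles, Bonferroni families, normality screen, learning effect
and restoration metric."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from spvsim import behavior, design, stats
from spvsim.stats import (
    DegenerateDataError,
    NoInformationError,
    restoration_percentage,
    wilcoxon_signed_rank,
)


@pytest.fixture(scope="module")
def trials():
    sched = design.build_study_schedule(20, seed=8)
    return behavior.sample_trials(sched, seed=21)


@pytest.fixture(scope="module")
def z(trials):
    return stats.standardize_within_participant(trials)


class TestStandardization:
    def test_per_participant_mean_zero_sd_one(self, z):
        for ep in stats.ENDPOINTS:
            g = z.groupby("participant_id")[f"z_{ep}"].agg(["mean", "std"])
            assert g["mean"].abs().max() < 1e-9
            assert (g["std"] - 1).abs().max() < 1e-9

    def test_zero_spread_raises_named_error(self, trials):
        flat = trials.copy()
        flat.loc[flat["participant_id"] == "P01", "rating"] = 5
        with pytest.raises(DegenerateDataError, match="P01.*rating"):
            stats.standardize_within_participant(flat)

    def test_affine_invariance(self, trials):
        scaled = trials.copy()
        scaled["duration_s"] = 3.0 * scaled["duration_s"] + 11.0
        za = stats.standardize_within_participant(trials, endpoints=("duration_s",))
        zb = stats.standardize_within_participant(scaled, endpoints=("duration_s",))
        assert np.allclose(za["z_duration_s"], zb["z_duration_s"])


def _brute_force_wilcoxon(diffs):
    """Two-sided p by explicit enumeration of all sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ge = le = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        ge += w >= w_obs - 1e-9
        le += w <= w_obs + 1e-9
    total = 2**n
    return min(1.0, 2 * min(ge / total, le / total))


class TestWilcoxon:
    def test_five_concordant_pairs_give_exact_p(self):
        w, p = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0])
        assert w == 15.0
        assert p == pytest.approx(2 / 32)

    def test_pair_swap_reflects_statistic_keeps_p(self, rng):
        d = rng.normal(size=12)
        w1, p1 = wilcoxon_signed_rank(d)
        w2, p2 = wilcoxon_signed_rank(-d)
        m = np.count_nonzero(d)
        assert w1 + w2 == pytest.approx(m * (m + 1) / 2)
        assert p1 == pytest.approx(p2)

    @pytest.mark.parametrize("n", [5, 8, 10, 12])
    def test_exact_path_equals_brute_force_enumeration(self, n, rng):
        for _ in range(25):
            d = np.round(rng.normal(size=n), 1)  # rounding provokes ties
            if not np.any(d):
                continue
            _, p = wilcoxon_signed_rank(d)
            assert p == pytest.approx(_brute_force_wilcoxon(d), abs=1e-12)

    def test_matches_scipy_exact_on_tie_free_data(self, rng):
        for _ in range(20):
            d = rng.normal(size=11)
            _, p = wilcoxon_signed_rank(d)
            p_sp = sps.wilcoxon(d, method="exact", alternative="two-sided").pvalue
            assert p == pytest.approx(p_sp, abs=1e-12)

    def test_approximate_path_close_to_scipy(self, rng):
        d = rng.normal(size=40)
        _, p = wilcoxon_signed_rank(d, mode="approx")
        p_sp = sps.wilcoxon(d, correction=True, method="approx").pvalue
        assert p == pytest.approx(p_sp, rel=1e-6)

    def test_all_zero_differences_raise(self):
        with pytest.raises(NoInformationError):
            wilcoxon_signed_rank([0.0, 0.0, 0.0])


class TestPlannedComparisons:
    def test_complexity_family_threshold_displayed_as_0_0083(self, z):
        report = stats.run_planned_comparisons(z, stats.complexity_family("duration_s"))
        assert report.displayed_thresholds == {6: 0.0083}
        assert all(r.adjusted_alpha == pytest.approx(0.05 / 6) for r in report.results)

    def test_method_family_threshold_displayed_as_0_0125(self, z):
        report = stats.run_planned_comparisons(z, stats.method_family("collisions"))
        assert report.displayed_thresholds == {4: 0.0125}
        assert len(report.results) == 4

    def test_significance_flag_equals_threshold_comparison(self, z):
        report = stats.run_planned_comparisons(z, stats.complexity_family("duration_s"))
        for r in report.results:
            assert r.significant == (r.p_value < r.adjusted_alpha)

    def test_identical_conditions_surface_no_information_error(self, z):
        comp = stats.PlannedComparison(
            endpoint="duration_s",
            label="self vs self",
            condition_a={"vision": "ced_spv", "resolution": 26, "complexity": "plain"},
            condition_b={"vision": "ced_spv", "resolution": 26, "complexity": "plain"},
            family_size=1,
        )
        report = stats.run_planned_comparisons(z, [comp])
        assert report.results[0].error is not None
        assert report.results[0].p_value is None

    def test_bonferroni_monotone_in_family_size(self, z):
        fam = stats.complexity_family("duration_s")
        small = stats.run_planned_comparisons(z, fam[:1])
        # same comparison embedded in the full family
        full = stats.run_planned_comparisons(z, fam)
        r_small, r_full = small.results[0], full.results[0]
        assert r_small.p_value == r_full.p_value
        assert not (r_full.significant and not r_small.significant)


class TestShapiroScreen:
    def test_null_calibration_rejection_rate_near_alpha(self):
        """On standard-normal samples the screen rejects ~5% of the time."""
        rng = np.random.default_rng(99)
        rejections = sum(
            sps.shapiro(rng.normal(size=50)).pvalue < 0.05 for _ in range(1000)
        )
        assert 25 <= rejections <= 80  # ~3 sigma binomial band around 50

    def test_skewed_data_rejected_often(self):
        rng = np.random.default_rng(7)
        rejections = sum(
            sps.shapiro(np.exp(rng.normal(size=50))).pvalue < 0.05 for _ in range(200)
        )
        assert rejections > 100

    def test_screen_reports_all_endpoints(self, z):
        out = stats.shapiro_wilk_screen(z)
        assert set(out) == set(stats.ENDPOINTS)
        for w, p in out.values():
            assert 0 <= w <= 1
            assert 0 <= p <= 1

    def test_constant_sample_rejected(self, trials):
        flat = trials.copy()
        flat["z_duration_s"] = 0.0
        flat["z_collisions"] = 0.0
        flat["z_rating"] = 0.0
        with pytest.raises(ValueError):
            stats.shapiro_wilk_screen(flat)


class TestLearningEffect:
    def test_monotone_decreasing_durations_give_negative_r(self):
        slots = design.build_trial_schedule("P01", seed=0)
        df = design.schedule_to_frame(slots)
        df["duration_s"] = 100.0 - np.arange(len(df)) + np.linspace(0, 0.1, len(df)) ** 2
        df["collisions"] = 0
        df["rating"] = 5
        r, p, _ = stats.learning_effect(df)
        assert r < -0.9

    def test_shuffling_destroys_correlation(self, trials, rng):
        rs = []
        for _ in range(100):
            shuffled = trials.copy()
            shuffled["duration_s"] = rng.permutation(shuffled["duration_s"].to_numpy())
            r, _, _ = stats.learning_effect(shuffled)
            rs.append(abs(r))
        assert np.mean(rs) < 0.05

    def test_injected_session_shift_recovered(self):
        sched = design.build_study_schedule(5, seed=3)
        params = behavior.BehavioralModelParams(
            participant_sd=(0.0, 0.0, 0.0),
            residual_sd=(0.0, 0.0),
            session2_duration_shift_s=-3.468,
        )
        data = behavior.sample_trials(sched, params, seed=0)
        _, _, shift = stats.learning_effect(data)
        assert shift == pytest.approx(3.468)


class TestRestoration:
    @pytest.mark.parametrize("direction", ["lower_is_better", "higher_is_better"])
    def test_anchors_and_midpoint(self, direction):
        floor, ceiling = (50.0, 10.0) if direction == "lower_is_better" else (2.0, 9.0)
        assert restoration_percentage(ceiling, floor, ceiling, direction) == pytest.approx(100.0)
        assert restoration_percentage(floor, floor, ceiling, direction) == pytest.approx(0.0)
        mid = (floor + ceiling) / 2
        assert restoration_percentage(mid, floor, ceiling, direction) == pytest.approx(50.0)

    def test_values_outside_band_not_clamped(self):
        assert restoration_percentage(5.0, 50.0, 10.0, "lower_is_better") > 100.0

    def test_equal_anchors_rejected(self):
        with pytest.raises(ValueError):
            restoration_percentage(1.0, 5.0, 5.0, "lower_is_better")

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        floor=st.floats(-100, 100),
        ceiling=st.floats(-100, 100),
        frac=st.floats(0, 1),
    )
    def test_linearity_between_anchors(self, floor, ceiling, frac):
        """Restoration interpolates linearly: a point a fraction f of the
        way from floor to ceiling restores 100*f percent."""
        if abs(floor - ceiling) < 1e-6:
            return
        x = floor + frac * (ceiling - floor)
        direction = "lower_is_better" if ceiling < floor else "higher_is_better"
        got = restoration_percentage(x, floor, ceiling, direction)
        assert got == pytest.approx(100 * frac, abs=1e-6)


class TestSpeedAccuracy:
    def test_reports_slope_sign_per_condition(self, trials):
        out = stats.speed_accuracy_slopes(trials)
        assert not out.empty
        assert set(out["sign"]).issubset({-1, 0, 1})
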