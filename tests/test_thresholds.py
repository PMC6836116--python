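import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import ndtr

from latmask import (
    BootstrapSummary,
    PopulationParams,
    ProbitGLMM,
    SessionDesign,
    ValidationError,
    baseline_spec,
    bootstrap_threshold_sd,
    compare_group_thresholds,
    group_thresholds,
    simulate_dataset,
    threshold_75,
)


def _bisect_ndtr_inverse(p, lo=-10.0, hi=10.0, tol=1e-12):
    """Independent inverse of the standard normal CDF by bisection."""
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if ndtr(mid) < p:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestThreshold75:
    def test_median_criterion_at_zero_intercept(self):
        assert threshold_75(0.0, 1.0, criterion=0.5) == pytest.approx(0.0, abs=1e-12)

    def test_unit_slope_against_bisection_oracle(self):
        oracle = _bisect_ndtr_inverse(0.75)
        assert threshold_75(0.0, 1.0) == pytest.approx(oracle, abs=1e-6)
        assert round(threshold_75(0.0, 1.0), 6) == round(oracle, 6)

    def test_study_scale_example(self):
        assert threshold_75(-0.5, 29.0) == pytest.approx((0.67449 + 0.5) / 29.0, rel=1e-4)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValidationError, match="undefined"):
            threshold_75(0.0, 0.0)

    def test_negative_slope_warns_but_returns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            t = threshold_75(1.0, -2.0)
        assert np.isfinite(t)

    def test_criterion_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            threshold_75(0.0, 1.0, criterion=1.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        intercept=st.floats(-3.0, 3.0),
        slope=st.floats(1.0, 60.0),
        criterion=st.floats(0.05, 0.95),
    )
    def test_inverse_of_probit_prediction(self, intercept, slope, criterion):
        t = threshold_75(intercept, slope, criterion)
        assert ndtr(intercept + slope * t) == pytest.approx(criterion, abs=1e-10)


def _toy_summary(draws_control, draws_migraine):
    draws = {
        "control": np.asarray(draws_control, dtype=float),
        "migraine_aura": np.asarray(draws_migraine, dtype=float),
    }
    return BootstrapSummary(
        n_samples=len(draws["control"]),
        thresholds=draws,
        sd={g: float(np.std(v, ddof=1)) for g, v in draws.items()},
        point={g: float(np.mean(v)) for g, v in draws.items()},
        n_dropped=0,
        criterion=0.75,
        seed=0,
        covariance_mode="random_effects",
    )


class TestCompareGroups:
    def test_fully_separated_draws_hit_continuity_floor(self):
        s = _toy_summary(np.linspace(0.05, 0.06, 40), np.linspace(0.01, 0.02, 40))
        assert compare_group_thresholds(s) == pytest.approx(2.0 / 41.0)

    def test_label_swap_leaves_p_unchanged(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0.04, 0.002, 60), rng.normal(0.038, 0.002, 60)
        assert compare_group_thresholds(_toy_summary(a, b)) == compare_group_thresholds(
            _toy_summary(b, a)
        )

    def test_single_group_summary_rejected(self):
        s = _toy_summary([1, 2, 3], [1, 2, 3])
        del s.thresholds["control"]
        with pytest.raises(ValidationError):
            compare_group_thresholds(s)

    def test_p_never_exceeds_one(self):
        s = _toy_summary([1.0, 2.0, 1.5, 1.7], [1.1, 1.9, 1.4, 1.8])
        assert 0 < compare_group_thresholds(s) <= 1


class TestBootstrap:
    @pytest.fixture(scope="class")
    @staticmethod
    def zero_sigma_fit(zero_sigma_table):
        model = ProbitGLMM.from_trials(zero_sigma_table, baseline_spec())
        return model.fit(fix_sigma=np.zeros((2, 2)))

    def test_identical_seeds_identical_summaries(self, zero_sigma_fit, baseline_design):
        kwargs = dict(
            group_sizes=(10, 10),
            design=baseline_design,
            n_samples=5,
            refit_sigma="zero",
        )
        a = bootstrap_threshold_sd(zero_sigma_fit, seed=5, **kwargs)
        b = bootstrap_threshold_sd(zero_sigma_fit, seed=5, **kwargs)
        for g in a.thresholds:
            assert np.array_equal(a.thresholds[g], b.thresholds[g])
        assert a.sd == b.sd

    def test_sd_shrinks_with_group_size(self, zero_sigma_fit, baseline_design):
        small = bootstrap_threshold_sd(
            zero_sigma_fit, (10, 10), baseline_design, n_samples=50,
            seed=1, refit_sigma="zero",
        )
        large = bootstrap_threshold_sd(
            zero_sigma_fit, (40, 40), baseline_design, n_samples=50,
            seed=1, refit_sigma="zero",
        )
        for g in small.sd:
            assert large.sd[g] < small.sd[g]

    def test_sd_concentrates_with_trial_count(self, zero_sigma_fit):
        few = SessionDesign(reps_per_level=20, flanker_distances=())
        many = SessionDesign(reps_per_level=10_000, flanker_distances=())
        loose = bootstrap_threshold_sd(
            zero_sigma_fit, (10, 10), few, n_samples=30, seed=2, refit_sigma="zero"
        )
        tight = bootstrap_threshold_sd(
            zero_sigma_fit, (10, 10), many, n_samples=30, seed=2, refit_sigma="zero"
        )
        for g in loose.sd:
            assert tight.sd[g] < 0.1 * loose.sd[g]

    def test_covariance_modes_both_run(self, zero_sigma_table, baseline_design):
        fit = ProbitGLMM.from_trials(zero_sigma_table, baseline_spec()).fit(
            fix_sigma=np.zeros((2, 2))
        )
        s = bootstrap_threshold_sd(
            fit, (10, 10), baseline_design, n_samples=5, seed=3,
            covariance_mode="fixed_effects", refit_sigma="zero",
        )
        assert set(s.thresholds) == {"control", "migraine_aura"}
        with pytest.raises(ValidationError):
            bootstrap_threshold_sd(
                fit, (10, 10), baseline_design, n_samples=2, seed=3,
                covariance_mode="bogus",
            )

    def test_pipeline_recovers_generating_thresholds(self, baseline_design):
        """simulate -> fit -> threshold recovers the generating thresholds.

        The mean recovered threshold over 20 replicate experiments must lie
        within 2 bootstrap SDs of the generating value for each group.
        """
        pop = PopulationParams(
            beta=(-0.5, 29.0, -0.4, 12.0),
            sigma_re=((0.04, 0.0), (0.0, 16.0)),
            group_sizes=(31, 24),
        )
        true = {
            "control": threshold_75(-0.5, 29.0),
            "migraine_aura": threshold_75(-0.9, 41.0),
        }
        fits = [
            ProbitGLMM.from_trials(
                simulate_dataset(pop, baseline_design, seed=700 + i), baseline_spec()
            ).fit(compute_cov=False)
            for i in range(20)
        ]
        summary = bootstrap_threshold_sd(
            fits[0], (31, 24), baseline_design, n_samples=30, seed=7,
            n_quad=1,
        )
        recovered = {g: [] for g in true}
        for fit in fits:
            for g, t in group_thresholds(fit).items():
                recovered[g].append(t)
        for g in true:
            assert abs(np.mean(recovered[g]) - true[g]) < 2 * summary.sd[g]
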