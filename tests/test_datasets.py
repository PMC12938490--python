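"""Synthetic generators: contracts, parameter recovery, reproducibility."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from embaudit.datasets import (
    BehaviorVector,
    PromptSet,
    StudyDataset,
    generate_autocorrelated_series,
    generate_condition_study,
    generate_feedback_prompts,
    generate_horizon_choices,
    generate_linear_target,
    generate_number_prompts,
    replicate_prompt_set,
    vshape_transform,
)
from embaudit.errors import ParameterError, TemplateError, UsageError


class TestPromptSet:
    def test_field_length_mismatch_rejected(self):
        with pytest.raises(UsageError):
            PromptSet(prompts=["a", "b"], concept=np.array([1.0]))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(UsageError):
            PromptSet(prompts=["a", "b"], ids=["x", "x"])

    def test_non_finite_concept_rejected(self):
        with pytest.raises(UsageError):
            PromptSet(prompts=["a"], concept=np.array([np.nan]))


class TestNumberPrompts:
    @pytest.mark.parametrize(
        "n_min,n_max,step,template,n_expected,first,last",
        [
            (0, 100, 10, "This is number {}", 11, "This is number 0", "This is number 100"),
            (5, 5, 1, "This is number {}", 1, "This is number 5", "This is number 5"),
            (1, 10, 1, "This is trial {}", 10, "This is trial 1", "This is trial 10"),
        ],
    )
    def test_grid(self, n_min, n_max, step, template, n_expected, first, last):
        ps = generate_number_prompts(n_min, n_max, step, template)
        assert len(ps) == n_expected
        assert ps.prompts[0] == first
        assert ps.prompts[-1] == last
        assert ps.concept[0] == n_min and ps.concept[-1] <= n_max

    def test_concepts_follow_grid(self, number_prompts):
        assert np.array_equal(number_prompts.concept, np.arange(0, 101, 10.0))

    @pytest.mark.parametrize("template", ["no placeholder", "two {} holes {}"])
    def test_malformed_template(self, template):
        with pytest.raises(TemplateError):
            generate_number_prompts(0, 10, 1, template)

    def test_inverted_range_rejected(self):
        with pytest.raises(ParameterError):
            generate_number_prompts(10, 0, 1)


class TestLinearTarget:
    def test_noiseless_identity(self, dense_prompts):
        ds = generate_linear_target(dense_prompts, 1.0, 0.0, 0.0, seed=0)
        assert np.allclose(ds.behavior.values, dense_prompts.concept)

    def test_sign_flip_reverses_ordering(self, dense_prompts):
        ds = generate_linear_target(dense_prompts, -1.0, 100.0, 0.0, seed=0)
        assert np.all(np.diff(ds.behavior.values) < 0)

    def test_noise_mean_within_sampling_band(self, dense_prompts):
        sd = 5.0
        ds = generate_linear_target(dense_prompts, 1.0, 0.0, sd, seed=2)
        resid = ds.behavior.values - dense_prompts.concept
        assert abs(resid.mean()) < 3 * sd / np.sqrt(len(dense_prompts))

    def test_parameter_recovery_by_ols(self, dense_prompts):
        """OLS on concept recovers the generating slope/intercept within 3 SE."""
        slope, intercept, sd = 2.0, 10.0, 4.0
        ds = generate_linear_target(dense_prompts, slope, intercept, sd, seed=3)
        x = dense_prompts.concept
        X = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(X, ds.behavior.values, rcond=None)
        resid = ds.behavior.values - X @ beta
        sigma2 = resid @ resid / (len(x) - 2)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        assert abs(beta[1] - slope) < 3 * np.sqrt(cov[1, 1])
        assert abs(beta[0] - intercept) < 3 * np.sqrt(cov[0, 0])

    def test_missing_concept_rejected(self):
        ps = PromptSet(prompts=["a", "b"])
        with pytest.raises(UsageError):
            generate_linear_target(ps, 1.0, 0.0, 1.0, seed=0)

    def test_seed_reproducibility(self, dense_prompts):
        a = generate_linear_target(dense_prompts, 1.0, 0.0, 5.0, seed=9)
        b = generate_linear_target(dense_prompts, 1.0, 0.0, 5.0, seed=9)
        assert np.array_equal(a.behavior.values, b.behavior.values)


class TestVShape:
    def test_symmetry_about_pivot(self):
        bv = BehaviorVector(np.array([0.0, 50.0, 100.0]))
        out = vshape_transform(bv, pivot=50.0).values
        assert out[0] == pytest.approx(out[2])
        assert out[0] > out[1]

    def test_pivot_at_minimum_is_monotone_rescaling(self):
        vals = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        out = vshape_transform(BehaviorVector(vals), pivot=float(vals.min())).values
        assert np.array_equal(np.argsort(out), np.argsort(vals))

    def test_median_pivot_resolution(self):
        bv = BehaviorVector(np.array([20.0, 30.0, 40.0]))
        out = vshape_transform(bv, pivot="median").values
        assert out[0] == pytest.approx(out[2])

    def test_range_preserved(self, linear_study):
        out = vshape_transform(linear_study.behavior).values
        y = linear_study.behavior.values
        assert out.min() == pytest.approx(y.min())
        assert out.max() == pytest.approx(y.max())

    def test_binary_mode_rejected(self):
        bv = BehaviorVector(np.array([0.0, 1.0]), mode="binary")
        with pytest.raises(UsageError):
            vshape_transform(bv)

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=30, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_double_fold_is_monotone_composition(self, values):
        """Folding twice, pivoting at the fold's minimum, preserves the fold's order."""
        bv = BehaviorVector(np.asarray(values))
        once = vshape_transform(bv, pivot="median")
        twice = vshape_transform(once, pivot=float(once.values.min()))
        order = np.argsort(once.values, kind="stable")
        # second fold is a non-decreasing function of the first
        assert np.all(np.diff(twice.values[order]) >= -1e-9)


class TestConditionStudy:
    def test_balanced_design(self):
        ds = generate_condition_study(("none", "moderate", "strong"), (90, 70, 50),
                                      within_sd=5.0, n_per_condition=20, seed=0)
        assert len(ds) == 60
        counts = {c: ds.prompt_set.condition.count(c) for c in set(ds.prompt_set.condition)}
        assert counts == {"none": 20, "moderate": 20, "strong": 20}
        # individual prompts within a condition
        assert len(set(ds.prompt_set.prompts)) == 60

    def test_degenerate_noise_hits_means_exactly(self):
        ds = generate_condition_study(("a", "b"), (10.0, 20.0), within_sd=0.0,
                                      n_per_condition=5, seed=0)
        for name, mu in [("a", 10.0), ("b", 20.0)]:
            vals = [v for v, c in zip(ds.behavior.values, ds.prompt_set.condition)
                    if c == name]
            assert np.allclose(vals, mu)

    def test_single_row(self):
        ds = generate_condition_study(("only",), (42.0,), within_sd=0.0,
                                      n_per_condition=1, seed=0)
        assert len(ds) == 1 and ds.behavior.values[0] == 42.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(UsageError):
            generate_condition_study(("a", "b"), (1.0,), 1.0, 2, 0)


class TestAutocorrelatedSeries:
    def test_lag1_autocorrelation_near_coefficient(self):
        """Sample lag-1 autocorrelation at n=150 stays in the estimator band."""
        phi = 0.8
        ds = generate_autocorrelated_series(150, phi, 1.0, seed=4)
        x = ds.behavior.values
        xc = x - x.mean()
        rho = (xc[:-1] @ xc[1:]) / (xc @ xc)
        assert abs(rho - phi) < 0.15

    def test_white_noise_limit(self):
        ds = generate_autocorrelated_series(400, 0.0, 1.0, seed=5)
        x = ds.behavior.values
        xc = x - x.mean()
        rho = (xc[:-1] @ xc[1:]) / (xc @ xc)
        assert abs(rho) < 2 / np.sqrt(len(x))

    def test_trial_prompt_grid(self):
        ds = generate_autocorrelated_series(150, 0.8, 1.0, seed=0)
        assert ds.prompt_set.prompts[0] == "This is trial 1"
        assert ds.prompt_set.prompts[-1] == "This is trial 150"
        assert np.array_equal(ds.prompt_set.concept, np.arange(1, 151.0))

    def test_nonstationary_coefficient_rejected(self):
        with pytest.raises(UsageError):
            generate_autocorrelated_series(10, 1.0, 1.0, seed=0)

    def test_truth_records_coefficient(self):
        ds = generate_autocorrelated_series(10, 0.3, 1.0, seed=0)
        assert ds.truth["ar_coefficient"] == 0.3


class TestHorizonChoices:
    def test_design_counts_exact(self):
        ds = generate_horizon_choices(n_games=50, horizon_lengths=(1, 6), seed=0)
        assert len(ds) == 50 * (1 + 6)
        # every horizon-6 game contributes remaining-trials 6..1
        labels = [c for c in ds.prompt_set.condition if c.startswith("h6")]
        for r in range(1, 7):
            assert labels.count(f"h6-r{r}") == 50

    def test_first_choice_gap_within_binomial_band(self):
        gap = 0.15
        ds = generate_horizon_choices(n_games=500, horizon_lengths=(1, 6),
                                      first_choice_explore_gap=gap,
                                      exploit_growth=0.05, seed=6)
        y = ds.behavior.values
        cond = np.array(ds.prompt_set.condition)
        p_short = y[cond == "h1-r1"].mean()
        p_long_first = y[cond == "h6-r6"].mean()
        assert abs((p_short - p_long_first) - gap) < 0.06

    def test_null_growth_flat_within_long_horizon(self):
        ds = generate_horizon_choices(n_games=500, horizon_lengths=(1, 6),
                                      exploit_growth=0.0, seed=7)
        y = ds.behavior.values
        cond = np.array(ds.prompt_set.condition)
        means = [y[cond == f"h6-r{r}"].mean() for r in range(1, 7)]
        assert max(means) - min(means) < 4 * np.sqrt(0.25 / 500) * 2

    def test_exploitation_grows_with_experience(self):
        ds = generate_horizon_choices(n_games=800, horizon_lengths=(1, 6),
                                      exploit_growth=0.1, seed=8)
        y = ds.behavior.values
        cond = np.array(ds.prompt_set.condition)
        means = [y[cond == f"h6-r{r}"].mean() for r in (6, 3, 1)]
        assert means[0] < means[1] < means[2]

    def test_invalid_probability_rejected(self):
        with pytest.raises(ParameterError):
            generate_horizon_choices(10, (1, 6), first_choice_explore_gap=0.5,
                                     exploit_growth=0.2, base_p_best=0.6, seed=0)

    def test_prompts_encode_remaining_trials(self):
        ds = generate_horizon_choices(n_games=2, horizon_lengths=(2,), seed=0)
        assert "trials left" in ds.prompt_set.prompts[0]


class TestReplicationAndIO:
    def test_replicates_share_text_with_distinct_ids(self, number_prompts):
        rep = replicate_prompt_set(number_prompts, 3)
        assert len(rep) == 3 * len(number_prompts)
        assert rep.prompts[0] == rep.prompts[1] == rep.prompts[2]
        assert len(set(rep.ids)) == len(rep)
        assert np.array_equal(rep.concept[:3], np.repeat(number_prompts.concept[0], 3))

    def test_bundle_round_trip(self, tmp_path, linear_study):
        prefix = tmp_path / "study"
        linear_study.save(prefix)
        loaded = StudyDataset.load(prefix)
        assert loaded.prompt_set.prompts == linear_study.prompt_set.prompts
        assert np.allclose(loaded.behavior.values, linear_study.behavior.values)
        assert np.allclose(loaded.prompt_set.concept, linear_study.prompt_set.concept)
        assert loaded.truth == linear_study.truth
        assert loaded.seed == linear_study.seed

    def test_identical_seed_identical_dataset(self):
        a = generate_horizon_choices(n_games=20, seed=77)
        b = generate_horizon_choices(n_games=20, seed=77)
        assert a.prompt_set.prompts == b.prompt_set.prompts
        assert np.array_equal(a.behavior.values, b.behavior.values)

    def test_feedback_prompts_concept_unrelated_to_trial(self):
        ps = generate_feedback_prompts(200, seed=3)
        t = np.arange(1, 201)
        r = np.corrcoef(ps.concept, t)[0, 1]
        assert abs(r) < 0.2
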