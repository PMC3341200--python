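import numpy as np
import pytest

from pias3net import (
    insensitive_parameters,
    normalize,
    sample_parameters,
    sensitivity_measure,
)
from pias3net.params import PARAM_NAMES
from pias3net.sensitivity import (
    OutcomeMatrix,
    ParameterSample,
    binned_statistic_matrix,
    outcome_matrix,
    permutation_filter,
)


class TestSampling:
    def test_within_factor_range(self, params):
        sample = sample_parameters(params, 500, seed=3)
        for name in PARAM_NAMES:
            default = getattr(params, name)
            col = sample.values[name]
            assert np.all(col >= 0.5 * default - 1e-12)
            assert np.all(col <= 2.0 * default + 1e-12)

    def test_median_at_default_by_log_symmetry(self, params):
        sample = sample_parameters(params, 10_000, seed=11)
        for name in ("k_Mdiss", "p_PIAS3", "gamma_STAT3"):
            default = getattr(params, name)
            med = np.median(sample.values[name])
            # log-uniform on [ln 0.5, ln 2] is symmetric about 0
            assert med == pytest.approx(default, rel=0.05)

    def test_deterministic_given_seed(self, params):
        a = sample_parameters(params, 50, seed=9).values
        b = sample_parameters(params, 50, seed=9).values
        assert a.equals(b)
        c = sample_parameters(params, 50, seed=10).values
        assert not a.equals(c)

    def test_degenerate_range_reproduces_defaults(self, params):
        sample = sample_parameters(params, 3, seed=0, factor_range=(1.0, 1.0))
        for name in PARAM_NAMES:
            assert np.allclose(sample.values[name], getattr(params, name))

    def test_invalid_inputs_rejected(self, params):
        with pytest.raises(ValueError):
            sample_parameters(params, 0, seed=0)
        with pytest.raises(ValueError):
            sample_parameters(params, 5, seed=0, factor_range=(2.0, 0.5))


class TestBinnedStatistic:
    def test_all_true_outcomes_give_zero(self, rng):
        x = rng.uniform(size=1000)
        assert sensitivity_measure(x, np.ones(1000, dtype=bool)) == 0.0

    def test_median_separator_gives_exactly_fifty(self, rng):
        """Outcome = indicator(parameter > median) at n = 10^4: half the
        bins are all-failure, half all-success, overall rate 1/2, so the
        statistic is 100 * 0.5 = 50 exactly."""
        x = rng.normal(size=10_000)
        outcome = x > np.median(x)
        assert sensitivity_measure(x, outcome, n_bins=100) == 50.0

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.uniform(0.5, 2.0, size=2000)
        outcome = rng.random(2000) < 0.3 + 0.4 * (x > 1.0)
        s0 = sensitivity_measure(x, outcome)
        assert sensitivity_measure(np.exp(x), outcome) == s0
        assert sensitivity_measure(-1.0 / x, outcome) == s0

    def test_indivisible_bin_count_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            sensitivity_measure(rng.uniform(size=1001), np.ones(1001, dtype=bool))

    def test_upper_bound(self, rng):
        """s_ij <= n_bins * max(f, 1-f) for any outcome pattern."""
        for _ in range(10):
            x = rng.uniform(size=1000)
            outcome = rng.random(1000) < rng.uniform(0.05, 0.95)
            f = outcome.mean()
            s = sensitivity_measure(x, outcome)
            assert s <= 100 * max(f, 1 - f) + 1e-9

    def test_matrix_form_matches_scalar_form(self, rng):
        values = rng.uniform(size=(600, 4))
        outcomes = rng.random((600, 3)) < 0.6
        s = binned_statistic_matrix(values, outcomes, n_bins=100)
        for i in range(3):
            for j in range(4):
                assert s[i, j] == pytest.approx(
                    sensitivity_measure(values[:, j], outcomes[:, i]))


def _toy_sample_outcomes(rng, n=10_000):
    """One separating parameter, one pure-noise parameter."""
    values = rng.uniform(0.5, 2.0, size=(n, 2))
    outcomes = np.column_stack([
        values[:, 0] > np.median(values[:, 0]),   # driven by parameter 0
        rng.random(n) < 0.5,                      # independent of both
    ])
    frame = ParameterSample(
        __import__("pandas").DataFrame(values, columns=["p0", "p1"]),
        seed=0)
    om = OutcomeMatrix(outcomes, np.ones(n, dtype=bool), (1, 2))
    return frame, om, values, outcomes


class TestPermutationFilter:
    def test_null_columns_zeroed_and_signal_survives(self, rng):
        sample, om, values, outcomes = _toy_sample_outcomes(rng)
        s = binned_statistic_matrix(values, outcomes, 100)
        thresholds, filtered = permutation_filter(
            sample, om, s, n_permutations=200, seed=5)
        assert np.all(thresholds >= 0)
        # experiment 1 is the median indicator of parameter 0: s = 50
        assert filtered[0, 0] == 50.0
        # the noise parameter never drives experiment 1
        assert filtered[0, 1] == 0.0
        # the coin-flip experiment is filtered to zero everywhere
        assert np.all(filtered[1] == 0.0)

    def test_filtered_never_exceeds_raw(self, rng):
        sample, om, values, outcomes = _toy_sample_outcomes(rng, n=2000)
        s = binned_statistic_matrix(values, outcomes, 100)
        _, filtered = permutation_filter(sample, om, s, 100, seed=1)
        assert np.all(filtered <= s)

    def test_insensitive_set_excludes_separator(self, rng):
        sample, om, values, outcomes = _toy_sample_outcomes(rng)
        s = binned_statistic_matrix(values, outcomes, 100)
        _, filtered = permutation_filter(sample, om, s, 200, seed=5)
        names = ("p0", "p1")
        assert insensitive_parameters(filtered, names) == {"p1"}


class TestNormalize:
    def test_zero_row_stays_zero(self):
        s = np.array([[0.0, 0.0], [2.0, 4.0]])
        out = normalize(s)
        assert np.all(out[0] == 0.0)

    def test_row_max_becomes_one_and_order_preserved(self, rng):
        s = rng.uniform(0.1, 30, size=(5, 7))
        out = normalize(s)
        assert np.allclose(out.max(axis=1), 1.0)
        for i in range(5):
            assert np.array_equal(np.argsort(out[i]), np.argsort(s[i]))
        assert out.min() >= 0 and out.max() <= 1

    def test_all_zero_matrix_gives_all_names(self):
        assert insensitive_parameters(np.zeros((28, 30))) == set(PARAM_NAMES)


class TestOutcomeMatrix:
    def test_defaults_row_matches_direct_battery(self, params):
        """A degenerate sample at the exact defaults reproduces the
        default battery verdicts: 27 of 28 pass."""
        from pias3net import run_all

        sample = sample_parameters(params, 1, seed=0, factor_range=(1.0, 1.0))
        om = outcome_matrix(sample)
        direct = run_all(params)
        expected = np.array([direct[i].passed for i in sorted(direct)])
        assert np.array_equal(om.outcomes[0], expected)
        assert om.outcomes[0].sum() == 27

    def test_identical_rows_give_identical_outcomes(self, params):
        sample = sample_parameters(params, 2, seed=0, factor_range=(1.0, 1.0))
        om = outcome_matrix(sample)
        assert np.array_equal(om.outcomes[0], om.outcomes[1])
        assert np.all((om.success_rates == 0.0) | (om.success_rates == 1.0))
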