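import numpy as np
import pytest
from scipy import stats

from exprdist import (
    ConfigError,
    DistFamily,
    bootstrap_gof,
    fit_log_cv_vs_mean,
    fleishman_coefficients,
    generate,
    kruskal_wallis,
    moment_table,
)
from exprdist.synthetic import (
    NAMED_FAMILIES,
    SyntheticSpec,
    _sample_named_family,
    fleishman_feasible_kurtosis,
)


class TestSpecValidation:
    def test_bad_proportion_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticSpec(noise_fraction=1.2)

    def test_family_weights_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            SyntheticSpec(family_weights={"normal": 0.5, "gamma": 0.3})

    def test_condition_counts_must_match_samples(self):
        with pytest.raises(ConfigError):
            SyntheticSpec(n_samples=10, condition_labels={"a": 3, "b": 3})

    def test_empty_conditions_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticSpec(condition_labels={})

    def test_positive_families_rejected_in_log_ratio_mode(self):
        with pytest.raises(ConfigError):
            SyntheticSpec(mode="log_ratio", family_weights={"gamma": 1.0})

    def test_yaml_round_trip(self, tmp_path):
        spec = SyntheticSpec(n_genes=10, n_samples=6, condition_labels={"a": 3, "b": 3}, seed=4)
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        assert SyntheticSpec.from_yaml(path) == spec


class TestGenerate:
    def test_shape_and_determinism(self):
        spec = SyntheticSpec(n_genes=100, n_samples=24, seed=9,
                             condition_labels={"a": 12, "b": 12})
        m1, t1 = generate(spec)
        m2, t2 = generate(SyntheticSpec(n_genes=100, n_samples=24, seed=9,
                                        condition_labels={"a": 12, "b": 12}))
        assert m1.values.shape == (100, 24)
        np.testing.assert_array_equal(m1.values, m2.values)
        assert t1.equals(t2)

    def test_truth_flags_match_proportions(self):
        spec = SyntheticSpec(n_genes=1000, n_samples=12, seed=1, noise_fraction=0.25,
                             affected_fraction=0.3, mixture_fraction=0.1,
                             condition_labels={"a": 6, "b": 6})
        _, truth = generate(spec)
        assert truth.noise.sum() == 250
        assert truth.affected.sum() == 300
        assert truth.mixture.sum() == 100
        assert not (truth.affected & truth.mixture).any()

    def test_zero_variance_spec_gives_constant_degenerate_row(self):
        spec = SyntheticSpec(
            n_genes=1, n_samples=5, cv_trend=(-np.inf, 0.0),
            noise_fraction=0.0, affected_fraction=0.0,
            condition_labels={"a": 5},
        )
        matrix, truth = generate(spec)
        assert np.ptp(matrix.values[0]) == 0.0
        assert bool(truth.degenerate.iloc[0])
        assert truth.family.iloc[0] == "constant"

    def test_noise_stratum_sits_below_floor(self, null_study):
        _, matrix, truth = null_study
        means = matrix.values.mean(axis=1)
        noise = truth.noise.to_numpy()
        assert (truth["mean"].to_numpy()[noise] <= 6.0).all()
        assert means[noise].mean() < means[~noise].mean()

    def test_sample_moments_unbiased_for_normal_family(self):
        """t-tests across genes at alpha=0.01: sample means center on the
        target means and ddof-1 variances on the target variances."""
        spec = SyntheticSpec(n_genes=3000, n_samples=40, seed=21, noise_fraction=0.0,
                             affected_fraction=0.0, condition_labels={"a": 20, "b": 20})
        matrix, truth = generate(spec)
        mean_err = matrix.values.mean(axis=1) - truth["mean"].to_numpy()
        var_err = matrix.values.var(axis=1, ddof=1) - truth["sd"].to_numpy() ** 2
        for err in (mean_err, var_err):
            t = err.mean() / (err.std(ddof=1) / np.sqrt(err.size))
            assert abs(t) < stats.norm.isf(0.005)


class TestConditionEffects:
    def test_affected_gene_power_matches_monte_carlo_oracle(self):
        """Kruskal-Wallis detection rate of affected genes agrees with a
        standalone power simulation at identical settings."""
        spec = SyntheticSpec(
            n_genes=800, n_samples=30, seed=13, noise_fraction=0.0,
            affected_fraction=0.5, affected_effect=2.0, affected_effect_in_sd=True,
            mixture_fraction=0.0, condition_labels={"a": 10, "b": 10, "c": 10},
        )
        matrix, truth = generate(spec)
        groups = [range(0, 10), range(10, 20), range(20, 30)]
        aff = truth.affected.to_numpy()
        p = np.array(
            [kruskal_wallis([matrix.values[g, ix] for ix in groups])[1]
             for g in range(spec.n_genes)]
        )
        power_obs = (p[aff] <= 0.1).mean()

        # oracle: same shift geometry (conditions at -0.5, 0, +0.5 x effect x sd)
        rng = np.random.default_rng(99)
        hits = 0
        reps = 1500
        offsets = np.repeat([-0.5, 0.0, 0.5], 10) * 2.0
        for _ in range(reps):
            x = rng.normal(0, 1, 30) + offsets
            hits += kruskal_wallis([x[:10], x[10:20], x[20:]])[1] <= 0.1
        power_mc = hits / reps
        se = np.sqrt(
            power_mc * (1 - power_mc) / reps + power_obs * (1 - power_obs) / aff.sum()
        )
        assert abs(power_obs - power_mc) < 3 * se + 0.01

    def test_unaffected_fraction_near_alpha_complement(self):
        spec = SyntheticSpec(n_genes=2000, n_samples=30, seed=3, noise_fraction=0.0,
                             affected_fraction=0.0, condition_labels={"a": 10, "b": 10, "c": 10})
        matrix, _ = generate(spec)
        groups = [range(0, 10), range(10, 20), range(20, 30)]
        p = np.array(
            [kruskal_wallis([matrix.values[g, ix] for ix in groups])[1]
             for g in range(2000)]
        )
        assert abs((p > 0.1).mean() - 0.9) < 0.025


@pytest.mark.parametrize("family", NAMED_FAMILIES)
def test_named_family_moment_matching(family):
    """Each family's parameters are solved so the population mean/sd hit the
    requested targets; checked on large samples."""
    rng = np.random.default_rng(5)
    m, s = (8.0, 0.4) if family not in ("normal", "logistic", "extreme_value") else (2.0, 1.5)
    draws, _ = _sample_named_family(rng, family, m, s, 400_000)
    assert draws.mean() == pytest.approx(m, abs=6 * s / np.sqrt(400_000) + 1e-3)
    assert draws.std() == pytest.approx(s, rel=0.02)


class TestFleishman:
    @pytest.mark.parametrize("skew, kurt", [(0.0, 3.0), (0.8, 4.5), (-1.0, 5.0), (0.3, 2.4)])
    def test_cubic_transform_matches_target_moments(self, skew, kurt):
        a, b, c, d = fleishman_coefficients(skew, kurt)
        z = np.random.default_rng(11).standard_normal(2_000_000)
        y = a + b * z + c * z**2 + d * z**3
        assert y.mean() == pytest.approx(0.0, abs=5e-3)
        assert y.std() == pytest.approx(1.0, abs=5e-3)
        assert stats.skew(y) == pytest.approx(skew, abs=0.03)
        assert stats.kurtosis(y, fisher=False) == pytest.approx(kurt, abs=0.1)

    def test_infeasible_target_rejected(self):
        with pytest.raises(ConfigError):
            fleishman_coefficients(0.0, 1.2)  # below the platykurtic boundary

    def test_feasibility_floor_is_solvable(self):
        for s in (-1.5, -0.5, 0.0, 0.7, 2.0):
            fleishman_coefficients(s, fleishman_feasible_kurtosis(s) + 0.02)


class TestTrendEmulation:
    def test_cv_trend_slope_recovered_within_three_se(self):
        spec = SyntheticSpec(n_genes=10_000, n_samples=100, seed=17, noise_fraction=0.0,
                             affected_fraction=0.0, cv_trend=(-2.10, -0.22))
        matrix, _ = generate(spec)
        fit = fit_log_cv_vs_mean(moment_table(matrix))
        for est, se, truth in zip(fit.coefficients, fit.standard_errors, (-2.10, -0.22)):
            assert abs(est - truth) < 3 * se

    def test_single_family_genes_pass_own_gof_at_nominal_rate(self):
        """Clean one-family genes should be rejected by their own family's
        bootstrap GOF at about the nominal 5% rate."""
        spec = SyntheticSpec(n_genes=250, n_samples=60, seed=23, noise_fraction=0.0,
                             affected_fraction=0.0, mixture_fraction=0.0,
                             condition_labels={"a": 60})
        matrix, _ = generate(spec)
        rej = sum(
            bootstrap_gof(matrix.values[g], DistFamily.NORMAL, "ad", B=300,
                          seed=np.random.default_rng((23, g))).reject_95
            for g in range(250)
        )
        frac = rej / 250
        assert abs(frac - 0.05) < 2.9 * np.sqrt(0.05 * 0.95 / 250) + 0.01
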