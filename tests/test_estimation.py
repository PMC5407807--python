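"""IV estimation: Wald ratio, 2SLS, sensitivity analyses, translation."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

from bidirmr import (
    AssocResult,
    IVRegression,
    ParameterError,
    StructuralParams,
    WeakInstrumentError,
    adjusted_iv,
    harmonize,
    instrument_split,
    obs_vs_iv,
    simulate_cohort,
    standardize,
    translate_to_percent,
    tsls,
    wald_ratio,
    weighted_score,
)
from bidirmr.data import TRAIT_BMI, TRAIT_T
from bidirmr.simulate import generic_profile


def _assoc(beta, se, n=7446, r2=0.02):
    return AssocResult(beta, se, 0.01, r2, n)


def _sim_pipeline(specs, n, params, seed, direction="bmi_to_t"):
    profile = params.cohort_profiles[0]
    matrix, table = simulate_cohort(specs, n, params, profile.name, seed=seed)
    matrix = harmonize(matrix, specs)
    z_bmi = standardize(table.data["bmi"], table.data, ["age", "smoking"], "natural_log")
    z_t = standardize(
        table.data["testosterone"], table.data, ["age", "smoking", "sampling_time"]
    )
    bmi_specs = [s for s in specs if s.trait == TRAIT_BMI]
    t_specs = [s for s in specs if s.trait == TRAIT_T]
    if direction == "bmi_to_t":
        score = weighted_score(matrix, bmi_specs)
        return matrix, table, score, z_bmi, z_t
    score = weighted_score(matrix, t_specs)
    return matrix, table, score, z_t, z_bmi


class TestWaldRatio:
    def test_printed_t_direction_rows(self):
        """Ratios of the published T-direction coefficients, 2 dp."""
        weighted = wald_ratio(
            _assoc(-0.020, 0.020), _assoc(-0.281, 0.020), direction="t_to_bmi"
        )
        assert round(weighted.ratio, 2) == 0.07
        unweighted = wald_ratio(
            _assoc(-0.004, 0.015), _assoc(-0.191, 0.015), direction="t_to_bmi"
        )
        assert round(unweighted.ratio, 2) == 0.02

    def test_null_numerator_symmetric_ci(self):
        result = wald_ratio(_assoc(0.0, 0.02), _assoc(-0.28, 0.02))
        assert result.ratio == 0.0
        assert result.ci_low == pytest.approx(-result.ci_high)
        assert result.p == pytest.approx(1.0)

    def test_zero_denominator_refused(self):
        with pytest.raises(WeakInstrumentError):
            wald_ratio(_assoc(-0.02, 0.01), _assoc(0.0, 0.01))

    def test_delta_method_se(self):
        out, exp = _assoc(-0.02, 0.004), _assoc(-0.28, 0.01)
        result = wald_ratio(out, exp)
        expected = abs(out.beta / exp.beta) * np.sqrt(
            (out.se / out.beta) ** 2 + (exp.se / exp.beta) ** 2
        )
        assert result.se == pytest.approx(expected, rel=1e-12)

    def test_unit_labels_per_direction(self):
        bmi_dir = wald_ratio(_assoc(-0.006, 0.002), _assoc(0.022, 0.002), "bmi_to_t")
        t_dir = wald_ratio(_assoc(-0.02, 0.02), _assoc(-0.281, 0.02), "t_to_bmi")
        assert "SD testosterone per SD ln-BMI" == bmi_dir.units
        assert "SD ln-BMI per SD testosterone" == t_dir.units


class TestTSLS:
    def test_equals_wald_ratio_single_instrument(self):
        rng = np.random.default_rng(41)
        n = 2000
        g = rng.binomial(2, 0.4, n).astype(float)
        x = 0.1 * g + rng.normal(size=n)
        y = -0.3 * x + rng.normal(size=n)
        fit = IVRegression(y, x, g).fit()
        slope_y = np.polyfit(g, y, 1)[0]
        slope_x = np.polyfit(g, x, 1)[0]
        assert fit.estimate == pytest.approx(slope_y / slope_x, abs=1e-10)

    def test_instrument_affine_invariance(self):
        rng = np.random.default_rng(43)
        n = 1500
        g = rng.normal(size=n)
        x = 0.2 * g + rng.normal(size=n)
        y = 0.25 * x + rng.normal(size=n)
        base = IVRegression(y, x, g).fit()
        scaled = IVRegression(y, x, 3.7 * g + 11.0).fit()
        assert scaled.estimate == pytest.approx(base.estimate, abs=1e-10)
        assert scaled.se == pytest.approx(base.se, abs=1e-10)

    def test_parameter_recovery_large_sample(self, specs_full):
        """2SLS recovers the generator truth -0.25 at n=100k."""
        params = StructuralParams(
            cohort_profiles=(generic_profile(100_000),), heterogeneity_sd=0.0, seed=5
        )
        _, _, score, z_bmi, z_t = _sim_pipeline(specs_full, 100_000, params, seed=5)
        iv = tsls(score, z_bmi, z_t)
        assert iv.ratio == pytest.approx(-0.25, abs=0.05)
        assert iv.f_first_stage > 100

    def test_deconfounding_vs_observational(self, specs_full):
        """Latent-confounded null: observational biased, 2SLS near zero."""
        params = StructuralParams(
            beta_causal=0.0,
            conf_latent_bmi=0.45,
            conf_latent_t=-0.50,
            cohort_profiles=(generic_profile(50_000),),
            heterogeneity_sd=0.0,
            seed=6,
        )
        _, _, score, z_bmi, z_t = _sim_pipeline(specs_full, 50_000, params, seed=6)
        obs_slope = np.polyfit(z_bmi.z.to_numpy(), z_t.z.to_numpy(), 1)[0]
        iv = tsls(score, z_bmi, z_t)
        assert abs(obs_slope) > 0.1
        assert abs(iv.ratio) < 0.06

    def test_weak_instrument_refused(self):
        rng = np.random.default_rng(47)
        n = 500
        g = rng.normal(size=n)
        x = rng.normal(size=n)  # instrument unrelated to exposure
        y = rng.normal(size=n)
        with pytest.raises(WeakInstrumentError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                IVRegression(y, x, 0.0001 * g + 1e-6 * rng.normal(size=n)).fit()

    def test_small_sample_rejected(self):
        with pytest.raises(ParameterError):
            IVRegression(np.ones(30), np.ones(30), np.ones(30))


class TestAdjustedIV:
    def test_full_shbg_mediation_attenuates(self, specs_full):
        params = StructuralParams(
            cohort_profiles=(generic_profile(40_000),), heterogeneity_sd=0.0, seed=7
        ).with_shbg_mediation(1.0)
        matrix, table, score, z_bmi, z_t = _sim_pipeline(specs_full, 40_000, params, seed=7)
        unadjusted = tsls(score, z_bmi, z_t)
        z_shbg = standardize(
            table.data["shbg"], table.data, ["age", "smoking", "sampling_time"],
            name="shbg",
        )
        adjusted = adjusted_iv(score, z_bmi, z_t, z_shbg)
        assert abs(adjusted.ratio) < 0.5 * abs(unadjusted.ratio)

    def test_shbg_independent_path_unchanged(self, specs_full):
        params = StructuralParams(
            shbg_bmi_coeff=0.0,
            cohort_profiles=(generic_profile(40_000),),
            heterogeneity_sd=0.0,
            seed=8,
        )
        matrix, table, score, z_bmi, z_t = _sim_pipeline(specs_full, 40_000, params, seed=8)
        unadjusted = tsls(score, z_bmi, z_t)
        z_shbg = standardize(
            table.data["shbg"], table.data, ["age", "smoking", "sampling_time"],
            name="shbg",
        )
        adjusted = adjusted_iv(score, z_bmi, z_t, z_shbg)
        assert abs(adjusted.ratio - unadjusted.ratio) < unadjusted.se

    def test_all_missing_shbg_skipped(self, specs_full):
        from bidirmr import StandardizedPhenotype

        params = StructuralParams(
            cohort_profiles=(generic_profile(5_000),), heterogeneity_sd=0.0, seed=9
        )
        _, table, score, z_bmi, z_t = _sim_pipeline(specs_full, 5_000, params, seed=9)
        empty = StandardizedPhenotype(
            pd.Series(dtype=float), "shbg", [], "none"
        )
        assert adjusted_iv(score, z_bmi, z_t, empty) is None


class TestInstrumentSplit:
    def test_partition_validation(self, specs_full):
        bmi_specs = [s for s in specs_full if s.trait == TRAIT_BMI]
        params = StructuralParams(
            cohort_profiles=(generic_profile(5_000),), heterogeneity_sd=0.0, seed=10
        )
        matrix, _, _, z_bmi, z_t = _sim_pipeline(specs_full, 5_000, params, seed=10)
        with pytest.raises(ParameterError):
            instrument_split(matrix, bmi_specs, ([], [s.rsid for s in bmi_specs]),
                             z_bmi, z_t)
        with pytest.raises(ParameterError):
            instrument_split(
                matrix, bmi_specs,
                ([bmi_specs[0].rsid], [s.rsid for s in bmi_specs[:50]]),
                z_bmi, z_t,
            )

    def test_homogeneous_split_consistent(self, specs_full):
        """Half-vs-half split: similar estimates, both CIs cover truth."""
        bmi_specs = [s for s in specs_full if s.trait == TRAIT_BMI]
        params = StructuralParams(
            cohort_profiles=(generic_profile(50_000),), heterogeneity_sd=0.0, seed=11
        )
        matrix, _, _, z_bmi, z_t = _sim_pipeline(specs_full, 50_000, params, seed=11)
        half = [s.rsid for s in bmi_specs[:48]]
        rest = [s.rsid for s in bmi_specs[48:]]
        left, right, p_diff = instrument_split(
            matrix, bmi_specs, (half, rest), z_bmi, z_t
        )
        assert p_diff > 0.05
        for side in (left, right):
            assert side.ci_low <= -0.25 <= side.ci_high

    def test_pleiotropy_detected(self, specs_full):
        """A direct variant-to-outcome path makes the split estimates differ."""
        bmi_specs = [s for s in specs_full if s.trait == TRAIT_BMI]
        target = [s.rsid for s in bmi_specs[:10]]
        params = StructuralParams(
            pleiotropy_rsids=tuple(target),
            pleiotropy_effect=-0.15,
            cohort_profiles=(generic_profile(50_000),),
            heterogeneity_sd=0.0,
            seed=12,
        )
        matrix, _, _, z_bmi, z_t = _sim_pipeline(specs_full, 50_000, params, seed=12)
        rest = [s.rsid for s in bmi_specs[10:]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            left, right, p_diff = instrument_split(
                matrix, bmi_specs, (target, rest), z_bmi, z_t
            )
        assert p_diff < 0.05


class TestObsVsIV:
    def test_equality_gives_p_one(self):
        iv = tsls_like = wald_ratio(_assoc(-0.006, 0.002), _assoc(0.022, 0.002))
        obs = _assoc(iv.ratio, 0.01)
        assert obs_vs_iv(obs, iv) == pytest.approx(1.0)

    def test_boundary_variance_warns(self):
        iv = wald_ratio(_assoc(-0.006, 0.0001), _assoc(0.022, 0.0001))
        obs = _assoc(-0.30, 0.5)  # observational SE larger than IV SE
        with pytest.warns(UserWarning):
            p = obs_vs_iv(obs, iv)
        assert 0.0 < p <= 1.0

    def test_discordance_detected(self, specs_full):
        """Strong confounding, truth 0: observational and IV disagree."""
        params = StructuralParams(
            beta_causal=0.0,
            conf_latent_bmi=0.45,
            conf_latent_t=-0.50,
            cohort_profiles=(generic_profile(50_000),),
            heterogeneity_sd=0.0,
            seed=13,
        )
        _, _, score, z_bmi, z_t = _sim_pipeline(specs_full, 50_000, params, seed=13)
        from scipy import stats as _stats

        fit = _stats.linregress(z_bmi.z.to_numpy(), z_t.z.to_numpy())
        obs = AssocResult(fit.slope, fit.stderr, max(fit.pvalue, 1e-300),
                          fit.rvalue**2, len(z_bmi.z))
        iv = tsls(score, z_bmi, z_t)
        assert obs_vs_iv(obs, iv) < 0.05


class TestTranslation:
    def test_null_ratio_is_zero_percent(self):
        result = translate_to_percent(0.0, 1.6, 0.15, 4.2)
        assert result.percent_change == 0.0

    def test_no_bmi_change_is_zero(self):
        result = translate_to_percent(-0.25, 1.6, 0.15, 4.2, bmi_from=30, bmi_to=30)
        assert result.percent_change == 0.0

    def test_pooled_moment_arithmetic(self):
        """Published-scale moments: -0.25 ratio -> ~+11.7% for BMI 30->25."""
        result = translate_to_percent(-0.25, 1.6, 0.148, 4.2)
        assert result.percent_change == pytest.approx(11.73, abs=0.05)

    def test_negative_ratio_and_bmi_loss_increase_t(self):
        result = translate_to_percent(-0.25, 1.6, 0.15, 4.2)
        assert result.percent_change > 0

    def test_antisymmetry_up_to_denominator(self):
        down = translate_to_percent(-0.25, 1.6, 0.15, 4.2, 30, 25)
        up = translate_to_percent(-0.25, 1.6, 0.15, 4.2, 25, 30)
        assert down.percent_change == pytest.approx(-up.percent_change)

    def test_ci_translates_with_ratio(self):
        iv = wald_ratio(_assoc(-0.006, 0.002), _assoc(0.022, 0.002))
        result = translate_to_percent(iv, 1.6, 0.15, 4.2)
        assert result.ci_low_percent < result.percent_change < result.ci_high_percent

    def test_domain_errors(self):
        with pytest.raises(ParameterError):
            translate_to_percent(-0.25, 0.0, 0.15, 4.2)
        with pytest.raises(ParameterError):
            translate_to_percent(-0.25, 1.6, 0.15, -1.0)
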