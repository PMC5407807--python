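"""Generator properties: variance targeting, moment matching, MR assumptions."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from bidirmr import (
    ConfigurationError,
    ParameterError,
    StructuralParams,
    simulate_cohort,
    simulate_study,
    simulate_variants,
)
from bidirmr.data import AUTOSOMAL, X_MALE, TRAIT_BMI, TRAIT_T
from bidirmr.simulate import expected_score_r2, generic_profile


class TestSimulateVariants:
    def test_panel_composition(self):
        specs = simulate_variants(97, 3, (0.019, 0.025), seed=1)
        assert len(specs) == 100
        bmi = [s for s in specs if s.trait == TRAIT_BMI]
        t = [s for s in specs if s.trait == TRAIT_T]
        assert len(bmi) == 97 and len(t) == 3
        assert all(s.chrom_class == AUTOSOMAL for s in bmi)
        assert sum(s.chrom_class == X_MALE for s in t) == 1
        assert all(s.weight >= 0 for s in specs)
        assert all(0 < s.eaf < 1 for s in specs)

    def test_variance_targets_exact_by_construction(self):
        specs = simulate_variants(97, 3, (0.019, 0.025), seed=1)
        assert expected_score_r2(specs, TRAIT_BMI) == pytest.approx(0.019, rel=1e-9)
        assert expected_score_r2(specs, TRAIT_T) == pytest.approx(0.025, rel=1e-9)

    def test_single_variant_r2_equals_target(self):
        specs = simulate_variants(1, 1, (0.01, 0.01), seed=7)
        assert len(specs) == 2
        for trait in (TRAIT_BMI, TRAIT_T):
            assert expected_score_r2(specs, trait) == pytest.approx(0.01, rel=1e-12)

    def test_realized_r2_monte_carlo(self):
        """The 2*p*(1-p)*w² bookkeeping holds in a large simulated sample."""
        specs = simulate_variants(5, 2, (0.02, 0.02), seed=3)
        params = StructuralParams(
            cohort_profiles=(generic_profile(200_000),),
            heterogeneity_sd=0.0,
            seed=3,
        )
        matrix, table = simulate_cohort(specs, 200_000, params, "POOLED", seed=13)
        ln_bmi = np.log(table.data["bmi"].to_numpy())
        weights = {s.rsid: s.weight for s in specs if s.trait == TRAIT_BMI}
        score = sum(
            matrix.dosages[r].to_numpy() * w for r, w in weights.items()
        )
        r2 = np.corrcoef(score, ln_bmi)[0, 1] ** 2
        assert r2 == pytest.approx(0.02, rel=0.10)

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            simulate_variants(0, 3, (0.019, 0.025))
        with pytest.raises(ParameterError):
            simulate_variants(97, 3, (0.0, 0.025))
        with pytest.raises(ParameterError):
            simulate_variants(97, 3, (0.019, 0.5))

    def test_deterministic(self):
        a = simulate_variants(10, 3, (0.019, 0.025), seed=42)
        b = simulate_variants(10, 3, (0.019, 0.025), seed=42)
        assert a == b


class TestSimulateCohort:
    def test_profile_moments(self, specs_full):
        """A 50k-person cohort reproduces the requested BMI mean closely."""
        params = StructuralParams(seed=11)
        matrix, table = simulate_cohort(specs_full, 50_000, params, "MrOS", seed=11)
        assert 25.0 <= table.data["bmi"].mean() <= 27.6
        assert table.data["bmi"].std() == pytest.approx(3.6, rel=0.05)
        assert table.data["testosterone"].mean() == pytest.approx(4.5, rel=0.05)

    def test_null_model_t_score_independent_of_bmi(self, specs_full):
        params = StructuralParams(
            beta_causal=0.0,
            conf_age_bmi=0.0, conf_age_t=0.0,
            conf_smoke_bmi=0.0, conf_smoke_t=0.0,
            conf_latent_bmi=0.0, conf_latent_t=0.0,
            cohort_profiles=(generic_profile(100_000),),
            heterogeneity_sd=0.0,
            seed=2,
        )
        matrix, table = simulate_cohort(specs_full, 100_000, params, "POOLED", seed=2)
        t_weights = {s.rsid: s.weight for s in specs_full if s.trait == TRAIT_T}
        t_score = sum(matrix.dosages[r].to_numpy() * w for r, w in t_weights.items())
        corr = np.corrcoef(t_score, np.log(table.data["bmi"].to_numpy()))[0, 1]
        assert abs(corr) < 0.01

    def test_genotype_confounder_independence(self, specs_full):
        params = StructuralParams(
            cohort_profiles=(generic_profile(100_000),), heterogeneity_sd=0.0, seed=4
        )
        matrix, table = simulate_cohort(specs_full, 100_000, params, "POOLED", seed=4)
        weights = {s.rsid: s.weight for s in specs_full if s.trait == TRAIT_BMI}
        score = sum(matrix.dosages[r].to_numpy() * w for r, w in weights.items())
        for covariate in ("age", "smoking"):
            corr = np.corrcoef(score, table.data[covariate].to_numpy())[0, 1]
            assert abs(corr) < 0.01

    def test_dosage_bounds(self, medium_cohort):
        matrix, _, specs = medium_cohort
        for spec in specs:
            column = matrix.dosages[spec.rsid]
            assert column.min() >= 0
            assert column.max() <= (2 if spec.chrom_class == AUTOSOMAL else 1)

    def test_variance_bookkeeping(self, specs_full):
        """Var(ln BMI) matches the log-normal target within 2% at n=200k."""
        params = StructuralParams(
            cohort_profiles=(generic_profile(200_000),), heterogeneity_sd=0.0, seed=6
        )
        matrix, table = simulate_cohort(specs_full, 200_000, params, "POOLED", seed=6)
        profile = params.cohort_profiles[0]
        target_var = np.log1p((profile.bmi_sd / profile.bmi_mean) ** 2)
        realized = np.var(np.log(table.data["bmi"].to_numpy()))
        assert realized == pytest.approx(target_var, rel=0.02)
        # score variance component
        weights = {s.rsid: s.weight for s in specs_full if s.trait == TRAIT_BMI}
        score = sum(matrix.dosages[r].to_numpy() * w for r, w in weights.items())
        assert np.var(score) == pytest.approx(0.019, rel=0.05)

    def test_unknown_cohort_raises(self, specs_small):
        with pytest.raises(ConfigurationError):
            simulate_cohort(specs_small, 100, StructuralParams(), "Atlantis")

    def test_determinism_bit_identical(self, specs_small):
        params = StructuralParams(seed=3)
        m1, t1 = simulate_cohort(specs_small, 500, params, "GOOD", seed=3)
        m2, t2 = simulate_cohort(specs_small, 500, params, "GOOD", seed=3)
        pd.testing.assert_frame_equal(m1.dosages, m2.dosages)
        pd.testing.assert_frame_equal(t1.data, t2.data)

    def test_missingness_rate(self, specs_small):
        params = StructuralParams(missing_rate=0.1, seed=8)
        matrix, _ = simulate_cohort(specs_small, 5_000, params, "SHIP", seed=8)
        rate = matrix.dosages.isna().to_numpy().mean()
        assert rate == pytest.approx(0.1, abs=0.01)


class TestSimulateStudy:
    def test_five_cohorts_total_7446(self, specs_small):
        study = simulate_study(StructuralParams(seed=1), specs=specs_small)
        assert len(study.cohorts) == 5
        assert study.total_n == 7446
        assert [t.n for _, t in study.cohorts] == [929, 1682, 1912, 427, 2496]

    def test_single_profile_study(self, specs_small):
        params = StructuralParams(cohort_profiles=(generic_profile(500),), seed=2)
        study = simulate_study(params, specs=specs_small)
        assert len(study.cohorts) == 1

    def test_dropped_variant_emulation(self, specs_small):
        dropped = specs_small[0].rsid
        params = StructuralParams(
            drop_variants={"Inter99": (dropped,)}, seed=3
        )
        study = simulate_study(params, specs=specs_small)
        by_name = {t.cohort: m for m, t in study.cohorts}
        assert dropped not in by_name["Inter99"].variant_ids
        assert dropped in by_name["GOOD"].variant_ids

    def test_heterogeneity_spreads_observational_slope(self, specs_small):
        """Replicated studies show between-cohort slope variance ~ het_sd²."""
        deltas = []
        for seed in range(40):
            params = StructuralParams(
                heterogeneity_sd=0.08,
                cohort_profiles=tuple(
                    dataclasses.replace(p, n=600)
                    for p in StructuralParams().cohort_profiles
                ),
                seed=100 + seed,
            )
            study = simulate_study(params, specs=specs_small)
            slopes = []
            for matrix, table in study.cohorts:
                x = np.log(table.data["bmi"].to_numpy())
                y = table.data["testosterone"].to_numpy()
                x = (x - x.mean()) / x.std()
                y = (y - y.mean()) / y.std()
                slopes.append(np.polyfit(x, y, 1)[0])
            deltas.append(np.var(slopes, ddof=1))
        # observed slope variance = het variance + sampling noise (~1/600)
        between = np.mean(deltas) - 1.0 / 600
        assert 0.08**2 * 0.4 < between < 0.08**2 * 2.5

    def test_mediation_solver_routes_effect_through_shbg(self):
        params = StructuralParams().with_shbg_mediation(1.0)
        b_direct, gamma, d = params.shbg_coefficients()
        assert b_direct == pytest.approx(0.0, abs=1e-10)
        assert gamma * d == pytest.approx(params.beta_causal, abs=1e-10)
        untouched = StructuralParams().with_shbg_mediation(0.0)
        assert untouched.shbg_bmi_coeff == 0.0
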