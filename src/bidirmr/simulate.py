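"""Synthetic multi-cohort generator for the bidirectional BMI-testosterone MR design.

The generator draws genotypes independently of all confounders (the defining
property of a valid genetic instrument) and builds phenotypes from a
linear-Gaussian structural model on the standardized scale:

    x* (std ln BMI)  = G_BMI + a1*z_age + a2*z_smoke + c1*U + e_x
    s* (std SHBG)    = d*x* + lam*u + e_s
    y* (std T)       = b_direct*x* + gamma*s* - G_T + b1*z_age + b2*z_smoke + c2*U + e_y

``U`` is a latent confounder the analysis cannot adjust for (lifestyle,
adiposity-related physiology beyond age and smoking); with the default
coefficients it leaves the covariate-adjusted observational slope ~0.05 SD
more negative than the causal effect, the pattern the genetic instruments
are there to resolve.

where ``G_BMI = sum_i w_i (g_i - E g_i)`` is the centered weighted dosage sum
over the BMI instruments with variance equal to the target instrument R²
(likewise ``G_T`` for the testosterone-decreasing instruments), ``u`` is a
latent factor shared by SHBG and T, and noise variances are solved so that
every standardized trait has unit variance.  The TOTAL causal effect of one SD
of ln BMI on T in SD units is ``beta_causal = b_direct + gamma*d``: it is the
quantity a two-stage-least-squares analysis of the simulated data estimates.
Standardized traits are then mapped to each cohort's native scale (BMI
log-normal in kg/m2, T and SHBG linear in ng/ml and nmol/l).

Only second moments matter to the downstream analysis (everything is
Z-scored), which is why a linear-Gaussian model on the standardized scale is
sufficient to emulate the study.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng

from .data import (
    AUTOSOMAL,
    NUCLEOTIDES,
    TRAIT_BMI,
    TRAIT_T,
    X_MALE,
    CohortTable,
    DosageMatrix,
    VariantSpec,
)
from .errors import ConfigurationError, ParameterError

# rsIDs of the three testosterone instruments from the male testosterone GWAS;
# rs5934505 is X-linked and hemizygous in men.
T_SNP_RSIDS = ("rs6258", "rs12150660", "rs5934505")


@dataclasses.dataclass(frozen=True)
class CohortProfile:
    """Target native-scale moments for one cohort (means with SDs)."""

    name: str
    n: int
    bmi_mean: float
    bmi_sd: float
    t_mean: float
    t_sd: float
    shbg_mean: float
    shbg_sd: float
    age_mean: float
    age_sd: float
    smoking_prev: float

    def __post_init__(self) -> None:
        for field in ("bmi_sd", "t_sd", "shbg_sd", "age_sd"):
            if getattr(self, field) <= 0:
                raise ParameterError(f"{self.name}: {field} must be > 0")
        if not 0.0 < self.smoking_prev < 1.0:
            raise ParameterError(f"{self.name}: smoking prevalence must be in (0,1)")
        if self.n < 10:
            raise ParameterError(f"{self.name}: n must be >= 10")


# Five-cohort design with the study's published characteristics.
FIVE_COHORT_PROFILES: tuple[CohortProfile, ...] = (
    CohortProfile("GOOD", 929, 22.4, 3.2, 4.7, 1.5, 20.4, 7.2, 18.9, 0.6, 0.09),
    CohortProfile("MrOS", 1682, 26.3, 3.6, 4.5, 1.7, 46.0, 22.9, 75.4, 3.2, 0.09),
    CohortProfile("SHIP", 1912, 27.7, 4.0, 4.8, 1.7, 51.3, 25.6, 50.8, 16.4, 0.34),
    CohortProfile("SHIP-Trend", 427, 27.8, 3.7, 4.0, 1.3, 38.3, 14.2, 50.1, 14.2, 0.22),
    CohortProfile("Inter99", 2496, 26.8, 4.0, 4.4, 1.6, 31.8, 13.1, 46.7, 7.9, 0.36),
)


def generic_profile(n: int, name: str = "POOLED") -> CohortProfile:
    """A single pooled-scale male cohort (moments near the five-cohort average)."""
    return CohortProfile(name, n, 26.5, 3.9, 4.5, 1.6, 38.0, 18.0, 52.0, 15.0, 0.27)


@dataclasses.dataclass
class StructuralParams:
    """Parameters of the structural model, all on the standardized scale.

    ``beta_causal`` is the total causal effect of ln BMI on T in SD(T) per
    SD(ln BMI); confounder coefficients are SD units per SD of the (centered,
    scaled) confounder; R² targets are the variance fractions the two
    instrument scores explain; ``shbg_t_corr`` is the target SHBG-T
    correlation (0.51 ~ SHBG explaining ~26% of T variance);
    ``heterogeneity_sd`` is a between-cohort SD added to the direct causal
    path, producing cohort-to-cohort spread of the observational slope.
    ``conf_latent_*`` load both traits on a latent confounder outside the
    adjustment set, so the covariate-adjusted observational slope stays
    biased relative to the causal effect (by their product, ~ -0.05 at the
    defaults) while the genotype-based estimates are not.
    """

    beta_causal: float = -0.25
    conf_age_bmi: float = 0.25
    conf_age_t: float = -0.20
    conf_smoke_bmi: float = 0.10
    conf_smoke_t: float = -0.05
    conf_latent_bmi: float = 0.25
    conf_latent_t: float = -0.20
    r2_grs_bmi: float = 0.019
    r2_grs_t: float = 0.025
    shbg_t_corr: float = 0.51
    shbg_bmi_coeff: float = -0.10
    shbg_latent_loading: float = 0.60
    heterogeneity_sd: float = 0.05
    grs_age_interaction: float = 0.0
    pleiotropy_rsids: tuple[str, ...] = ()
    pleiotropy_effect: float = 0.0
    missing_rate: float = 0.0
    drop_variants: Mapping[str, tuple[str, ...]] = dataclasses.field(default_factory=dict)
    cohort_profiles: tuple[CohortProfile, ...] = FIVE_COHORT_PROFILES
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("r2_grs_bmi", "r2_grs_t"):
            value = getattr(self, name)
            if not 0.0 <= value <= 0.2:
                raise ParameterError(f"{name} must be in [0, 0.2], got {value}")
        if not self.cohort_profiles:
            raise ParameterError("cohort_profiles must be non-empty")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ParameterError("missing_rate must be in [0, 1)")
        if abs(self.shbg_bmi_coeff) >= 1.0:
            raise ParameterError("shbg_bmi_coeff must have magnitude < 1")

    def shbg_coefficients(self) -> tuple[float, float, float]:
        """(b_direct, gamma, d): solve the SHBG loading from the correlation target.

        gamma is chosen so corr(T, SHBG) hits ``shbg_t_corr`` up to small
        confounder cross-terms, holding the TOTAL ln BMI -> T effect at
        ``beta_causal`` = b_direct + gamma*d.
        """
        d = self.shbg_bmi_coeff
        gamma = (self.shbg_t_corr - self.beta_causal * d) / (1.0 - d * d)
        b_direct = self.beta_causal - gamma * d
        return b_direct, gamma, d

    def with_shbg_mediation(self, fraction: float) -> "StructuralParams":
        """Route ``fraction`` of the causal BMI->T path through SHBG.

        Solves beta*(fraction-1)*d² + corr*d - fraction*beta = 0 for the SHBG
        <- ln BMI coefficient d subject to gamma*d = fraction*beta_causal.
        """
        if not 0.0 <= fraction <= 1.0:
            raise ParameterError("mediated fraction must be in [0, 1]")
        beta, corr = self.beta_causal, self.shbg_t_corr
        if fraction == 0.0 or beta == 0.0:
            return dataclasses.replace(self, shbg_bmi_coeff=0.0)
        a = beta * (fraction - 1.0)
        roots = np.roots([a, corr, -fraction * beta]) if a != 0 else np.array(
            [fraction * beta / corr]
        )
        real = [float(r.real) for r in np.atleast_1d(roots) if abs(r.imag) < 1e-12]
        candidates = [r for r in real if abs(r) < 1.0]
        if not candidates:
            raise ParameterError("no admissible SHBG coefficient for this mediation")
        d = min(candidates, key=abs)
        return dataclasses.replace(self, shbg_bmi_coeff=d)


# ---------------------------------------------------------------------------
# Variant simulation
# ---------------------------------------------------------------------------


def simulate_variants(
    n_bmi: int,
    n_t: int,
    r2_targets: tuple[float, float] = (0.019, 0.025),
    seed: int = 0,
) -> list[VariantSpec]:
    """Draw instrument SNP panels whose scores explain the target variance.

    Effect-allele frequencies are uniform on (0.08, 0.86) — centred slightly
    below 0.5 so the 97-SNP allele-count score sits near the published mean of
    ~91 — and log-normal raw weights are rescaled so that
    ``sum_i ploidy_i * p_i * (1-p_i) * w_i²`` equals each R² target exactly
    (the score's explained variance on the unit-variance standardized trait).
    With ``n_t = 3`` the panel mimics the published testosterone instruments:
    two autosomal SNPs and one X-linked SNP hemizygous in men.
    """
    if n_bmi < 1 or n_t < 1:
        raise ParameterError("variant counts must be >= 1")
    for target in r2_targets:
        if not 0.0 < target < 0.2:
            raise ParameterError(f"r2 target must be in (0, 0.2), got {target}")
    rng = default_rng(seed)

    def _panel(count: int, target: float, trait: str) -> list[VariantSpec]:
        eaf = rng.uniform(0.08, 0.86, size=count)
        raw = rng.lognormal(mean=math.log(0.02), sigma=0.5, size=count)
        if trait == TRAIT_T and count == 3:
            classes = [AUTOSOMAL, AUTOSOMAL, X_MALE]
            rsids = list(T_SNP_RSIDS)
        else:
            classes = [AUTOSOMAL] * count
            prefix = "rs90" if trait == TRAIT_BMI else "rs95"
            rsids = [f"{prefix}{i:05d}" for i in range(count)]
        ploidy = np.array([2 if c == AUTOSOMAL else 1 for c in classes])
        variance = ploidy * eaf * (1.0 - eaf)
        scale = math.sqrt(target / float(np.sum(variance * raw**2)))
        specs = []
        for i in range(count):
            alleles = rng.choice(NUCLEOTIDES, size=2, replace=False)
            specs.append(
                VariantSpec(
                    rsid=rsids[i],
                    chrom_class=classes[i],
                    effect_allele=str(alleles[0]),
                    other_allele=str(alleles[1]),
                    weight=float(raw[i] * scale),
                    eaf=float(eaf[i]),
                    trait=trait,
                )
            )
        return specs

    return _panel(n_bmi, r2_targets[0], TRAIT_BMI) + _panel(n_t, r2_targets[1], TRAIT_T)


def expected_score_r2(specs: Iterable[VariantSpec], trait: str) -> float:
    """Theoretical variance a trait's weighted score explains of the unit trait."""
    return float(
        sum(s.dosage_variance * s.weight**2 for s in specs if s.trait == trait)
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def _lognormal_moments(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of ln X for a log-normal X with the given mean and SD."""
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def simulate_cohort(
    specs: Sequence[VariantSpec],
    n: int,
    params: StructuralParams,
    cohort_name: str,
    seed: int | None = None,
    rng: Generator | None = None,
) -> tuple[DosageMatrix, CohortTable]:
    """Simulate one cohort under the structural model.

    Genotypes are binomial at each variant's effect-allele frequency (two
    draws autosomal, one for the male X variant) and independent of every
    confounder.  Native BMI is log-normal matched to the cohort profile's
    mean/SD; T and SHBG are linear maps of their standardized values (floored
    at a small positive value, which affects <0.5% of draws at the published
    moments).
    """
    profile = next((p for p in params.cohort_profiles if p.name == cohort_name), None)
    if profile is None:
        raise ConfigurationError(
            f"cohort {cohort_name!r} not in params.cohort_profiles "
            f"({[p.name for p in params.cohort_profiles]})"
        )
    if n < 10:
        raise ParameterError("n must be >= 10")
    if rng is None:
        rng = default_rng(params.seed if seed is None else seed)

    delta = rng.normal(0.0, params.heterogeneity_sd) if params.heterogeneity_sd > 0 else 0.0

    rsids = [s.rsid for s in specs]
    eaf = np.array([s.eaf for s in specs])
    trials = np.array([s.ploidy for s in specs])
    genotypes = rng.binomial(trials[None, :], eaf[None, :], size=(n, len(specs))).astype(
        float
    )
    centered = genotypes - (trials * eaf)[None, :]

    bmi_idx = np.array([s.trait == TRAIT_BMI for s in specs])
    t_idx = ~bmi_idx
    weights = np.array([s.weight for s in specs])
    g_bmi = centered[:, bmi_idx] @ weights[bmi_idx]
    g_t = centered[:, t_idx] @ weights[t_idx]

    r2_b = expected_score_r2(specs, TRAIT_BMI)
    r2_t = expected_score_r2(specs, TRAIT_T)

    age = np.maximum(rng.normal(profile.age_mean, profile.age_sd, size=n), 18.0)
    z_age = (age - profile.age_mean) / profile.age_sd
    smoking = (rng.random(n) < profile.smoking_prev).astype(int)
    z_smoke = (smoking - profile.smoking_prev) / math.sqrt(
        profile.smoking_prev * (1.0 - profile.smoking_prev)
    )

    a1, a2 = params.conf_age_bmi, params.conf_smoke_bmi
    b1, b2 = params.conf_age_t, params.conf_smoke_t
    c1, c2 = params.conf_latent_bmi, params.conf_latent_t
    b_direct, gamma, d = params.shbg_coefficients()
    b_direct = b_direct + delta

    var_ex = 1.0 - r2_b - a1**2 - a2**2 - c1**2
    if var_ex <= 0:
        raise ParameterError("ln-BMI variance budget exceeded (score + confounders)")
    u_conf = rng.normal(0, 1, n)
    x_star = (
        g_bmi + a1 * z_age + a2 * z_smoke + c1 * u_conf
        + rng.normal(0, math.sqrt(var_ex), n)
    )
    if params.grs_age_interaction != 0.0 and r2_b > 0:
        x_star = x_star + params.grs_age_interaction * (g_bmi / math.sqrt(r2_b)) * z_age

    lam = params.shbg_latent_loading
    var_es = 1.0 - d**2 - lam**2
    if var_es <= 0:
        raise ParameterError("SHBG variance budget exceeded")
    u = rng.normal(0, 1, n)
    s_star = d * x_star + lam * u + rng.normal(0, math.sqrt(var_es), n)

    a_total = b_direct + gamma * d
    var_struct = b_direct**2 + gamma**2 + 2 * b_direct * gamma * d
    var_ey = 1.0 - (
        var_struct
        + r2_t
        + b1**2
        + b2**2
        + c2**2
        + 2 * a_total * (a1 * b1 + a2 * b2 + c1 * c2)
    )
    if var_ey <= 0:
        raise ParameterError("testosterone variance budget exceeded")
    y_star = (
        b_direct * x_star
        + gamma * s_star
        - g_t
        + b1 * z_age
        + b2 * z_smoke
        + c2 * u_conf
        + rng.normal(0, math.sqrt(var_ey), n)
    )
    if params.pleiotropy_effect != 0.0 and params.pleiotropy_rsids:
        mask = np.array([s.rsid in params.pleiotropy_rsids for s in specs])
        sub = centered[:, mask] @ weights[mask]
        sub_sd = math.sqrt(
            sum(
                s.dosage_variance * s.weight**2
                for s in specs
                if s.rsid in params.pleiotropy_rsids
            )
        )
        y_star = y_star + params.pleiotropy_effect * sub / sub_sd

    mu_ln, sd_ln = _lognormal_moments(profile.bmi_mean, profile.bmi_sd)
    bmi = np.exp(mu_ln + sd_ln * x_star)
    testosterone = np.maximum(profile.t_mean + profile.t_sd * y_star, 0.05)
    shbg = np.maximum(profile.shbg_mean + profile.shbg_sd * s_star, 0.5)
    sampling_time = rng.uniform(7.0, 11.0, n)

    if params.missing_rate > 0:
        mask = rng.random(genotypes.shape) < params.missing_rate
        genotypes[mask] = np.nan

    ids = pd.Index([f"{cohort_name}_{i:06d}" for i in range(n)], name="individual_id")
    dosage_frame = pd.DataFrame(genotypes, index=ids, columns=rsids)
    matrix = DosageMatrix(
        dosage_frame,
        {s.rsid: s.effect_allele for s in specs},
        {s.rsid: s.chrom_class for s in specs},
    )
    dropped = params.drop_variants.get(cohort_name, ())
    if dropped:
        matrix = matrix.drop_variants(dropped)

    table = CohortTable(
        pd.DataFrame(
            {
                "bmi": bmi,
                "testosterone": testosterone,
                "shbg": shbg,
                "age": age,
                "smoking": smoking,
                "sampling_time": sampling_time,
            },
            index=ids,
        ),
        cohort=cohort_name,
    )
    return matrix, table


@dataclasses.dataclass
class SimulatedStudy:
    """A simulated multi-cohort study: instrument panel plus per-cohort data."""

    specs: list[VariantSpec]
    cohorts: list[tuple[DosageMatrix, CohortTable]]

    @property
    def total_n(self) -> int:
        return sum(table.n for _, table in self.cohorts)


def simulate_study(
    params: StructuralParams,
    specs: Sequence[VariantSpec] | None = None,
    n_bmi: int = 97,
    n_t: int = 3,
) -> SimulatedStudy:
    """Simulate every cohort in ``params.cohort_profiles`` with a shared panel.

    The default configuration yields the five-cohort design totalling 7446
    men.  Reproducible: cohort seeds are spawned deterministically from
    ``params.seed``.
    """
    ss = SeedSequence(params.seed)
    children = ss.spawn(len(params.cohort_profiles) + 1)
    if specs is None:
        variant_seed = int(children[0].generate_state(1)[0] % (2**31))
        specs = simulate_variants(
            n_bmi, n_t, (params.r2_grs_bmi, params.r2_grs_t), seed=variant_seed
        )
    cohorts = [
        simulate_cohort(
            specs, profile.n, params, profile.name, rng=default_rng(child)
        )
        for profile, child in zip(params.cohort_profiles, children[1:])
    ]
    return SimulatedStudy(list(specs), cohorts)


def scramble_alleles(
    matrix: DosageMatrix,
    specs: Sequence[VariantSpec],
    seed: int = 0,
    prob: float = 0.5,
) -> DosageMatrix:
    """Randomly re-orient a subset of variants to their other allele.

    For a flipped variant the stored dosage becomes ``ploidy - g`` and the
    counted allele becomes the spec's other allele.  Used to exercise the
    harmonizer: harmonizing a scrambled matrix must reproduce the original.
    """
    rng = default_rng(seed)
    out = matrix.copy()
    by_rsid = {s.rsid: s for s in specs}
    for rsid in out.variant_ids:
        if rng.random() < prob:
            spec = by_rsid[rsid]
            out.dosages[rsid] = spec.ploidy - out.dosages[rsid]
            current = out.counted_allele[rsid]
            out.counted_allele[rsid] = (
                spec.other_allele if current == spec.effect_allele else spec.effect_allele
            )
    return out
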