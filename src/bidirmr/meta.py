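"""Inverse-variance meta-analysis (fixed and DerSimonian-Laird random effects)
and the pooled individual-level alternative.

Per-cohort estimates are combined with weights ``1/se²`` (fixed effect) or
``1/(se² + tau²)`` (random effects), where tau² is the DerSimonian-Laird
method-of-moments between-study variance.  Cochran's Q and I² quantify
heterogeneity; ``model_select`` mirrors the study's practice of switching to
random effects when the Q test rejects homogeneity.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import CohortTable, DosageMatrix, VariantSpec
from .diagnostics import AssocResult, associate
from .errors import DataError, ParameterError
from .estimation import IVResult, tsls
from .scores import RiskScore, harmonize, unweighted_score, weighted_score
from .standardize import StandardizedPhenotype, standardize

logger = logging.getLogger(__name__)

_Z975 = float(stats.norm.ppf(0.975))


@dataclasses.dataclass
class MetaResult:
    """A combined estimate with heterogeneity statistics."""

    pooled_beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    q_stat: float
    q_p: float
    i_squared: float
    tau_squared: float
    model: str  # "fixed" | "random"
    k: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.i_squared <= 100.0:
            raise ParameterError("I² must be in [0, 100]")
        if self.tau_squared < 0:
            raise ParameterError("tau² must be >= 0")
        if not self.ci_low <= self.pooled_beta <= self.ci_high:
            raise ParameterError("CI must bracket the pooled estimate")
        if self.model == "fixed" and self.tau_squared != 0.0:
            raise ParameterError("fixed-effect tau² must be 0")


def _validate(betas: Sequence[float], ses: Sequence[float], k_min: int) -> tuple[np.ndarray, np.ndarray]:
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.shape != ses.shape or betas.ndim != 1:
        raise ParameterError("betas and ses must be 1-D and matched")
    if len(betas) < k_min:
        raise ParameterError(f"need at least {k_min} studies")
    if np.any(ses <= 0):
        raise ParameterError("all standard errors must be > 0")
    return betas, ses


def _heterogeneity(betas: np.ndarray, ses: np.ndarray) -> tuple[float, float, float]:
    """Cochran's Q (fixed weights), its p-value, and I² in percent."""
    k = len(betas)
    if k == 1:
        return 0.0, 1.0, 0.0
    w = 1.0 / ses**2
    pooled = float(np.sum(w * betas) / np.sum(w))
    q = float(np.sum(w * (betas - pooled) ** 2))
    q_p = float(stats.chi2.sf(q, k - 1))
    i2 = max(0.0, (q - (k - 1)) / q) * 100.0 if q > 0 else 0.0
    return q, q_p, i2


def _combine(betas: np.ndarray, ses: np.ndarray, tau2: float, model: str) -> MetaResult:
    q, q_p, i2 = _heterogeneity(betas, ses)
    w = 1.0 / (ses**2 + tau2)
    pooled = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    p = float(max(2.0 * stats.norm.sf(abs(pooled) / se), np.finfo(float).tiny))
    return MetaResult(
        pooled_beta=pooled,
        se=se,
        ci_low=pooled - _Z975 * se,
        ci_high=pooled + _Z975 * se,
        p=p,
        q_stat=q,
        q_p=q_p,
        i_squared=i2,
        tau_squared=tau2,
        model=model,
        k=len(betas),
    )


def fixed_meta(betas: Sequence[float], ses: Sequence[float]) -> MetaResult:
    """Fixed-effect inverse-variance combination (weights 1/se²)."""
    betas, ses = _validate(betas, ses, k_min=1)
    return _combine(betas, ses, tau2=0.0, model="fixed")


def random_meta(betas: Sequence[float], ses: Sequence[float]) -> MetaResult:
    """DerSimonian-Laird random-effects combination.

    tau² = max(0, (Q - (k-1)) / (sum(w) - sum(w²)/sum(w))) with fixed-effect
    weights w; when Q <= k-1 this collapses exactly to the fixed-effect model
    (tau² = 0).
    """
    betas, ses = _validate(betas, ses, k_min=2)
    w = 1.0 / ses**2
    q, _, _ = _heterogeneity(betas, ses)
    k = len(betas)
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    return _combine(betas, ses, tau2=tau2, model="random")


def model_select(
    betas: Sequence[float], ses: Sequence[float], alpha: float = 0.05
) -> MetaResult:
    """Q-test-driven choice: random effects when heterogeneity is detected
    (q_p < alpha), fixed effect otherwise."""
    betas, ses = _validate(betas, ses, k_min=1)
    if len(betas) == 1:
        return fixed_meta(betas, ses)
    _, q_p, _ = _heterogeneity(betas, ses)
    if q_p < alpha:
        logger.info("model_select: heterogeneity q_p=%.4g < %.2f -> random effects", q_p, alpha)
        return random_meta(betas, ses)
    logger.info("model_select: q_p=%.4g >= %.2f -> fixed effect", q_p, alpha)
    return fixed_meta(betas, ses)


def meta_to_frame(per_study: dict[str, tuple[float, float]], combined: MetaResult) -> pd.DataFrame:
    """Forest-plot-ready table: per-study rows plus the combined estimate."""
    w_total = sum(1.0 / (se**2 + combined.tau_squared) for _, se in per_study.values())
    rows = []
    for study, (beta, se) in per_study.items():
        weight = (1.0 / (se**2 + combined.tau_squared)) / w_total * 100.0
        rows.append(
            {
                "study": study,
                "beta": beta,
                "se": se,
                "ci_low": beta - _Z975 * se,
                "ci_high": beta + _Z975 * se,
                "weight_pct": weight,
                "model": "",
            }
        )
    rows.append(
        {
            "study": f"combined ({combined.model})",
            "beta": combined.pooled_beta,
            "se": combined.se,
            "ci_low": combined.ci_low,
            "ci_high": combined.ci_high,
            "weight_pct": 100.0,
            "model": combined.model,
        }
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pooled individual-level analysis
# ---------------------------------------------------------------------------


def _pooled_tables(cohorts: Sequence[tuple[DosageMatrix, CohortTable]]) -> pd.DataFrame:
    frames = []
    for _, table in cohorts:
        frame = table.data.copy()
        frame["cohort"] = table.cohort
        frames.append(frame)
    return pd.concat(frames)


def pooled_scores(
    cohorts: Sequence[tuple[DosageMatrix, CohortTable]],
    specs: Sequence[VariantSpec],
    weighted: bool = True,
    **score_kwargs,
) -> RiskScore:
    """Concatenated per-cohort scores, each cohort scored on its available
    variants (the 96-of-97-SNP cohort keeps its shorter panel)."""
    variant_sets = [set(m.variant_ids) for m, _ in cohorts]
    shared = set.intersection(*variant_sets) if variant_sets else set()
    if not shared:
        raise DataError("cohorts share no variants; cannot pool")
    union = set.union(*variant_sets)
    if shared != union:
        logger.info(
            "pooled_scores: cohorts differ in %d variant(s); each cohort scored "
            "on its own panel", len(union - shared)
        )
    builder = weighted_score if weighted else unweighted_score
    pieces = [builder(harmonize(m, specs), specs, **score_kwargs) for m, _ in cohorts]
    values = pd.concat([p.values for p in pieces])
    used = pd.concat([p.n_variants_used for p in pieces])
    return RiskScore(values, weighted, used, pieces[0].scale_note)


def pooled_standardized(
    cohorts: Sequence[tuple[DosageMatrix, CohortTable]],
    phenotype: str,
    adjustment: Sequence[str],
    transform: str = "none",
) -> StandardizedPhenotype:
    """Pooled-sample Z-score with cohort indicators in the adjustment set."""
    pooled = _pooled_tables(cohorts)
    return standardize(
        pooled[phenotype],
        covariates=pooled,
        adjustment_set=[*adjustment, "cohort"],
        transform=transform,
        name=phenotype,
    )


def pooled_analysis(
    cohorts: Sequence[tuple[DosageMatrix, CohortTable]],
    specs: Sequence[VariantSpec],
    kind: str = "association",
    direction: str = "bmi_to_t",
    weighted: bool = True,
    instrument: str = "GRS",
) -> AssocResult | IVResult:
    """Run the requested analysis on concatenated individual-level data.

    ``kind="association"`` regresses the pooled adjusted outcome Z-score on
    the pooled score; ``kind="iv"`` runs pooled 2SLS.  Cohort membership is
    always in the adjustment set.
    """
    bmi_specs = [s for s in specs if s.trait == "bmi_increasing"]
    t_specs = [s for s in specs if s.trait == "t_decreasing"]
    z_bmi = pooled_standardized(cohorts, "bmi", ["age", "smoking"], "natural_log")
    z_t = pooled_standardized(
        cohorts, "testosterone", ["age", "smoking", "sampling_time"]
    )
    if direction == "bmi_to_t":
        score = pooled_scores(cohorts, bmi_specs, weighted=weighted)
        exposure, outcome = z_bmi, z_t
    elif direction == "t_to_bmi":
        score = pooled_scores(cohorts, t_specs, weighted=weighted)
        exposure, outcome = z_t, z_bmi
    else:
        raise ParameterError("direction must be 'bmi_to_t' or 't_to_bmi'")
    if kind == "association":
        return associate(score, outcome)
    if kind == "iv":
        return tsls(score, exposure, outcome, direction=direction, instrument=instrument)
    raise ParameterError("kind must be 'association' or 'iv'")
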