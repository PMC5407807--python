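"""Instrument-strength and MR-assumption diagnostics.

The validity of a risk-score instrument rests on: a strong association with
its own trait (quantified by the incremental R² and the single-instrument
F statistic ``(n-2) R² / (1-R²)``), no association with known confounders
(age, smoking), no effect-modification by covariates, linearity of the
score-trait relation, and per-SNP associations consistent with the aggregate
score (with nominal and Bonferroni significance flags).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data import DosageMatrix, VariantSpec
from .errors import DegenerateFitError, ParameterError
from .scores import RiskScore, _check_harmonized
from .standardize import StandardizedPhenotype

logger = logging.getLogger(__name__)

MIN_N = 30


@dataclasses.dataclass
class AssocResult:
    """A score-phenotype regression summary."""

    beta: float
    se: float
    p: float
    r2: float
    n: int

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ParameterError("standard error must be > 0")
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ParameterError("r2 must be in [0, 1]")

    @property
    def ci(self) -> tuple[float, float]:
        half = stats.norm.ppf(0.975) * self.se
        return (self.beta - half, self.beta + half)


@dataclasses.dataclass
class PerSnpResult:
    rsid: str
    assoc: AssocResult | None
    nominal: bool
    bonferroni: bool
    monomorphic: bool = False


@dataclasses.dataclass
class DiagnosticsReport:
    """Everything the instrument-validation stage reports for one score."""

    instrument: str
    assoc: AssocResult
    f_stat: float
    confounder_pvals: dict[str, float]
    interaction_pvals: dict[str, float]
    quadratic_p: float | None = None
    per_snp: list[PerSnpResult] = dataclasses.field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"quantity": "beta", "value": self.assoc.beta},
            {"quantity": "se", "value": self.assoc.se},
            {"quantity": "p", "value": self.assoc.p},
            {"quantity": "r2", "value": self.assoc.r2},
            {"quantity": "n", "value": self.assoc.n},
            {"quantity": "f_stat", "value": self.f_stat},
        ]
        for cov, p in self.confounder_pvals.items():
            rows.append({"quantity": f"confounder_p[{cov}]", "value": p})
        for mod, p in self.interaction_pvals.items():
            rows.append({"quantity": f"interaction_p[{mod}]", "value": p})
        if self.quadratic_p is not None:
            rows.append({"quantity": "quadratic_p", "value": self.quadratic_p})
        return pd.DataFrame(rows).assign(instrument=self.instrument)

    def summary(self) -> str:
        lines = [
            f"Instrument {self.instrument}: beta={self.assoc.beta:.4f} "
            f"(SE {self.assoc.se:.4f}), p={self.assoc.p:.3g}, "
            f"R2={100 * self.assoc.r2:.2f}%, F={self.f_stat:.1f}, n={self.assoc.n}"
        ]
        for cov, p in self.confounder_pvals.items():
            verdict = "balanced" if p > 0.05 else "ASSOCIATED"
            lines.append(f"  confounder {cov}: p={p:.3f} ({verdict})")
        for mod, p in self.interaction_pvals.items():
            lines.append(f"  interaction with {mod}: p={p:.3f}")
        if self.quadratic_p is not None:
            lines.append(f"  quadratic term: p={self.quadratic_p:.3f}")
        if self.per_snp:
            nominal = sum(r.nominal for r in self.per_snp)
            bonf = sum(r.bonferroni for r in self.per_snp)
            lines.append(
                f"  per-SNP scan: {nominal}/{len(self.per_snp)} nominal, "
                f"{bonf} past Bonferroni"
            )
        return "\n".join(lines)


def _aligned(score: RiskScore, z: StandardizedPhenotype) -> tuple[np.ndarray, np.ndarray]:
    common = score.values.index.intersection(z.z.index)
    if len(common) < MIN_N:
        raise ParameterError(f"fewer than {MIN_N} matched individuals")
    return score.values.loc[common].to_numpy(), z.z.loc[common].to_numpy()


def associate(score: RiskScore, z: StandardizedPhenotype) -> AssocResult:
    """OLS slope of the standardized phenotype on the score.

    Covariate adjustment already lives inside ``z``, so the reported R² is
    the incremental variance the instrument explains of the adjusted trait —
    the quantity the single-instrument F statistic is built from.
    """
    x, y = _aligned(score, z)
    if np.var(x) == 0:
        raise DegenerateFitError("instrument has zero variance")
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2)
    if fit.stderr == 0:  # numerically exact fit
        return AssocResult(float(fit.slope), np.finfo(float).tiny, np.finfo(float).tiny,
                           1.0, len(x))
    return AssocResult(
        float(fit.slope), float(fit.stderr), float(max(fit.pvalue, np.finfo(float).tiny)),
        r2, len(x)
    )


def f_statistic(r2: float, n: int) -> float:
    """Single-instrument strength: ``(n - 2) * R² / (1 - R²)``."""
    if not 0.0 <= r2 < 1.0:
        raise ParameterError("r2 must be in [0, 1)")
    if n <= 2:
        raise ParameterError("n must exceed 2")
    return (n - 2) * r2 / (1.0 - r2)


def confounder_balance(
    score: RiskScore, covariates: pd.DataFrame
) -> dict[str, float]:
    """Per-covariate p-value for association with the score (score as outcome).

    Genotype is randomized at conception, so a valid instrument should be
    balanced over confounders; small p-values flag a violated assumption.
    Constant covariates are skipped with a warning.
    """
    pvals: dict[str, float] = {}
    for column in covariates.columns:
        x = covariates[column]
        common = score.values.index.intersection(x.dropna().index)
        xv = x.loc[common].to_numpy(dtype=float)
        if np.var(xv) == 0:
            logger.warning("confounder_balance: %s is constant, skipped", column)
            continue
        fit = stats.linregress(xv, score.values.loc[common].to_numpy())
        pvals[column] = float(fit.pvalue)
    return pvals


def interaction_test(
    score: RiskScore, z: StandardizedPhenotype, modifier: pd.Series, name: str = "modifier"
) -> float:
    """Two-sided p for a score x modifier product term in the OLS model."""
    common = score.values.index.intersection(z.z.index).intersection(
        modifier.dropna().index
    )
    if len(common) < MIN_N:
        raise ParameterError(f"fewer than {MIN_N} matched individuals")
    s = score.values.loc[common].to_numpy()
    m = modifier.loc[common].to_numpy(dtype=float)
    if np.var(m) == 0:
        raise ParameterError(f"modifier {name} is constant")
    if np.var(s) == 0:
        raise DegenerateFitError("instrument has zero variance")
    s_c = s - s.mean()
    m_c = m - m.mean()
    design = sm.add_constant(np.column_stack([s_c, m_c, s_c * m_c]))
    fit = sm.OLS(z.z.loc[common].to_numpy(), design).fit()
    return float(fit.pvalues[3])


def nonlinearity_test(score: RiskScore, z: StandardizedPhenotype) -> float:
    """Two-sided p for a squared-score term (the linearity check)."""
    x, y = _aligned(score, z)
    if np.var(x) == 0:
        raise DegenerateFitError("instrument has zero variance")
    x_c = x - x.mean()
    design = sm.add_constant(np.column_stack([x_c, x_c**2]))
    fit = sm.OLS(y, design).fit()
    return float(fit.pvalues[2])


def per_snp_scan(
    matrix: DosageMatrix,
    specs: Sequence[VariantSpec],
    z: StandardizedPhenotype,
    alpha: float = 0.05,
) -> list[PerSnpResult]:
    """Per-variant OLS of the adjusted trait on dosage, with multiplicity flags.

    Nominal significance is ``p < alpha``; Bonferroni is ``p < alpha / m``
    with ``m`` the number of polymorphic variants actually tested.
    Monomorphic variants are flagged and excluded from the denominator.
    """
    if not 0.0 < alpha < 1.0:
        raise ParameterError("alpha must be in (0, 1)")
    present = _check_harmonized(matrix, specs)
    fits: dict[str, tuple] = {}
    monomorphic: list[str] = []
    for spec in present:
        column = matrix.dosages[spec.rsid]
        common = column.dropna().index.intersection(z.z.index)
        g = column.loc[common].to_numpy(dtype=float)
        if np.var(g) == 0:
            monomorphic.append(spec.rsid)
            continue
        fits[spec.rsid] = (stats.linregress(g, z.z.loc[common].to_numpy()), len(common))
    m_tested = len(fits)
    results: list[PerSnpResult] = []
    for spec in present:
        if spec.rsid in monomorphic:
            results.append(PerSnpResult(spec.rsid, None, False, False, True))
            continue
        fit, n_used = fits[spec.rsid]
        assoc = AssocResult(
            float(fit.slope), float(fit.stderr),
            float(max(fit.pvalue, np.finfo(float).tiny)),
            float(fit.rvalue**2),
            int(n_used),
        )
        results.append(
            PerSnpResult(
                spec.rsid,
                assoc,
                assoc.p < alpha,
                assoc.p < alpha / m_tested,
            )
        )
    return results
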