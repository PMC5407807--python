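"""Causal-effect estimation: Wald IV ratio, two-stage least squares, and the
companion sensitivity analyses.

Under the instrumental-variable assumptions (instrument associated with the
exposure, independent of confounders, and affecting the outcome only through
the exposure) the Wald ratio

    beta_IV = beta_{instrument->outcome} / beta_{instrument->exposure}

is a consistent estimator of the causal effect of the exposure on the outcome.
With a single aggregate score instrument and no extra covariates, two-stage
least squares (2SLS) gives the identical point estimate with a one-sample
variance; with covariates the 2SLS machinery handles them in both stages.

The module follows the statsmodels Model/Results idiom:
:class:`IVRegression` is constructed from arrays or a DataFrame and
``fit()`` returns an :class:`IVRegressionResults` carrying the estimate, its
uncertainty, first-stage strength diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import DosageMatrix, VariantSpec
from .diagnostics import AssocResult, associate, f_statistic
from .errors import (
    DataError,
    ParameterError,
    WeakInstrumentError,
    WeakInstrumentWarning,
)
from .scores import RiskScore, weighted_score, unweighted_score
from .standardize import StandardizedPhenotype

DIRECTIONS = ("bmi_to_t", "t_to_bmi")
UNIT_LABELS = {
    "bmi_to_t": "SD testosterone per SD ln-BMI",
    "t_to_bmi": "SD ln-BMI per SD testosterone",
}

_Z975 = float(stats.norm.ppf(0.975))


@dataclasses.dataclass
class IVResult:
    """A causal estimate with its CI, p-value and provenance."""

    ratio: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    method: str  # "wald_ratio" | "tsls"
    direction: str
    instrument: str
    adjustment: list[str] = dataclasses.field(default_factory=list)
    n: int | None = None
    f_first_stage: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ParameterError(f"direction must be one of {DIRECTIONS}")
        if not self.ci_low <= self.ratio <= self.ci_high:
            raise ParameterError("CI must bracket the point estimate")

    @property
    def units(self) -> str:
        return UNIT_LABELS[self.direction]


def wald_ratio(
    assoc_outcome: AssocResult,
    assoc_exposure: AssocResult,
    direction: str = "bmi_to_t",
    instrument: str = "GRS",
) -> IVResult:
    """IV ratio of the score-outcome to the score-exposure coefficient.

    The standard error uses the first-order delta method
    ``|ratio| * sqrt((se_out/beta_out)² + (se_exp/beta_exp)²)``; the null
    numerator degenerates to ``se_out / |beta_exp|``.  CIs and p are
    normal-approximation (instruments here have F >> 10, where delta-method
    and Fieller intervals agree).
    """
    b_out, b_exp = assoc_outcome.beta, assoc_exposure.beta
    if b_exp == 0:
        raise WeakInstrumentError("exposure association is exactly zero")
    ratio = b_out / b_exp
    if b_out == 0:
        se = assoc_outcome.se / abs(b_exp)
    else:
        se = abs(ratio) * math.sqrt(
            (assoc_outcome.se / b_out) ** 2 + (assoc_exposure.se / b_exp) ** 2
        )
    p = 2.0 * stats.norm.sf(abs(ratio) / se) if se > 0 else 0.0
    return IVResult(
        ratio=ratio,
        se=se,
        ci_low=ratio - _Z975 * se,
        ci_high=ratio + _Z975 * se,
        p=float(max(p, np.finfo(float).tiny)),
        method="wald_ratio",
        direction=direction,
        instrument=instrument,
        n=assoc_outcome.n,
        f_first_stage=f_statistic(assoc_exposure.r2, assoc_exposure.n),
    )


class IVRegression:
    """Two-stage least squares with a single instrument and optional covariates.

    Parameters
    ----------
    outcome, exposure, instrument : array-like, matched by position
    exog : optional 2-D array of extra covariates included in BOTH stages
    """

    def __init__(self, outcome, exposure, instrument, exog=None,
                 direction: str = "bmi_to_t", instrument_name: str = "GRS",
                 adjustment: Sequence[str] = ()):  # noqa: D401
        self.outcome = np.asarray(outcome, dtype=float)
        self.exposure = np.asarray(exposure, dtype=float)
        self.instrument = np.asarray(instrument, dtype=float)
        if exog is None:
            self.exog = np.empty((len(self.outcome), 0))
        else:
            self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
            if self.exog.shape[0] != len(self.outcome):
                self.exog = self.exog.T
        if not len(self.outcome) == len(self.exposure) == len(self.instrument):
            raise ParameterError("outcome, exposure and instrument lengths differ")
        if len(self.outcome) <= 50:
            raise ParameterError("2SLS requires n > 50")
        self.direction = direction
        self.instrument_name = instrument_name
        self.adjustment = list(adjustment)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, outcome: str, exposure: str,
                       instrument: str, exog: Sequence[str] = (), **kwargs):
        cols = [outcome, exposure, instrument, *exog]
        sub = frame[cols].dropna()
        return cls(
            sub[outcome], sub[exposure], sub[instrument],
            sub[list(exog)].to_numpy() if exog else None,
            adjustment=list(exog), **kwargs,
        )

    def fit(self, cov_type: str = "classical", f_floor: float = 10.0
            ) -> "IVRegressionResults":
        """Estimate by 2SLS.

        ``cov_type`` is "classical" (homoskedastic) or "robust" (HC0
        sandwich).  First-stage partial F below ``f_floor`` warns; F < 1 is
        refused as an unusable instrument.
        """
        n = len(self.outcome)
        ones = np.ones((n, 1))
        Z = np.hstack([ones, self.instrument[:, None], self.exog])
        X = np.hstack([ones, self.exposure[:, None], self.exog])
        y = self.outcome

        # First stage: exposure on instrument (+ covariates)
        first_coef, *_ = np.linalg.lstsq(Z, self.exposure, rcond=None)
        first_resid = self.exposure - Z @ first_coef
        dof1 = n - Z.shape[1]
        sigma1 = first_resid @ first_resid / dof1
        ZtZ_inv = np.linalg.inv(Z.T @ Z)
        se_inst = math.sqrt(max(sigma1 * ZtZ_inv[1, 1], np.finfo(float).tiny))
        f_first = (first_coef[1] / se_inst) ** 2
        if f_first < 1.0:
            raise WeakInstrumentError(
                f"first-stage F = {f_first:.2f} < 1; the instrument does not "
                "move the exposure"
            )
        if f_first < f_floor:
            warnings.warn(
                f"first-stage F = {f_first:.1f} below {f_floor}",
                WeakInstrumentWarning,
                stacklevel=2,
            )

        X_hat = Z @ np.linalg.lstsq(Z, X, rcond=None)[0]
        beta = np.linalg.solve(X_hat.T @ X, X_hat.T @ y)
        resid = y - X @ beta  # residuals at the ACTUAL exposure
        k = X.shape[1]
        bread = np.linalg.inv(X_hat.T @ X_hat)
        if cov_type == "classical":
            sigma2 = resid @ resid / (n - k)
            cov = sigma2 * bread
        elif cov_type == "robust":
            meat = (X_hat * resid[:, None] ** 2).T @ X_hat
            cov = bread @ meat @ bread
        else:
            raise ParameterError("cov_type must be 'classical' or 'robust'")
        return IVRegressionResults(self, beta, cov, f_first, n, cov_type)


class IVRegressionResults:
    """2SLS results: point estimates, covariance, diagnostics, summary table."""

    def __init__(self, model: IVRegression, params: np.ndarray, cov: np.ndarray,
                 f_first_stage: float, nobs: int, cov_type: str):
        self.model = model
        self.params = params
        self.cov_params = cov
        self.bse = np.sqrt(np.diag(cov))
        self.f_first_stage = float(f_first_stage)
        self.nobs = int(nobs)
        self.cov_type = cov_type

    @property
    def estimate(self) -> float:
        """The causal-effect coefficient (on the exposure)."""
        return float(self.params[1])

    @property
    def se(self) -> float:
        return float(self.bse[1])

    @property
    def pvalue(self) -> float:
        z = abs(self.estimate) / self.se
        return float(max(2.0 * stats.norm.sf(z), np.finfo(float).tiny))

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        half = stats.norm.ppf(1.0 - alpha / 2.0) * self.se
        return (self.estimate - half, self.estimate + half)

    def as_iv_result(self) -> IVResult:
        low, high = self.conf_int()
        return IVResult(
            ratio=self.estimate,
            se=self.se,
            ci_low=low,
            ci_high=high,
            p=self.pvalue,
            method="tsls",
            direction=self.model.direction,
            instrument=self.model.instrument_name,
            adjustment=self.model.adjustment,
            n=self.nobs,
            f_first_stage=self.f_first_stage,
        )

    def summary(self) -> str:
        low, high = self.conf_int()
        lines = [
            "Two-stage least squares (single instrument)",
            f"  instrument:      {self.model.instrument_name}",
            f"  direction:       {self.model.direction} "
            f"({UNIT_LABELS[self.model.direction]})",
            f"  n:               {self.nobs}",
            f"  first-stage F:   {self.f_first_stage:.1f}",
            f"  causal estimate: {self.estimate:.4f} "
            f"(SE {self.se:.4f}, {self.cov_type})",
            f"  95% CI:          [{low:.4f}, {high:.4f}]",
            f"  p (two-sided):   {self.pvalue:.3g}",
        ]
        if self.model.adjustment:
            lines.insert(3, f"  adjusted for:    {', '.join(self.model.adjustment)}")
        return "\n".join(lines)


def tsls(
    score: RiskScore,
    exposure_z: StandardizedPhenotype,
    outcome_z: StandardizedPhenotype,
    extra_covariates: pd.DataFrame | None = None,
    direction: str = "bmi_to_t",
    instrument: str = "GRS",
    cov_type: str = "classical",
) -> IVResult:
    """Convenience wrapper: align on shared individuals and run 2SLS."""
    common = score.values.index.intersection(exposure_z.z.index).intersection(
        outcome_z.z.index
    )
    exog = None
    adjustment: list[str] = []
    if extra_covariates is not None:
        common = common.intersection(extra_covariates.dropna().index)
        exog = extra_covariates.loc[common].to_numpy(dtype=float)
        adjustment = list(extra_covariates.columns)
    model = IVRegression(
        outcome_z.z.loc[common],
        exposure_z.z.loc[common],
        score.values.loc[common],
        exog=exog,
        direction=direction,
        instrument_name=instrument,
        adjustment=adjustment,
    )
    return model.fit(cov_type=cov_type).as_iv_result()


def adjusted_iv(
    score: RiskScore,
    exposure_z: StandardizedPhenotype,
    outcome_z: StandardizedPhenotype,
    covariate_z: StandardizedPhenotype,
    direction: str = "bmi_to_t",
    instrument: str = "GRS",
) -> IVResult | None:
    """2SLS with an extra standardized covariate in both stages.

    Used for the SHBG-conditioned analyses: the effect of BMI on T given
    SHBG, and of BMI on SHBG given T.  Returns None (a logged skip) when the
    covariate is entirely missing.
    """
    if covariate_z.z.dropna().empty:
        import logging

        logging.getLogger(__name__).warning(
            "adjusted_iv skipped: covariate %s has no data", covariate_z.phenotype_name
        )
        return None
    frame = covariate_z.z.rename(covariate_z.phenotype_name).to_frame()
    result = tsls(
        score, exposure_z, outcome_z, frame, direction=direction, instrument=instrument
    )
    return result


def instrument_split(
    matrix: DosageMatrix,
    specs: Sequence[VariantSpec],
    partition: tuple[Sequence[str], Sequence[str]],
    exposure_z: StandardizedPhenotype,
    outcome_z: StandardizedPhenotype,
    direction: str = "bmi_to_t",
    weighted: bool = True,
) -> tuple[IVResult, IVResult, float]:
    """Two independent sub-instruments plus a consistency test.

    The pleiotropy check: partition the panel (e.g. the FTO SNP vs the
    remaining 96), estimate the causal effect with each sub-instrument
    independently, and z-test the difference.  Similar point estimates
    (difference p > 0.05) argue against instrument-specific pleiotropy.
    """
    left, right = (set(partition[0]), set(partition[1]))
    if not left or not right:
        raise ParameterError("both partition sides must be non-empty")
    if left & right:
        raise ParameterError("partition sides overlap")
    all_rsids = {s.rsid for s in specs}
    if left | right != all_rsids:
        raise ParameterError("partition must cover the variant spec list")
    results = []
    for side, label in ((left, "subset_1"), (right, "subset_2")):
        sub_specs = [s for s in specs if s.rsid in side]
        builder = weighted_score if weighted else unweighted_score
        score = builder(matrix, sub_specs)
        results.append(
            tsls(score, exposure_z, outcome_z, direction=direction,
                 instrument=f"{label} ({len(sub_specs)} SNPs)")
        )
    diff = results[0].ratio - results[1].ratio
    se_diff = math.sqrt(results[0].se ** 2 + results[1].se ** 2)
    p_diff = float(2.0 * stats.norm.sf(abs(diff) / se_diff))
    return results[0], results[1], p_diff


def obs_vs_iv(beta_obs: AssocResult, iv: IVResult) -> float:
    """Hausman-type test of observational vs IV estimate equality.

    z = (beta_obs - ratio) / sqrt(max(se_iv² - se_obs², floor)) with floor
    se_iv² * 1e-6; a non-positive variance difference beyond the floor is a
    boundary case reported with a warning and the floored variance.
    """
    var_diff = iv.se**2 - beta_obs.se**2
    floor = iv.se**2 * 1e-6
    if var_diff <= floor:
        warnings.warn(
            "observational SE is not smaller than the IV SE; Hausman variance "
            "floored",
            UserWarning,
            stacklevel=2,
        )
        var_diff = floor
    z = (beta_obs.beta - iv.ratio) / math.sqrt(var_diff)
    p = min(2.0 * stats.norm.sf(abs(z)), 1.0)
    return float(max(p, np.finfo(float).tiny))


@dataclasses.dataclass
class TranslationResult:
    """A causal SD/SD ratio re-expressed as a % change in testosterone for a
    stated BMI change."""

    percent_change: float
    ci_low_percent: float | None
    ci_high_percent: float | None
    bmi_from: float
    bmi_to: float
    sd_t: float
    sd_logbmi: float
    t_pred_at_from: float


def translate_to_percent(
    iv: IVResult | float,
    sd_t: float,
    sd_logbmi: float,
    t_pred_at_from: float,
    bmi_from: float = 30.0,
    bmi_to: float = 25.0,
) -> TranslationResult:
    """Chain the IV ratio into a percent change of serum T for a BMI change.

    percent = 100 * ratio * (SD(T)/SD(ln BMI)) * (ln(bmi_to) - ln(bmi_from))
                  / T_pred(bmi_from)

    i.e. convert the SD/SD ratio to T units per unit ln BMI, multiply by the
    log-BMI change, and express relative to the predicted T at the starting
    BMI.  Exact chained arithmetic, no approximation.
    """
    if sd_t <= 0 or sd_logbmi <= 0 or t_pred_at_from <= 0:
        raise ParameterError("SDs and predicted T must be positive")
    if bmi_from <= 0 or bmi_to <= 0:
        raise ParameterError("BMI values must be positive")
    log_change = math.log(bmi_to) - math.log(bmi_from)
    factor = 100.0 * (sd_t / sd_logbmi) * log_change / t_pred_at_from

    if isinstance(iv, IVResult):
        ratio = iv.ratio
        bounds = sorted((iv.ci_low * factor, iv.ci_high * factor))
        ci_low, ci_high = bounds
    else:
        ratio = float(iv)
        ci_low = ci_high = None
    return TranslationResult(
        percent_change=ratio * factor,
        ci_low_percent=ci_low,
        ci_high_percent=ci_high,
        bmi_from=bmi_from,
        bmi_to=bmi_to,
        sd_t=sd_t,
        sd_logbmi=sd_logbmi,
        t_pred_at_from=t_pred_at_from,
    )


def predicted_t_at_bmi(
    tables: Sequence, bmi_value: float = 30.0
) -> float:
    """Predicted native-scale T at a given BMI from the pooled OLS of T on
    ln BMI plus age/smoking/sampling-time/cohort at their sample means."""
    import statsmodels.api as sm

    frames = []
    for table in tables:
        frame = table.data[["bmi", "testosterone", "age", "smoking", "sampling_time"]].copy()
        frame["cohort"] = table.cohort
        frames.append(frame)
    pooled = pd.concat(frames).dropna()
    design = pd.get_dummies(
        pooled[["age", "smoking", "sampling_time", "cohort"]],
        columns=["cohort"],
        drop_first=True,
        dtype=float,
    )
    design.insert(0, "ln_bmi", np.log(pooled["bmi"]))
    design = sm.add_constant(design)
    fit = sm.OLS(pooled["testosterone"].to_numpy(), design.to_numpy()).fit()
    at_means = design.mean(axis=0).to_numpy().copy()
    at_means[1] = math.log(bmi_value)
    value = float(at_means @ fit.params)
    if value <= 0:
        raise DataError("predicted T at the requested BMI is non-positive")
    return value
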