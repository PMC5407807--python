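"""Covariate-adjusted Z-scores — the working scale of every analysis here.

BMI is right-skewed and is natural-log transformed before standardization;
total testosterone and SHBG are standardized on their native scale.  A
standardized phenotype is the OLS residual of the (transformed) trait on its
adjustment set — age, smoking and, for hormone outcomes, time of blood
sampling, with cohort/site entered as categorical indicators — divided by the
residual SD, so it has mean 0 and SD 1 and is exactly orthogonal to every
adjustment covariate.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DegenerateFitError, ParameterError

TRANSFORMS = ("none", "natural_log")


@dataclasses.dataclass
class StandardizedPhenotype:
    """Unit-variance standardized residuals of one phenotype."""

    z: pd.Series
    phenotype_name: str
    adjustment_set: list[str]
    transform: str

    @property
    def individual_ids(self) -> pd.Index:
        return self.z.index


def ln_bmi(
    bmi: pd.Series | np.ndarray, diagnostic: bool = False
) -> np.ndarray | tuple[np.ndarray, tuple[float, float]]:
    """Natural-log transform BMI; optionally report a Shapiro-Wilk diagnostic.

    The Shapiro-Wilk statistic is computed on the raw input (subsampled to
    5000 values, the test's reliable range) and is reported only — it gates
    nothing.
    """
    values = np.asarray(bmi, dtype=float)
    if np.any(values <= 0):
        raise DataError("BMI must be strictly positive")
    transformed = np.log(values)
    if not diagnostic:
        return transformed
    sample = values
    if sample.size > 5000:
        rng = np.random.default_rng(0)
        sample = rng.choice(sample, size=5000, replace=False)
    w_stat, p_value = stats.shapiro(sample)
    return transformed, (float(w_stat), float(p_value))


def _design_matrix(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    expanded = pd.get_dummies(covariates, drop_first=True, dtype=float)
    names = list(expanded.columns)
    design = np.column_stack([np.ones(len(expanded)), expanded.to_numpy(dtype=float)])
    return design, names


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    suspects = []
    for j in range(1, design.shape[1]):
        others = np.delete(design, j, axis=1)
        fitted = others @ np.linalg.lstsq(others, design[:, j], rcond=None)[0]
        residual = design[:, j] - fitted
        if np.sum(residual**2) < 1e-10 * max(np.sum(design[:, j] ** 2), 1.0):
            suspects.append(names[j - 1])
    return suspects


def standardize(
    values: pd.Series,
    covariates: pd.DataFrame | None = None,
    adjustment_set: Sequence[str] = (),
    transform: str = "none",
    name: str = "phenotype",
) -> StandardizedPhenotype:
    """Residualize a phenotype on its adjustment set and scale to unit SD.

    Complete-case: individuals missing the phenotype or any adjustment
    covariate are dropped.  Categorical covariates (e.g. cohort/site) become
    indicator columns.  An empty adjustment set reduces to the plain Z-score.
    """
    if transform not in TRANSFORMS:
        raise ParameterError(f"transform must be one of {TRANSFORMS}")
    adjustment = list(adjustment_set)
    y = pd.Series(values).astype(float)
    if adjustment:
        if covariates is None:
            raise ParameterError("adjustment requested but no covariates supplied")
        missing = set(adjustment) - set(covariates.columns)
        if missing:
            raise ParameterError(f"adjustment covariates not present: {sorted(missing)}")
        frame = covariates.loc[y.index, adjustment]
        keep = y.notna() & frame.notna().all(axis=1)
    else:
        keep = y.notna()
    y = y[keep]
    n = len(y)
    if n <= len(adjustment) + 2:
        raise ParameterError("too few complete cases for the adjustment set")
    if transform == "natural_log":
        y = pd.Series(ln_bmi(y), index=y.index)

    if adjustment:
        design, names = _design_matrix(frame[keep])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            raise DegenerateFitError(
                "rank-deficient adjustment set; collinear columns: "
                f"{_collinear_columns(design, names)}"
            )
        coefficients, *_ = np.linalg.lstsq(design, y.to_numpy(), rcond=None)
        residuals = y.to_numpy() - design @ coefficients
    else:
        residuals = y.to_numpy() - y.mean()

    sd = float(np.sqrt(np.mean(residuals**2)))
    if sd < 1e-10 * max(float(np.std(y)), 1.0) or sd == 0.0:
        raise DegenerateFitError(
            f"{name}: residual variance is (numerically) zero after adjustment"
        )
    z = pd.Series(residuals / sd, index=y.index)
    return StandardizedPhenotype(z, name, adjustment, transform)


def write_standardized_tsv(phenotype: StandardizedPhenotype, path) -> None:
    with open(path, "w") as handle:
        handle.write(
            f"# phenotype={phenotype.phenotype_name} "
            f"transform={phenotype.transform} "
            f"adjustment={','.join(phenotype.adjustment_set) or 'none'}\n"
        )
        phenotype.z.rename("z").to_csv(handle, sep="\t", index_label="individual_id")
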