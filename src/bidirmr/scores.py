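"""Genetic risk scores: allele harmonization, weighted/unweighted sums.

A score is a per-individual sum of trait-increasing (BMI) or trait-decreasing
(testosterone) allele dosages, optionally weighted by published per-allele
effect sizes.  Harmonization re-orients every dosage column so it counts the
weight table's effect allele before any score is formed.

Scale convention: the weighted score is multiplied by ``M / sum(w)`` by
default (``M`` = number of contributing variants), which puts it on the
allele-count scale of the unweighted score — the convention that reproduces
the published cohort means (~89 weighted vs ~91 unweighted for 97 SNPs).  IV
estimates are invariant to any positive linear rescaling of the instrument,
so the choice is cosmetic; the raw ``sum(w*g)`` is available with
``rescale=False``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import DosageMatrix, VariantSpec, X_MALE
from .errors import DataError, ParameterError

MISSING_POLICIES = ("impute_eaf", "omit")
ABSENT_POLICIES = ("omit", "rescale")


@dataclasses.dataclass
class RiskScore:
    """A per-individual genetic risk score."""

    values: pd.Series
    weighted: bool
    n_variants_used: pd.Series
    scale_note: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise DataError("risk score contains non-finite values")

    @property
    def individual_ids(self) -> pd.Index:
        return self.values.index


def harmonize(matrix: DosageMatrix, specs: Sequence[VariantSpec]) -> DosageMatrix:
    """Re-orient every variant to count the spec's effect allele.

    Columns counted on the other allele are complemented (``2 - g``
    autosomal, ``1 - g`` for the male X variant).  Idempotent; a counted
    allele matching neither spec allele is a data error naming the variant.
    """
    by_rsid = {s.rsid: s for s in specs}
    out = matrix.copy()
    for rsid in out.variant_ids:
        spec = by_rsid.get(rsid)
        if spec is None:
            continue
        counted = out.counted_allele[rsid]
        if counted == spec.effect_allele:
            continue
        if counted == spec.other_allele:
            out.dosages[rsid] = spec.ploidy - out.dosages[rsid]
            out.counted_allele[rsid] = spec.effect_allele
        else:
            raise DataError(
                f"{rsid}: counted allele {counted!r} matches neither "
                f"{spec.effect_allele!r} nor {spec.other_allele!r}"
            )
    return out


def _check_harmonized(matrix: DosageMatrix, specs: Sequence[VariantSpec]) -> list[VariantSpec]:
    present = []
    for spec in specs:
        if spec.rsid not in matrix.dosages.columns:
            continue
        if matrix.counted_allele[spec.rsid] != spec.effect_allele:
            raise DataError(
                f"{spec.rsid}: matrix is not harmonized (counts "
                f"{matrix.counted_allele[spec.rsid]!r}, expected {spec.effect_allele!r})"
            )
        present.append(spec)
    if not present:
        raise ParameterError("no spec variant present in the dosage matrix")
    return present


def _score(
    matrix: DosageMatrix,
    specs: Sequence[VariantSpec],
    weights: np.ndarray | None,
    missing_policy: str,
    absent_policy: str,
    x_dosage_scale: float,
    total_variants: int,
) -> tuple[pd.Series, pd.Series]:
    present = _check_harmonized(matrix, specs)
    rsids = [s.rsid for s in present]
    values = matrix.dosages[rsids].to_numpy(dtype=float)
    scale = np.array(
        [x_dosage_scale if s.chrom_class == X_MALE else 1.0 for s in present]
    )
    values = values * scale[None, :]
    mean_dosage = np.array([s.mean_dosage for s in present]) * scale
    nan_mask = np.isnan(values)
    if missing_policy == "impute_eaf":
        values = np.where(nan_mask, mean_dosage[None, :], values)
        used = np.full(len(values), len(present))
    elif missing_policy == "omit":
        values = np.where(nan_mask, 0.0, values)
        used = len(present) - nan_mask.sum(axis=1)
    else:
        raise ParameterError(f"missing_policy must be one of {MISSING_POLICIES}")
    if weights is None:
        raw = values.sum(axis=1)
    else:
        raw = values @ weights
    if absent_policy == "rescale" and len(present) < total_variants:
        raw = raw * (total_variants / len(present))
    elif absent_policy not in ABSENT_POLICIES:
        raise ParameterError(f"absent_policy must be one of {ABSENT_POLICIES}")
    index = matrix.individual_ids
    return pd.Series(raw, index=index), pd.Series(used, index=index)


def unweighted_score(
    matrix: DosageMatrix,
    specs: Sequence[VariantSpec],
    missing_policy: str = "impute_eaf",
    absent_policy: str = "omit",
    x_dosage_scale: float = 1.0,
) -> RiskScore:
    """Sum of harmonized effect-allele dosages.

    ``missing_policy="impute_eaf"`` (default) replaces a sporadically missing
    entry by its expected dosage ``ploidy * eaf`` (unbiased under MCAR);
    ``"omit"`` contributes 0 and records the per-individual shortfall in
    ``n_variants_used``.  ``absent_policy`` governs variants missing from the
    whole cohort (the 96-of-97-SNP situation): ``"omit"`` (default, matching
    the published cohort-mean offset) or ``"rescale"`` (score * M_total/M_present).
    """
    if not specs:
        raise ParameterError("empty variant spec list")
    values, used = _score(
        matrix, specs, None, missing_policy, absent_policy, x_dosage_scale, len(specs)
    )
    return RiskScore(values, False, used, "allele-count scale (unweighted sum)")


def weighted_score(
    matrix: DosageMatrix,
    specs: Sequence[VariantSpec],
    rescale: bool = True,
    missing_policy: str = "impute_eaf",
    absent_policy: str = "omit",
    x_dosage_scale: float = 1.0,
) -> RiskScore:
    """Weighted sum ``sum_i w_i g_i`` of harmonized dosages.

    With ``rescale=True`` the sum is multiplied by ``M / sum_i w_i`` over the
    contributing variants, putting the score on the allele-count scale.
    """
    if not specs:
        raise ParameterError("empty variant spec list")
    present = _check_harmonized(matrix, specs)
    weights = np.array([s.weight for s in present])
    if np.all(weights == 0):
        raise ParameterError("all variant weights are zero")
    values, used = _score(
        matrix, present, weights, missing_policy, absent_policy, x_dosage_scale,
        len(specs),
    )
    if rescale:
        factor = len(present) / float(weights.sum())
        values = values * factor
        note = "allele-count scale (weighted, rescaled by M/sum(w))"
    else:
        note = "raw weighted scale (sum of w*g)"
    return RiskScore(values, True, used, note)


def write_scores_tsv(score: RiskScore, path: str | Path) -> None:
    frame = pd.DataFrame(
        {"score": score.values, "n_variants_used": score.n_variants_used}
    )
    frame.to_csv(path, sep="\t", index_label="individual_id")
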