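"""End-to-end bidirectional MR study: the package's model/results surface.

:class:`MRStudy` is built from multi-cohort data (or simulated via
``from_simulation``); ``fit()`` runs the full analysis in the study's order —
score construction, instrument validation, observational estimates (per
cohort, meta-analytic and pooled), IV estimation in both directions,
SHBG-conditioned variants, the independent-instrument pleiotropy split, the
clinical-units translation (BMI 30 -> 25 kg/m² as % change in T) and the
analytic power section — and returns an :class:`MRStudyResults` whose
``summary()`` renders the whole analysis and whose ``to_tables()`` writes
every table as TSV plus a JSON manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .data import (
    CohortTable,
    DosageMatrix,
    TRAIT_BMI,
    TRAIT_T,
    VariantSpec,
)
from .diagnostics import (
    AssocResult,
    DiagnosticsReport,
    associate,
    confounder_balance,
    f_statistic,
    interaction_test,
    nonlinearity_test,
    per_snp_scan,
)
from .errors import ConfigurationError
from .estimation import (
    IVResult,
    adjusted_iv,
    instrument_split,
    obs_vs_iv,
    predicted_t_at_bmi,
    translate_to_percent,
    tsls,
    TranslationResult,
    UNIT_LABELS,
)
from .meta import (
    MetaResult,
    meta_to_frame,
    model_select,
    pooled_scores,
    pooled_standardized,
)
from .power import half_effect_power, iv_power, PowerResult
from .scores import RiskScore, harmonize, unweighted_score, weighted_score
from .simulate import SimulatedStudy, StructuralParams, simulate_study
from .standardize import StandardizedPhenotype, standardize

logger = logging.getLogger(__name__)

SCORE_KEYS = ("wGRS_BMI", "uwGRS_BMI", "wGRS_T", "uwGRS_T")


@dataclasses.dataclass
class _CohortBundle:
    """Per-cohort working objects: harmonized dosages, scores, Z-scores."""

    matrix: DosageMatrix
    table: CohortTable
    scores: dict[str, RiskScore]
    z_bmi: StandardizedPhenotype
    z_t: StandardizedPhenotype
    z_shbg: StandardizedPhenotype | None


class MRStudy:
    """Bidirectional Mendelian-randomization study of BMI and testosterone.

    Parameters
    ----------
    cohorts : sequence of (DosageMatrix, CohortTable)
    specs : the instrument panel (BMI-increasing and T-decreasing variants)
    alpha : two-sided significance level for tests and the meta model choice
    seed : recorded in the manifest; the analysis itself is deterministic
    """

    def __init__(
        self,
        cohorts: Sequence[tuple[DosageMatrix, CohortTable]],
        specs: Sequence[VariantSpec],
        alpha: float = 0.05,
        seed: int | None = None,
        config: dict | None = None,
    ):
        if not cohorts:
            raise ConfigurationError("at least one cohort is required")
        self.cohorts = list(cohorts)
        self.specs = list(specs)
        self.alpha = alpha
        self.seed = seed
        self.config = config or {}
        self.bmi_specs = [s for s in self.specs if s.trait == TRAIT_BMI]
        self.t_specs = [s for s in self.specs if s.trait == TRAIT_T]
        if not self.bmi_specs or not self.t_specs:
            raise ConfigurationError("both BMI and T instrument panels are required")

    @classmethod
    def from_simulation(
        cls,
        params: StructuralParams | None = None,
        seed: int | None = None,
        n_bmi: int = 97,
        n_t: int = 3,
        alpha: float = 0.05,
    ) -> "MRStudy":
        """Simulate the five-cohort design and wrap it as a study."""
        params = params or StructuralParams()
        if seed is not None:
            params = dataclasses.replace(params, seed=seed)
        sim: SimulatedStudy = simulate_study(params, n_bmi=n_bmi, n_t=n_t)
        return cls(
            sim.cohorts,
            sim.specs,
            alpha=alpha,
            seed=params.seed,
            config={"simulation": dataclasses.asdict(params)},
        )

    # -- per-cohort working objects -------------------------------------

    def _bundle(self, matrix: DosageMatrix, table: CohortTable) -> _CohortBundle:
        matrix = harmonize(matrix, self.specs)
        scores = {
            "wGRS_BMI": weighted_score(matrix, self.bmi_specs),
            "uwGRS_BMI": unweighted_score(matrix, self.bmi_specs),
            "wGRS_T": weighted_score(matrix, self.t_specs),
            "uwGRS_T": unweighted_score(matrix, self.t_specs),
        }
        z_bmi = standardize(
            table.data["bmi"], table.data, ["age", "smoking"], "natural_log", "ln_bmi"
        )
        adjust_t = ["age", "smoking"]
        if "sampling_time" in table.data.columns:
            adjust_t.append("sampling_time")
        z_t = standardize(
            table.data["testosterone"], table.data, adjust_t, "none", "testosterone"
        )
        z_shbg = None
        if "shbg" in table.data.columns and table.data["shbg"].notna().any():
            z_shbg = standardize(table.data["shbg"], table.data, adjust_t, "none", "shbg")
        return _CohortBundle(matrix, table, scores, z_bmi, z_t, z_shbg)

    # -- main entry ------------------------------------------------------

    def fit(self) -> "MRStudyResults":
        bundles = {
            table.cohort: self._bundle(matrix, table)
            for matrix, table in self.cohorts
        }
        tables = [table for _, table in self.cohorts]

        score_summary = self._score_summary(bundles)
        z_bmi_pool = pooled_standardized(self.cohorts, "bmi", ["age", "smoking"], "natural_log")
        z_t_pool = pooled_standardized(
            self.cohorts, "testosterone", ["age", "smoking", "sampling_time"]
        )
        z_shbg_pool = pooled_standardized(
            self.cohorts, "shbg", ["age", "smoking", "sampling_time"]
        ) if all("shbg" in t.data.columns for t in tables) else None

        pooled_score = {
            "wGRS_BMI": pooled_scores(self.cohorts, self.bmi_specs, weighted=True),
            "uwGRS_BMI": pooled_scores(self.cohorts, self.bmi_specs, weighted=False),
            "wGRS_T": pooled_scores(self.cohorts, self.t_specs, weighted=True),
            "uwGRS_T": pooled_scores(self.cohorts, self.t_specs, weighted=False),
        }
        exposure_of = {
            "wGRS_BMI": z_bmi_pool, "uwGRS_BMI": z_bmi_pool,
            "wGRS_T": z_t_pool, "uwGRS_T": z_t_pool,
        }
        outcome_of = {
            "wGRS_BMI": z_t_pool, "uwGRS_BMI": z_t_pool,
            "wGRS_T": z_bmi_pool, "uwGRS_T": z_bmi_pool,
        }
        direction_of = {
            "wGRS_BMI": "bmi_to_t", "uwGRS_BMI": "bmi_to_t",
            "wGRS_T": "t_to_bmi", "uwGRS_T": "t_to_bmi",
        }

        diagnostics = self._diagnostics(bundles, pooled_score, exposure_of)

        observational = self._observational(bundles)

        iv_per_cohort, iv_meta, iv_pooled, table2 = self._iv_section(
            bundles, pooled_score, exposure_of, outcome_of, direction_of
        )

        shbg_adjusted = {}
        if z_shbg_pool is not None:
            shbg_adjusted["t_given_shbg"] = adjusted_iv(
                pooled_score["wGRS_BMI"], z_bmi_pool, z_t_pool, z_shbg_pool,
                direction="bmi_to_t", instrument="wGRS_BMI | SHBG",
            )
            shbg_adjusted["shbg_given_t"] = adjusted_iv(
                pooled_score["wGRS_BMI"], z_bmi_pool, z_shbg_pool, z_t_pool,
                direction="bmi_to_t", instrument="wGRS_BMI -> SHBG | T",
            )
        else:
            logger.warning("SHBG column absent in some cohort; adjusted IV skipped")

        split = self._split(bundles, z_bmi_pool, z_t_pool)

        translation = self._translation(tables, z_bmi_pool, iv_pooled)

        power = self._power_section(observational, diagnostics)

        obs_vs_iv_p = {
            key: obs_vs_iv(observational["pooled"], iv_pooled[key])
            for key in ("wGRS_BMI", "uwGRS_BMI")
        }

        manifest = self._manifest()
        return MRStudyResults(
            study=self,
            score_summary=score_summary,
            diagnostics=diagnostics,
            observational=observational,
            iv_per_cohort=iv_per_cohort,
            iv_meta=iv_meta,
            iv_pooled=iv_pooled,
            table2=table2,
            shbg_adjusted=shbg_adjusted,
            split=split,
            translation=translation,
            power=power,
            obs_vs_iv_p=obs_vs_iv_p,
            manifest=manifest,
        )

    # -- sections --------------------------------------------------------

    def _score_summary(self, bundles) -> pd.DataFrame:
        rows = []
        for name, bundle in bundles.items():
            row = {"cohort": name, "n": bundle.table.n}
            for key in SCORE_KEYS:
                values = bundle.scores[key].values
                row[f"{key}_mean"] = float(values.mean())
                row[f"{key}_sd"] = float(values.std(ddof=1))
            for pheno in ("bmi", "testosterone", "shbg", "age"):
                if pheno in bundle.table.data.columns:
                    row[f"{pheno}_mean"] = float(bundle.table.data[pheno].mean())
                    row[f"{pheno}_sd"] = float(bundle.table.data[pheno].std(ddof=1))
            rows.append(row)
        return pd.DataFrame(rows)

    def _diagnostics(self, bundles, pooled_score, exposure_of) -> dict[str, DiagnosticsReport]:
        pooled_cov = pd.concat(
            [b.table.data[["age", "smoking"]] for b in bundles.values()]
        )
        pooled_age = pooled_cov["age"]
        reports = {}
        for key in SCORE_KEYS:
            score = pooled_score[key]
            z_exposure = exposure_of[key]
            assoc = associate(score, z_exposure)
            report = DiagnosticsReport(
                instrument=key,
                assoc=assoc,
                f_stat=f_statistic(assoc.r2, assoc.n),
                confounder_pvals=confounder_balance(score, pooled_cov),
                interaction_pvals={
                    "age": interaction_test(score, z_exposure, pooled_age, "age")
                },
                quadratic_p=nonlinearity_test(score, z_exposure),
            )
            if key == "wGRS_BMI":
                matrix_all = pd.concat([b.matrix.dosages for b in bundles.values()])
                counted = {}
                chrom = {}
                for b in bundles.values():
                    counted.update(b.matrix.counted_allele)
                    chrom.update(b.matrix.chrom_class)
                pooled_matrix = DosageMatrix(matrix_all, counted, chrom)
                report.per_snp = per_snp_scan(
                    pooled_matrix, self.bmi_specs, z_exposure, self.alpha
                )
            if key == "wGRS_T":
                matrix_all = pd.concat([b.matrix.dosages for b in bundles.values()])
                counted = {}
                chrom = {}
                for b in bundles.values():
                    counted.update(b.matrix.counted_allele)
                    chrom.update(b.matrix.chrom_class)
                pooled_matrix = DosageMatrix(matrix_all, counted, chrom)
                report.per_snp = per_snp_scan(
                    pooled_matrix, self.t_specs, exposure_of["wGRS_T"], self.alpha
                )
            reports[key] = report
        return reports

    def _observational(self, bundles) -> dict:
        per_cohort: dict[str, AssocResult] = {}
        for name, bundle in bundles.items():
            x = bundle.z_bmi.z
            y = bundle.z_t.z
            common = x.index.intersection(y.index)
            from scipy import stats as _stats

            fit = _stats.linregress(x.loc[common].to_numpy(), y.loc[common].to_numpy())
            per_cohort[name] = AssocResult(
                float(fit.slope), float(fit.stderr), float(max(fit.pvalue, 1e-300)),
                float(fit.rvalue**2), len(common),
            )
        combined = model_select(
            [a.beta for a in per_cohort.values()],
            [a.se for a in per_cohort.values()],
            alpha=self.alpha,
        ) if len(per_cohort) > 1 else None
        # pooled observational: outcome z on exposure z, cohort-adjusted
        z_bmi = pooled_standardized(self.cohorts, "bmi", ["age", "smoking"], "natural_log")
        z_t = pooled_standardized(
            self.cohorts, "testosterone", ["age", "smoking", "sampling_time"]
        )
        from scipy import stats as _stats

        common = z_bmi.z.index.intersection(z_t.z.index)
        fit = _stats.linregress(
            z_bmi.z.loc[common].to_numpy(), z_t.z.loc[common].to_numpy()
        )
        pooled = AssocResult(
            float(fit.slope), float(fit.stderr), float(max(fit.pvalue, 1e-300)),
            float(fit.rvalue**2), len(common),
        )
        return {"per_cohort": per_cohort, "meta": combined, "pooled": pooled}

    def _iv_section(self, bundles, pooled_score, exposure_of, outcome_of, direction_of):
        iv_per_cohort: dict[str, dict[str, IVResult]] = {k: {} for k in SCORE_KEYS}
        for name, bundle in bundles.items():
            for key in SCORE_KEYS:
                direction = direction_of[key]
                exposure = bundle.z_bmi if direction == "bmi_to_t" else bundle.z_t
                outcome = bundle.z_t if direction == "bmi_to_t" else bundle.z_bmi
                try:
                    iv_per_cohort[key][name] = tsls(
                        bundle.scores[key], exposure, outcome,
                        direction=direction, instrument=key,
                    )
                except Exception as exc:  # cohort too small / weak: recorded, not fatal
                    logger.warning("cohort %s, %s: IV skipped (%s)", name, key, exc)
        iv_meta: dict[str, MetaResult | None] = {}
        for key in SCORE_KEYS:
            entries = iv_per_cohort[key]
            iv_meta[key] = model_select(
                [r.ratio for r in entries.values()],
                [r.se for r in entries.values()],
                alpha=self.alpha,
            ) if len(entries) > 1 else None

        iv_pooled: dict[str, IVResult] = {}
        table2_rows = []
        for key in SCORE_KEYS:
            direction = direction_of[key]
            score = pooled_score[key]
            assoc_exp = associate(score, exposure_of[key])
            assoc_out = associate(score, outcome_of[key])
            iv = tsls(
                score, exposure_of[key], outcome_of[key],
                direction=direction, instrument=key,
            )
            iv_pooled[key] = iv
            table2_rows.append(
                {
                    "instrument": key,
                    "coef_intermediate": assoc_exp.beta,
                    "coef_intermediate_ci_low": assoc_exp.ci[0],
                    "coef_intermediate_ci_high": assoc_exp.ci[1],
                    "coef_outcome": assoc_out.beta,
                    "coef_outcome_ci_low": assoc_out.ci[0],
                    "coef_outcome_ci_high": assoc_out.ci[1],
                    "iv_ratio": iv.ratio,
                    "iv_ci_low": iv.ci_low,
                    "iv_ci_high": iv.ci_high,
                    "iv_p": iv.p,
                    "units": UNIT_LABELS[direction],
                }
            )
        return iv_per_cohort, iv_meta, iv_pooled, pd.DataFrame(table2_rows)

    def _split(self, bundles, z_bmi_pool, z_t_pool):
        first = self.bmi_specs[0].rsid
        rest = [s.rsid for s in self.bmi_specs[1:]]
        if not rest:
            return None
        matrix_all = pd.concat([b.matrix.dosages for b in bundles.values()])
        counted = {}
        chrom = {}
        for b in bundles.values():
            counted.update(b.matrix.counted_allele)
            chrom.update(b.matrix.chrom_class)
        pooled_matrix = DosageMatrix(matrix_all, counted, chrom)
        try:
            return instrument_split(
                pooled_matrix, self.bmi_specs, ([first], rest), z_bmi_pool, z_t_pool,
            )
        except Exception as exc:
            logger.warning("instrument split skipped (%s)", exc)
            return None

    def _translation(self, tables, z_bmi_pool, iv_pooled) -> dict[str, TranslationResult]:
        pooled_t = pd.concat([t.data["testosterone"] for t in tables])
        pooled_lnbmi = np.log(pd.concat([t.data["bmi"] for t in tables]))
        sd_t = float(pooled_t.std(ddof=1))
        sd_logbmi = float(pooled_lnbmi.std(ddof=1))
        t_pred = predicted_t_at_bmi(tables, 30.0)
        return {
            key: translate_to_percent(iv_pooled[key], sd_t, sd_logbmi, t_pred)
            for key in ("wGRS_BMI", "uwGRS_BMI")
        }

    def _power_section(self, observational, diagnostics) -> dict[str, PowerResult]:
        beta_obs = abs(observational["pooled"].beta)
        n = observational["pooled"].n
        section = {}
        for key, r2_key in (("wGRS_BMI", "wGRS_BMI"), ("wGRS_T", "wGRS_T")):
            r2 = diagnostics[r2_key].assoc.r2
            section[f"{key}_full"] = iv_power(n, r2, beta_obs, self.alpha)
            section[f"{key}_half"] = half_effect_power(n, r2, beta_obs, self.alpha)
        return section

    def _manifest(self) -> dict:
        config_text = json.dumps(self.config, sort_keys=True, default=str)
        return {
            "package": "bidirmr",
            "version": __version__,
            "seed": self.seed,
            "alpha": self.alpha,
            "n_total": sum(t.n for _, t in self.cohorts),
            "n_variants": len(self.specs),
            "cohorts": [t.cohort for _, t in self.cohorts],
            "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        }


@dataclasses.dataclass
class MRStudyResults:
    """Everything the fitted study reports."""

    study: MRStudy
    score_summary: pd.DataFrame
    diagnostics: dict[str, DiagnosticsReport]
    observational: dict
    iv_per_cohort: dict[str, dict[str, IVResult]]
    iv_meta: dict[str, MetaResult | None]
    iv_pooled: dict[str, IVResult]
    table2: pd.DataFrame
    shbg_adjusted: dict[str, IVResult | None]
    split: tuple[IVResult, IVResult, float] | None
    translation: dict[str, TranslationResult]
    power: dict[str, PowerResult]
    obs_vs_iv_p: dict[str, float]
    manifest: dict

    # -- rendering -------------------------------------------------------

    def summary(self) -> str:
        obs = self.observational
        lines = [
            "Bidirectional Mendelian randomization: BMI and serum testosterone",
            "=" * 66,
            f"cohorts: {', '.join(self.manifest['cohorts'])} "
            f"(n = {self.manifest['n_total']})",
            f"instruments: {len(self.study.bmi_specs)} BMI SNPs, "
            f"{len(self.study.t_specs)} T SNPs",
            "",
            "Observational (SD T per SD ln BMI, adjusted):",
            f"  pooled: {obs['pooled'].beta:.3f} "
            f"(SE {obs['pooled'].se:.3f}, p {obs['pooled'].p:.2g})",
        ]
        if obs["meta"] is not None:
            meta = obs["meta"]
            lines.append(
                f"  meta ({meta.model}): {meta.pooled_beta:.3f} "
                f"[{meta.ci_low:.3f}, {meta.ci_high:.3f}], I²={meta.i_squared:.0f}%"
            )
        lines.append("")
        lines.append("Instrument validation (pooled):")
        for key, report in self.diagnostics.items():
            lines.append(
                f"  {key}: R²={100 * report.assoc.r2:.2f}%, F={report.f_stat:.0f}, "
                f"p={report.assoc.p:.2g}"
            )
        lines.append("")
        lines.append("IV estimates (pooled 2SLS):")
        for key, iv in self.iv_pooled.items():
            lines.append(
                f"  {key}: {iv.ratio:.3f} [{iv.ci_low:.3f}, {iv.ci_high:.3f}] "
                f"p={iv.p:.2g}  ({iv.units})"
            )
        for key, p in self.obs_vs_iv_p.items():
            lines.append(f"  observational vs IV ({key}): p = {p:.2f}")
        if self.shbg_adjusted.get("t_given_shbg") is not None:
            iv = self.shbg_adjusted["t_given_shbg"]
            lines.append(
                f"  BMI->T | SHBG: {iv.ratio:.3f} [{iv.ci_low:.3f}, {iv.ci_high:.3f}] "
                f"p={iv.p:.2g}"
            )
        if self.split is not None:
            left, right, p_diff = self.split
            lines.append(
                f"  instrument split: {left.ratio:.3f} vs {right.ratio:.3f} "
                f"(difference p = {p_diff:.2f})"
            )
        lines.append("")
        lines.append("BMI 30 -> 25 kg/m² translation (% change in serum T):")
        for key, tr in self.translation.items():
            lines.append(
                f"  {key}: {tr.percent_change:+.1f}% "
                f"[{tr.ci_low_percent:+.1f}%, {tr.ci_high_percent:+.1f}%]"
            )
        lines.append("")
        lines.append("Analytic power at the observed association size:")
        for key, pw in self.power.items():
            lines.append(
                f"  {key}: {100 * pw.power:.0f}% "
                f"(n={pw.n}, R²={100 * pw.r2_instrument:.2f}%, |beta|={abs(pw.beta_true):.2f})"
            )
        return "\n".join(lines)

    def to_tables(self, outdir: str | Path) -> None:
        """Write every section as TSV plus the manifest and text report."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.score_summary.to_csv(outdir / "score_summary.tsv", sep="\t", index=False)
        pd.concat([r.to_frame() for r in self.diagnostics.values()]).to_csv(
            outdir / "diagnostics.tsv", sep="\t", index=False
        )
        self.table2.to_csv(outdir / "iv_coefficients.tsv", sep="\t", index=False)
        obs = self.observational
        per_study = {k: (a.beta, a.se) for k, a in obs["per_cohort"].items()}
        if obs["meta"] is not None:
            meta_to_frame(per_study, obs["meta"]).to_csv(
                outdir / "observational_forest.tsv", sep="\t", index=False
            )
        for key, meta in self.iv_meta.items():
            if meta is None:
                continue
            per_study = {
                k: (r.ratio, r.se) for k, r in self.iv_per_cohort[key].items()
            }
            meta_to_frame(per_study, meta).to_csv(
                outdir / f"iv_forest_{key}.tsv", sep="\t", index=False
            )
        translation_rows = [
            {
                "instrument": key,
                "percent_change": tr.percent_change,
                "ci_low": tr.ci_low_percent,
                "ci_high": tr.ci_high_percent,
                "sd_t": tr.sd_t,
                "sd_logbmi": tr.sd_logbmi,
                "t_pred_at_bmi30": tr.t_pred_at_from,
            }
            for key, tr in self.translation.items()
        ]
        pd.DataFrame(translation_rows).to_csv(
            outdir / "translation.tsv", sep="\t", index=False
        )
        power_rows = [
            {
                "scenario": key,
                "power": pw.power,
                "n": pw.n,
                "r2": pw.r2_instrument,
                "beta": pw.beta_true,
                "alpha": pw.alpha,
            }
            for key, pw in self.power.items()
        ]
        pd.DataFrame(power_rows).to_csv(outdir / "power.tsv", sep="\t", index=False)
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        (outdir / "report.txt").write_text(self.summary() + "\n")

    def forest_plot(self, which: str = "observational", ax=None):
        """Forest plot of per-cohort and combined estimates (observational or
        an IV instrument key)."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if which == "observational":
            per = {
                k: (a.beta, a.se)
                for k, a in self.observational["per_cohort"].items()
            }
            combined = self.observational["meta"]
            title = "Observational: SD T per SD ln BMI"
        else:
            per = {k: (r.ratio, r.se) for k, r in self.iv_per_cohort[which].items()}
            combined = self.iv_meta[which]
            title = f"IV ({which})"
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.6 * (len(per) + 2)))
        labels = list(per)
        z975 = 1.959963984540054
        for i, label in enumerate(labels):
            beta, se = per[label]
            ax.errorbar(beta, i, xerr=z975 * se, fmt="s", color="k", capsize=3)
        if combined is not None:
            ax.errorbar(
                combined.pooled_beta, len(labels),
                xerr=z975 * combined.se, fmt="D", color="firebrick", capsize=3,
            )
            labels = labels + [f"combined ({combined.model})"]
        ax.axvline(0.0, color="grey", lw=0.8, ls="--")
        ax.set_yticks(range(len(labels)))
        ax.set_yticklabels(labels)
        ax.invert_yaxis()
        ax.set_title(title)
        ax.set_xlabel("effect (SD per SD), 95% CI")
        return ax


def run_from_config(config: dict, outdir: str | Path) -> MRStudyResults:
    """Build and fit a study from a configuration mapping, write the bundle.

    The config carries exactly one of a ``simulation`` block (StructuralParams
    fields plus optional n_bmi/n_t) or an ``inputs`` block (paths to the
    variant TSV, dosage TSVs and phenotype TSV).  Inputs are validated before
    any output is written; a failure leaves no partial tables.
    """
    from .data import read_dosage_tsv, read_phenotypes_tsv, read_variants_tsv
    from .simulate import CohortProfile

    has_sim = "simulation" in config
    has_inputs = "inputs" in config
    if has_sim == has_inputs:
        raise ConfigurationError(
            "config must contain exactly one of 'simulation' or 'inputs'"
        )
    alpha = float(config.get("alpha", 0.05))
    if has_sim:
        sim_cfg = dict(config["simulation"])
        n_bmi = int(sim_cfg.pop("n_bmi", 97))
        n_t = int(sim_cfg.pop("n_t", 3))
        profiles = sim_cfg.pop("cohort_profiles", None)
        if profiles is not None:
            sim_cfg["cohort_profiles"] = tuple(
                CohortProfile(**p) for p in profiles
            )
        params = StructuralParams(**sim_cfg)
        study = MRStudy.from_simulation(params, n_bmi=n_bmi, n_t=n_t, alpha=alpha)
    else:
        inputs = config["inputs"]
        for key in ("variants", "dosages", "phenotypes"):
            if key not in inputs:
                raise ConfigurationError(f"inputs block lacks {key!r}")
        for path in [inputs["variants"], inputs["phenotypes"], *inputs["dosages"].values()]:
            if not Path(path).exists():
                raise ConfigurationError(f"input file not found: {path}")
        specs = read_variants_tsv(inputs["variants"])
        tables = {t.cohort: t for t in read_phenotypes_tsv(inputs["phenotypes"])}
        cohorts = []
        for cohort_name, dosage_path in inputs["dosages"].items():
            if cohort_name not in tables:
                raise ConfigurationError(
                    f"no phenotypes for cohort {cohort_name!r}"
                )
            cohorts.append((read_dosage_tsv(dosage_path, specs), tables[cohort_name]))
        study = MRStudy(cohorts, specs, alpha=alpha, seed=config.get("seed"),
                        config=config)
    results = study.fit()
    results.to_tables(outdir)
    return results
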