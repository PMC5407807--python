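"""Core data containers and plain-text I/O.

The working objects mirror what a GWAS-derived risk-score analysis needs:

* :class:`VariantSpec` — one instrument SNP with its alleles, per-allele
  weight (SD of the standardized trait per counted allele) and effect-allele
  frequency.  BMI instruments are oriented to the BMI-increasing allele,
  testosterone instruments to the T-decreasing allele, so weights are
  non-negative by construction.
* :class:`DosageMatrix` — individuals x variants expected allele counts
  ("dosages") with explicit orientation metadata (which allele each column
  counts).  Autosomal dosages live in [0, 2]; the X-chromosome variant in
  males is hemizygous and lives in [0, 1].
* :class:`CohortTable` — per-individual phenotypes and covariates for one
  named cohort (BMI kg/m2, total testosterone ng/ml, SHBG nmol/l, age,
  smoking, blood-sampling time).

All interchange formats are plain text: TSV for variants, dosages, phenotypes
and scores, plus a minimal VCF dialect carrying a per-genotype ``DS`` (dosage)
field.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError

AUTOSOMAL = "autosomal"
X_MALE = "x_male"
CHROM_CLASSES = (AUTOSOMAL, X_MALE)

TRAIT_BMI = "bmi_increasing"
TRAIT_T = "t_decreasing"
TRAITS = (TRAIT_BMI, TRAIT_T)

NUCLEOTIDES = ("A", "C", "G", "T")

_BOUND_EPS = 1e-9

VARIANT_COLUMNS = [
    "rsid",
    "chrom_class",
    "effect_allele",
    "other_allele",
    "weight",
    "eaf",
    "trait",
]


@dataclasses.dataclass(frozen=True)
class VariantSpec:
    """One instrument SNP, oriented to its trait-increasing/-decreasing allele."""

    rsid: str
    chrom_class: str
    effect_allele: str
    other_allele: str
    weight: float
    eaf: float
    trait: str

    def __post_init__(self) -> None:
        if self.chrom_class not in CHROM_CLASSES:
            raise ParameterError(
                f"{self.rsid}: chrom_class must be one of {CHROM_CLASSES}, "
                f"got {self.chrom_class!r}"
            )
        if self.trait not in TRAITS:
            raise ParameterError(
                f"{self.rsid}: trait must be one of {TRAITS}, got {self.trait!r}"
            )
        if self.effect_allele == self.other_allele:
            raise DataError(f"{self.rsid}: effect and other allele are identical")
        for allele in (self.effect_allele, self.other_allele):
            if allele not in NUCLEOTIDES:
                raise DataError(f"{self.rsid}: allele {allele!r} is not a nucleotide")
        if not 0.0 < self.eaf < 1.0:
            raise ParameterError(f"{self.rsid}: eaf must be in (0, 1), got {self.eaf}")
        if self.weight < 0:
            raise ParameterError(
                f"{self.rsid}: weight must be >= 0 after orientation, got {self.weight}"
            )

    @property
    def ploidy(self) -> int:
        """Number of allele draws: 2 for autosomal, 1 for X in males."""
        return 2 if self.chrom_class == AUTOSOMAL else 1

    @property
    def mean_dosage(self) -> float:
        return self.ploidy * self.eaf

    @property
    def dosage_variance(self) -> float:
        """Binomial dosage variance at Hardy-Weinberg: ploidy * p * (1 - p)."""
        return self.ploidy * self.eaf * (1.0 - self.eaf)


def write_variants_tsv(specs: Sequence[VariantSpec], path: str | Path) -> None:
    """Write a GWAS-summary-style weight table."""
    frame = pd.DataFrame([dataclasses.asdict(s) for s in specs], columns=VARIANT_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_variants_tsv(path: str | Path) -> list[VariantSpec]:
    frame = pd.read_csv(path, sep="\t", dtype={"rsid": str}, float_precision="round_trip")
    missing = set(VARIANT_COLUMNS) - set(frame.columns)
    if missing:
        raise DataError(f"variant table {path} lacks columns {sorted(missing)}")
    return [
        VariantSpec(
            rsid=row.rsid,
            chrom_class=row.chrom_class,
            effect_allele=row.effect_allele,
            other_allele=row.other_allele,
            weight=float(row.weight),
            eaf=float(row.eaf),
            trait=row.trait,
        )
        for row in frame.itertuples(index=False)
    ]


@dataclasses.dataclass
class DosageMatrix:
    """Individuals x variants dosage values with allele-orientation metadata.

    ``dosages`` is indexed by individual id with one column per rsID; missing
    entries are NaN.  ``counted_allele`` records, per variant, the nucleotide
    whose expected copy number the column stores — the quantity the risk-score
    harmonizer operates on.
    """

    dosages: pd.DataFrame
    counted_allele: dict[str, str]
    chrom_class: dict[str, str]

    def __post_init__(self) -> None:
        cols = list(self.dosages.columns)
        for rsid in cols:
            if rsid not in self.counted_allele:
                raise DataError(f"no counted allele recorded for {rsid}")
            if self.chrom_class.get(rsid) not in CHROM_CLASSES:
                raise DataError(f"no valid chromosome class recorded for {rsid}")
        if cols:
            values = self.dosages.to_numpy(dtype=float)
            upper = np.array(
                [2.0 if self.chrom_class[c] == AUTOSOMAL else 1.0 for c in cols]
            )
            finite_mask = ~np.isnan(values)
            if finite_mask.any():
                if values[finite_mask].min() < -_BOUND_EPS:
                    raise DataError("negative dosage encountered")
                if (values - upper[None, :])[finite_mask].max() > _BOUND_EPS:
                    raise DataError(
                        "dosage exceeds ploidy bound (2 autosomal, 1 X-male)"
                    )

    @property
    def individual_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def variant_ids(self) -> list[str]:
        return list(self.dosages.columns)

    def copy(self) -> "DosageMatrix":
        return DosageMatrix(
            self.dosages.copy(), dict(self.counted_allele), dict(self.chrom_class)
        )

    def drop_variants(self, rsids: Iterable[str]) -> "DosageMatrix":
        """Return a matrix without the given variants (cohort-level absence)."""
        drop = [r for r in rsids if r in self.dosages.columns]
        return DosageMatrix(
            self.dosages.drop(columns=drop),
            {r: a for r, a in self.counted_allele.items() if r not in drop},
            {r: c for r, c in self.chrom_class.items() if r not in drop},
        )


PHENOTYPE_REQUIRED = ["bmi", "testosterone", "age", "smoking"]
PHENOTYPE_OPTIONAL = ["shbg", "sampling_time"]


@dataclasses.dataclass
class CohortTable:
    """Per-individual phenotypes and covariates for one named cohort."""

    data: pd.DataFrame
    cohort: str

    def __post_init__(self) -> None:
        missing = set(PHENOTYPE_REQUIRED) - set(self.data.columns)
        if missing:
            raise DataError(f"cohort {self.cohort}: missing columns {sorted(missing)}")
        if (self.data["bmi"] <= 0).any():
            raise DataError(f"cohort {self.cohort}: non-positive BMI")
        if (self.data["testosterone"] <= 0).any():
            raise DataError(f"cohort {self.cohort}: non-positive testosterone")
        if (self.data["age"] <= 0).any():
            raise DataError(f"cohort {self.cohort}: non-positive age")
        if not self.data["smoking"].isin([0, 1]).all():
            raise DataError(f"cohort {self.cohort}: smoking must be 0/1")

    @property
    def individual_ids(self) -> pd.Index:
        return self.data.index

    @property
    def n(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# TSV / VCF interchange
# ---------------------------------------------------------------------------


def write_dosage_tsv(matrix: DosageMatrix, path: str | Path) -> None:
    """Individuals x variants TSV with a header row of rsIDs; missing as NA.

    Allele orientation is carried by the variant table, not the dosage file:
    a written matrix is expected to count the variant table's effect allele.
    """
    matrix.dosages.to_csv(path, sep="\t", na_rep="NA", index_label="individual_id")


def read_dosage_tsv(
    path: str | Path,
    specs: Sequence[VariantSpec],
    counted_alleles: Mapping[str, str] | None = None,
) -> DosageMatrix:
    """Read a dosage TSV, taking orientation from ``specs`` unless overridden."""
    frame = pd.read_csv(path, sep="\t", index_col="individual_id", na_values="NA")
    by_rsid = {s.rsid: s for s in specs}
    unknown = [c for c in frame.columns if c not in by_rsid]
    if unknown:
        raise DataError(f"dosage file {path} has variants absent from the spec: {unknown}")
    counted = {
        c: (counted_alleles[c] if counted_alleles else by_rsid[c].effect_allele)
        for c in frame.columns
    }
    chrom = {c: by_rsid[c].chrom_class for c in frame.columns}
    return DosageMatrix(frame.astype(float), counted, chrom)


def write_phenotypes_tsv(cohorts: Sequence[CohortTable], path: str | Path) -> None:
    frames = []
    for cohort in cohorts:
        frame = cohort.data.copy()
        frame.insert(0, "cohort", cohort.cohort)
        frames.append(frame)
    pd.concat(frames).to_csv(path, sep="\t", na_rep="NA", index_label="individual_id")


def read_phenotypes_tsv(path: str | Path) -> list[CohortTable]:
    frame = pd.read_csv(path, sep="\t", index_col="individual_id", na_values="NA")
    if "cohort" not in frame.columns:
        raise DataError(f"phenotype file {path} lacks a 'cohort' column")
    return [
        CohortTable(sub.drop(columns="cohort"), cohort=str(name))
        for name, sub in frame.groupby("cohort", sort=False)
    ]


def write_vcf(matrix: DosageMatrix, specs: Sequence[VariantSpec], path: str | Path) -> None:
    """Write the minimal VCF dialect: one DS (dosage) value per genotype.

    REF is the non-counted allele and ALT the counted allele, so DS is the
    expected ALT-allele count.  Autosomal variants go on contig "1", the
    male X-linked variant on "X".  Requires an already-harmonized matrix
    (counted allele == effect allele) so the file is self-describing.
    """
    by_rsid = {s.rsid: s for s in specs}
    samples = [str(i) for i in matrix.individual_ids]
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Expected alternate allele dosage">',
        "##contig=<ID=1>",
        "##contig=<ID=X>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    values = matrix.dosages.to_numpy(dtype=float)
    for j, rsid in enumerate(matrix.variant_ids):
        spec = by_rsid[rsid]
        if matrix.counted_allele[rsid] != spec.effect_allele:
            raise DataError(f"{rsid}: harmonize before writing VCF")
        chrom = "1" if spec.chrom_class == AUTOSOMAL else "X"
        fields = [chrom, str(1000 + j), rsid, spec.other_allele, spec.effect_allele,
                  ".", "PASS", ".", "DS"]
        col = values[:, j]
        fields.extend("." if np.isnan(v) else f"{v:g}" for v in col)
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path, specs: Sequence[VariantSpec]) -> DosageMatrix:
    """Read the minimal DS-dosage VCF dialect back via pysam."""
    import pysam

    by_rsid = {s.rsid: s for s in specs}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        columns: dict[str, np.ndarray] = {}
        counted: dict[str, str] = {}
        chrom: dict[str, str] = {}
        for record in vcf:
            rsid = record.id
            if rsid not in by_rsid:
                raise DataError(f"VCF variant {rsid} absent from the spec")
            spec = by_rsid[rsid]
            values = np.array(
                [
                    np.nan
                    if record.samples[s].get("DS") is None
                    else float(record.samples[s]["DS"])
                    for s in samples
                ]
            )
            columns[rsid] = values
            counted[rsid] = record.alts[0]
            chrom[rsid] = spec.chrom_class
    frame = pd.DataFrame(columns, index=pd.Index(samples, name="individual_id"))
    return DosageMatrix(frame, counted, chrom)
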