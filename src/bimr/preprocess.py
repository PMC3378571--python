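"""Quality control, covariate derivation, trait transformation and assembly.

Implements chip-era genotype QC (per-sample and per-SNP call-rate filters,
minor-allele-frequency and Hardy-Weinberg filters, all with strict
"less than" semantics at the printed thresholds), the abbreviated MDRD
estimate of glomerular filtration rate, the variance-stabilizing trait
transformations used throughout the analysis, standardization, and
complete-case selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from scipy import stats

from bimr.synthetic import Cohort, TRAIT_COLUMNS

#: fixed transformation per analysis trait. BMI uses a NEGATED inverse square
#: root so the transformed value increases with BMI, keeping the sign of
#: reported coefficients aligned across traits.
TRAIT_TRANSFORMS = {
    "weight": "log",
    "waist": "log",
    "sua": "sqrt",
    "fat_mass": "sqrt",
    "bmi": "neg_inv_sqrt",
}


@dataclass(frozen=True)
class QcThresholds:
    """Marker/sample QC thresholds; all comparisons are strict ("less than")."""

    sample_min_call: float = 0.95
    snp_min_call: float = 0.70
    min_maf: float = 0.01
    hwe_alpha: float = 1e-4  # conventional GWAS-QC level; the test is configurable

    def __post_init__(self) -> None:
        for name in ("sample_min_call", "snp_min_call", "min_maf", "hwe_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


# ---------------------------------------------------------------------------
# input
# ---------------------------------------------------------------------------

#: cyvcf2 gt_types code -> dosage (0 hom-ref, 1 het, 2 missing, 3 hom-alt)
_GT_TYPE_TO_DOSAGE = np.array([0.0, 1.0, np.nan, 2.0])


def read_cohort(vcf_path, pheno_path) -> Cohort:
    """Load a cohort from a VCF (GT field) and a tab-delimited phenotype table.

    Sample IDs must match between the two files; the phenotype table may hold
    any superset of samples, and is aligned to the VCF sample order.
    """
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    dosage_cols: dict[str, np.ndarray] = {}
    info_rows = []
    for rec in vcf:
        snp_id = rec.ID or f"{rec.CHROM}:{rec.POS}"
        dosage_cols[snp_id] = _GT_TYPE_TO_DOSAGE[rec.gt_types]
        info_rows.append(
            {
                "snp_id": snp_id,
                "gene": rec.INFO.get("GENE", ""),
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0] if rec.ALT else ".",
            }
        )
    vcf.close()
    if not info_rows:
        raise ValueError(f"no variant records in {vcf_path}")
    index = pd.Index(samples, name="sample_id")
    dosages = pd.DataFrame(dosage_cols, index=index)
    snp_info = pd.DataFrame(info_rows).set_index("snp_id")

    pheno = pd.read_csv(pheno_path, sep="\t", index_col="sample_id", na_values="NA")
    missing = index.difference(pheno.index)
    if len(missing):
        raise ValueError(f"{len(missing)} VCF samples absent from phenotype table")
    return Cohort(dosages=dosages, pheno=pheno.loc[index], snp_info=snp_info)


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------


def filter_samples(
    dosages: pd.DataFrame, thresholds: QcThresholds = QcThresholds()
) -> tuple[pd.Index, pd.DataFrame]:
    """Drop samples whose genotype call rate is below the threshold.

    Returns the kept sample index and a per-sample report (call_rate, kept).
    The boundary is strict: a call rate exactly at the threshold is kept.
    """
    if dosages.shape[1] < 1:
        raise ValueError("need at least one SNP to compute sample call rates")
    call_rate = dosages.notna().mean(axis=1)
    kept = call_rate >= thresholds.sample_min_call
    report = pd.DataFrame({"call_rate": call_rate, "kept": kept})
    return dosages.index[kept], report


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """One-df chi-square goodness-of-fit test of Hardy-Weinberg proportions.

    Expected counts use the sample allele frequency; monomorphic input
    returns p = 1 (such markers are handled by the MAF filter instead).
    """
    counts = np.array([n_aa, n_ab, n_bb], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n < 1:
        raise ValueError("need at least one genotype")
    p = (counts[1] + 2.0 * counts[2]) / (2.0 * n)
    if p <= 0.0 or p >= 1.0:
        return 1.0
    q = 1.0 - p
    expected = n * np.array([q * q, 2.0 * p * q, p * p])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def snp_qc_report(
    dosages: pd.DataFrame, thresholds: QcThresholds = QcThresholds()
) -> pd.DataFrame:
    """Per-SNP QC verdicts: call rate, MAF, HWE p-value, kept flag and reasons."""
    if dosages.shape[0] < 1:
        raise ValueError("need at least one sample")
    rows = []
    for snp_id in dosages.columns:
        d = dosages[snp_id].dropna().to_numpy()
        n = len(d)
        call_rate = n / len(dosages)
        counts = [int((d == k).sum()) for k in (0, 1, 2)]
        if n:
            af = (counts[1] + 2 * counts[2]) / (2 * n)
            maf = min(af, 1.0 - af)
            hwe_p = hwe_test(*counts)
            monomorphic = len(np.unique(d)) < 2
        else:
            maf, hwe_p, monomorphic = 0.0, 1.0, True
        reasons = []
        if monomorphic:
            reasons.append("monomorphic")
        if call_rate < thresholds.snp_min_call:
            reasons.append("call_rate")
        if maf < thresholds.min_maf:
            reasons.append("maf")
        if hwe_p < thresholds.hwe_alpha:
            reasons.append("hwe")
        rows.append(
            {
                "snp_id": snp_id,
                "call_rate": call_rate,
                "maf": maf,
                "hwe_p": hwe_p,
                "kept": not reasons,
                "reasons": ";".join(reasons),
            }
        )
    return pd.DataFrame(rows).set_index("snp_id")


def filter_snps(
    dosages: pd.DataFrame, thresholds: QcThresholds = QcThresholds()
) -> tuple[list[str], pd.DataFrame]:
    """Drop monomorphic, low-call-rate, rare and HWE-violating SNPs."""
    report = snp_qc_report(dosages, thresholds)
    kept = [s for s in dosages.columns if report.loc[s, "kept"]]
    return kept, report


def qc_cohort(
    cohort: Cohort,
    thresholds: QcThresholds = QcThresholds(),
    iterate: bool = False,
) -> tuple[Cohort, dict[str, pd.DataFrame]]:
    """Apply sample QC then SNP QC (single pass by default).

    With ``iterate=True`` the two filters run alternately to a fixed point,
    which makes the result independent of filter order.
    """
    dosages, pheno = cohort.dosages, cohort.pheno
    reports: dict[str, pd.DataFrame] = {}
    while True:
        kept_samples, sample_rep = filter_samples(dosages, thresholds)
        dosages = dosages.loc[kept_samples]
        kept_snps, snp_rep = filter_snps(dosages, thresholds)
        dosages = dosages[kept_snps]
        reports.setdefault("samples", sample_rep)
        reports["snps"] = snp_rep
        nothing_removed = len(kept_samples) == len(sample_rep) and len(kept_snps) == len(
            snp_rep
        )
        if not iterate or nothing_removed:
            break
    out = Cohort(
        dosages=dosages,
        pheno=pheno.loc[dosages.index],
        snp_info=cohort.snp_info.loc[dosages.columns],
        config=cohort.config,
    )
    return out, reports


# ---------------------------------------------------------------------------
# derived covariates and transformations
# ---------------------------------------------------------------------------


def egfr_mdrd(creatinine_umol_l, age_years, sex):
    """Abbreviated MDRD estimated glomerular filtration rate (ml/min/1.73 m2).

    186 x (creatinine/88.4)^-1.154 x age^-0.203, times 0.742 for women.
    ``sex`` codes women as "F" (or 1/True); anything else is treated as male.
    """
    crea = np.asarray(creatinine_umol_l, dtype=float)
    age = np.asarray(age_years, dtype=float)
    if (crea <= 0).any():
        raise ValueError("creatinine must be > 0")
    if (age <= 0).any():
        raise ValueError("age must be > 0")
    female = _female_mask(sex, np.broadcast(crea, age).shape)
    gfr = 186.0 * (crea / 88.4) ** -1.154 * age**-0.203
    gfr = np.where(female, 0.742 * gfr, gfr)
    return gfr if gfr.ndim else float(gfr)


def _female_mask(sex, shape) -> np.ndarray:
    arr = np.asarray(sex)
    if arr.dtype.kind in "USO":
        female = np.char.upper(arr.astype(str)) == "F"
    else:
        female = arr.astype(float) == 1.0
    return np.broadcast_to(female, shape)


def transform_trait(values, kind: str):
    """Apply a trait's variance-stabilizing transform.

    ``kind`` is a transform name (log, sqrt, neg_inv_sqrt) or a trait name
    (weight, waist, sua, fat_mass, bmi). All require strictly positive input.
    """
    kind = TRAIT_TRANSFORMS.get(kind, kind)
    x = np.asarray(values, dtype=float)
    bad = np.nonzero(~np.isnan(x) & (x <= 0.0))[0]
    if len(bad):
        raise ValueError(f"non-positive value at position {bad[0]}: {x[bad[0]]}")
    if kind == "log":
        return np.log(x)
    if kind == "sqrt":
        return np.sqrt(x)
    if kind == "neg_inv_sqrt":
        return -1.0 / np.sqrt(x)
    raise ValueError(f"unknown transform {kind!r}")


def standardize(values):
    """Z-scores with the sample (n-1) SD, ignoring NaN.

    Standardization is meant to run on each analysis's complete-case sample,
    so the SD scale follows that sample's n.
    """
    x = np.asarray(values, dtype=float)
    obs = x[~np.isnan(x)]
    if len(obs) < 2:
        raise ValueError("need at least 2 non-missing values to standardize")
    sd = obs.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero variance: cannot standardize")
    return (x - obs.mean()) / sd


def complete_cases(
    cohort: Cohort,
    pheno_cols: Sequence[str] = (),
    snp_ids: Sequence[str] = (),
) -> pd.Index:
    """Samples non-missing on every required phenotype column and SNP."""
    missing_cols = [c for c in pheno_cols if c not in cohort.pheno.columns]
    if missing_cols:
        raise KeyError(f"phenotype columns not found: {missing_cols}")
    missing_snps = [s for s in snp_ids if s not in cohort.dosages.columns]
    if missing_snps:
        raise KeyError(f"SNPs not found: {missing_snps}")
    keep = pd.Series(True, index=cohort.sample_ids)
    for c in pheno_cols:
        keep &= cohort.pheno[c].notna()
    for s in snp_ids:
        keep &= cohort.dosages[s].notna()
    idx = cohort.sample_ids[keep]
    if len(idx) == 0:
        per_var = {c: int(cohort.pheno[c].isna().sum()) for c in pheno_cols}
        per_var.update({s: int(cohort.dosages[s].isna().sum()) for s in snp_ids})
        worst = max(per_var, key=per_var.get) if per_var else "?"
        raise ValueError(
            f"no complete cases; most missing variable: {worst} "
            f"({per_var.get(worst, 0)} missing)"
        )
    return idx


def trait_column(trait: str) -> str:
    """Phenotype-table column for an analysis trait name."""
    try:
        return TRAIT_COLUMNS[trait]
    except KeyError:
        raise KeyError(f"unknown trait {trait!r}; expected one of {sorted(TRAIT_COLUMNS)}")
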