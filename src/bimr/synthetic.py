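"""Synthetic genotype/phenotype cohorts for bidirectional Mendelian randomization.

The generator emulates a middle-aged European population cohort: biallelic
SNPs under Hardy-Weinberg equilibrium grouped into the adiposity genes
(FTO, MC4R, TMEM18) and the urate transporter gene SLC2A9; a latent shared
confounder; a directional causal structure between a latent adiposity factor
and serum uric acid (SUA); measured covariates that partially proxy the
confounder; missingness; and SNP defects that trip quality-control filters.

Instrument strength is calibrated so the variance a genetic score explains
in a standardized trait hits a configurable R-squared target, matching the
weak-instrument regime of adiposity genetics (score R-squared well below 1%)
and the stronger single-SNP SLC2A9 instrument for SUA (about 3%).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

ADIPOSITY_GENES = ("FTO", "MC4R", "TMEM18")
SUA_GENE = "SLC2A9"
GENES = ADIPOSITY_GENES + (SUA_GENE,)

#: chromosome carrying each gene (GRCh37 convention; plumbing for VCF output)
GENE_CHROM = {"FTO": "16", "MC4R": "18", "TMEM18": "2", "SLC2A9": "4"}

DIRECTIONS = ("adiposity_to_sua", "sua_to_adiposity", "null", "both")

ADIPOSITY_TRAITS = ("weight", "bmi", "waist", "fat_mass")

#: phenotype-table column for each analysis trait
TRAIT_COLUMNS = {
    "weight": "weight_kg",
    "bmi": "bmi",
    "waist": "waist_cm",
    "fat_mass": "fat_mass_kg",
    "sua": "sua_umol_l",
}

MEASUREMENT_COLUMNS = (
    "weight_kg",
    "bmi",
    "waist_cm",
    "fat_mass_kg",
    "sua_umol_l",
    "creatinine_umol_l",
)

COVARIATE_COLUMNS = ("sex", "age_years", "smoking", "alcohol", "diuretic")

#: loading of each observed adiposity trait on the latent adiposity factor.
#: Squared loading times the score R-squared target gives the per-trait
#: variance explained by the instrument, reproducing the spread of published
#: first-stage R-squared across traits (waist strongest, fat mass/BMI weakest).
DEFAULT_TRAIT_LOADINGS = {
    "waist": 1.0,
    "weight": 0.926,
    "bmi": 0.862,
    "fat_mass": 0.862,
}

#: location/scale of each measurement on its analysis-transform scale, by sex,
#: chosen to give raw-unit means and SDs of the order seen in adult European
#: cohorts (men heavier, women higher fat mass, SUA ~90 umol/L higher in men).
RAW_SCALE_PARAMS = {
    "weight_kg": {"M": (4.40, 0.163), "F": (4.196, 0.194)},  # log kg
    "waist_cm": {"M": (4.562, 0.118), "F": (4.424, 0.149)},  # log cm
    "bmi": {"M": (-0.1939, 0.0146), "F": (-0.1996, 0.0195)},  # -1/sqrt(kg/m2)
    "fat_mass_kg": {"M": (4.45, 0.854), "F": (4.837, 0.982)},  # sqrt kg
    "sua_umol_l": {"M": (19.0, 1.99), "F": (16.45, 2.04)},  # sqrt umol/L
}

_BASIS = ("score", "g", "u", "eps_adip", "eps_sua")


@dataclass(frozen=True)
class SnpDef:
    """Definition of one simulated biallelic SNP.

    ``maf`` is the frequency of the counted (alternate) allele; ``call_rate``
    below 1 injects missing genotypes; ``hwe_inbreeding`` is Wright's F,
    deforming genotype frequencies away from Hardy-Weinberg proportions
    (positive F depletes heterozygotes) to create QC-failing markers.
    """

    snp_id: str
    gene: str
    maf: float
    call_rate: float = 1.0
    hwe_inbreeding: float = 0.0

    def __post_init__(self) -> None:
        if self.gene not in GENES:
            raise ValueError(f"{self.snp_id}: gene must be one of {GENES}, got {self.gene!r}")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"{self.snp_id}: MAF must be in (0, 0.5], got {self.maf}")
        if not 0.0 < self.call_rate <= 1.0:
            raise ValueError(f"{self.snp_id}: call rate must be in (0, 1], got {self.call_rate}")
        p = self.genotype_probs()
        if min(p) < 0.0:
            raise ValueError(
                f"{self.snp_id}: inbreeding coefficient {self.hwe_inbreeding} "
                f"gives negative genotype frequencies at MAF {self.maf}"
            )

    def genotype_probs(self) -> tuple[float, float, float]:
        """(P(dosage 0), P(dosage 1), P(dosage 2)) under HWE with inbreeding F."""
        p, f = self.maf, self.hwe_inbreeding
        q = 1.0 - p
        return (q * q + p * q * f, 2.0 * p * q * (1.0 - f), p * p + p * q * f)

    def dosage_mean(self) -> float:
        p0, p1, p2 = self.genotype_probs()
        return p1 + 2.0 * p2

    def dosage_variance(self) -> float:
        p0, p1, p2 = self.genotype_probs()
        mu = p1 + 2.0 * p2
        return p0 * mu * mu + p1 * (1.0 - mu) ** 2 + p2 * (2.0 - mu) ** 2


@dataclass(frozen=True)
class TrueParams:
    """Generative (structural) parameters of a scenario.

    ``beta_causal`` is the standardized causal effect along ``direction``
    (per SD of the cause, in SD of the effect). ``conf_adiposity`` and
    ``conf_sua`` are the loadings of the latent confounder U ~ N(0,1) on the
    latent adiposity factor and on transformed SUA. The two R-squared targets
    fix the population variance each instrument explains in its own trait.
    """

    direction: str = "adiposity_to_sua"
    beta_causal: float = 0.30
    conf_adiposity: float = 0.45
    conf_sua: float = 0.45
    r2_adip_instrument: float = 0.0070
    r2_sua_instrument: float = 0.0316
    trait_loadings: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_LOADINGS)
    )

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {self.direction!r}")
        for name in ("r2_adip_instrument", "r2_sua_instrument"):
            r2 = getattr(self, name)
            if not 0.0 <= r2 < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {r2}")
        for trait, lam in self.trait_loadings.items():
            if trait not in ADIPOSITY_TRAITS:
                raise ValueError(f"unknown trait in trait_loadings: {trait!r}")
            if not 0.0 < abs(lam) <= 1.0:
                raise ValueError(f"trait loading for {trait} must be in (0, 1], got {lam}")


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete specification of one synthetic cohort."""

    n_samples: int
    snps: tuple[SnpDef, ...]
    true_params: TrueParams = field(default_factory=TrueParams)
    missing_rate_pheno: float = 0.0
    seed: int = 0
    raw_scale: bool = True
    #: SNPs forming the causal adiposity score; default: first three
    #: adiposity-gene SNPs in definition order.
    adiposity_score_snps: tuple[str, ...] | None = None
    #: SNP with a direct effect on SUA; default: first SLC2A9 SNP.
    sua_snp: str | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ValueError(f"n_samples must be >= 10, got {self.n_samples}")
        if not 0.0 <= self.missing_rate_pheno < 1.0:
            raise ValueError("missing_rate_pheno must be in [0, 1)")
        object.__setattr__(self, "snps", tuple(self.snps))
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp_id in scenario")
        if self.adiposity_score_snps is not None:
            object.__setattr__(
                self, "adiposity_score_snps", tuple(self.adiposity_score_snps)
            )
            missing = set(self.adiposity_score_snps) - set(ids)
            if missing:
                raise ValueError(f"adiposity_score_snps not in scenario: {sorted(missing)}")
        if self.sua_snp is not None and self.sua_snp not in ids:
            raise ValueError(f"sua_snp {self.sua_snp!r} not in scenario")

    # -- resolved instrument membership -------------------------------------

    def score_snp_ids(self) -> tuple[str, ...]:
        if self.adiposity_score_snps is not None:
            return self.adiposity_score_snps
        ids = tuple(s.snp_id for s in self.snps if s.gene in ADIPOSITY_GENES)[:3]
        if not ids:
            raise ValueError("scenario has no adiposity-gene SNPs")
        return ids

    def sua_snp_id(self) -> str:
        if self.sua_snp is not None:
            return self.sua_snp
        for s in self.snps:
            if s.gene == SUA_GENE:
                return s.snp_id
        raise ValueError("scenario has no SLC2A9 SNP")

    # -- (de)serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["true_params"]["trait_loadings"] = dict(self.true_params.trait_loadings)
        d["snps"] = [dataclasses.asdict(s) for s in self.snps]
        if self.adiposity_score_snps is not None:
            d["adiposity_score_snps"] = list(self.adiposity_score_snps)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        d = dict(d)
        d["snps"] = tuple(SnpDef(**s) for s in d["snps"])
        tp = d.get("true_params")
        if isinstance(tp, Mapping):
            d["true_params"] = TrueParams(**tp)
        if d.get("adiposity_score_snps") is not None:
            d["adiposity_score_snps"] = tuple(d["adiposity_score_snps"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class Cohort:
    """Aligned genotype dosages and phenotype/covariate table.

    ``dosages`` is an n-samples x m-SNPs float frame with values in
    {0, 1, 2, NaN}; ``pheno`` carries measurements and covariates; both are
    indexed by sample ID. ``snp_info`` (indexed by snp_id) records gene,
    chromosome, position and alleles.
    """

    dosages: pd.DataFrame
    pheno: pd.DataFrame
    snp_info: pd.DataFrame
    config: ScenarioConfig | None = None

    def __post_init__(self) -> None:
        if not self.dosages.index.equals(self.pheno.index):
            raise ValueError("dosages and pheno must be row-aligned on sample ID")
        if list(self.dosages.columns) != list(self.snp_info.index):
            raise ValueError("dosage columns must match snp_info index")
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be in {0, 1, 2} or missing")

    @property
    def sample_ids(self) -> pd.Index:
        return self.pheno.index

    @property
    def n_samples(self) -> int:
        return len(self.pheno)

    def gene_of(self, snp_id: str) -> str:
        return str(self.snp_info.loc[snp_id, "gene"])

    def snps_in_genes(self, genes: Iterable[str]) -> list[str]:
        genes = set(genes)
        return [s for s in self.snp_info.index if self.snp_info.loc[s, "gene"] in genes]


# ---------------------------------------------------------------------------
# genotype simulation and effect calibration
# ---------------------------------------------------------------------------


def simulate_genotypes(
    n: int,
    snps: Sequence[SnpDef],
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw an n x m dosage matrix under HWE (with optional inbreeding).

    Genotypes are trinomial draws from each SNP's genotype frequencies;
    entries are then set missing (NaN) independently at rate 1 - call_rate.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    full = _simulate_full_genotypes(n, snps, rng)
    return _mask_missing_calls(full, snps, rng)


def _simulate_full_genotypes(
    n: int, snps: Sequence[SnpDef], rng: np.random.Generator
) -> pd.DataFrame:
    cols = {}
    for snp in snps:
        probs = np.asarray(snp.genotype_probs())
        cols[snp.snp_id] = rng.choice(3, size=n, p=probs / probs.sum()).astype(float)
    return pd.DataFrame(cols, index=pd.RangeIndex(n))


def _mask_missing_calls(
    full: pd.DataFrame, snps: Sequence[SnpDef], rng: np.random.Generator
) -> pd.DataFrame:
    out = full.copy()
    for snp in snps:
        if snp.call_rate < 1.0:
            miss = rng.random(len(out)) < (1.0 - snp.call_rate)
            out.loc[miss, snp.snp_id] = np.nan
    return out


def calibrate_effect(target_r2: float, regressor_variance: float) -> float:
    """Slope alpha such that alpha*G + noise (unit total variance) has R2 = target.

    For a unit-variance trait built as ``alpha * G + e`` the variance explained
    by G is ``alpha**2 * Var(G)``, so ``alpha = sqrt(target_r2 / Var(G))``.
    """
    if not 0.0 <= target_r2 < 1.0:
        raise ValueError(f"target_r2 must be in [0, 1), got {target_r2}")
    if regressor_variance <= 0.0:
        raise ValueError(f"regressor_variance must be > 0, got {regressor_variance}")
    return math.sqrt(target_r2 / regressor_variance)


def instrument_strength_replicates(
    target_r2: float,
    n: int,
    mafs: Sequence[float],
    reps: int = 300,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo first-stage F-statistics for a calibrated score instrument.

    Simulates ``reps`` cohorts of size ``n``: independent HWE SNPs at the
    given MAFs summed into an unweighted allele score, and a standardized
    exposure built as ``alpha * score + noise`` with ``alpha`` calibrated so
    the population variance explained equals ``target_r2``. Each replicate's
    crude first-stage regression F is returned; the mean estimates the
    large-sample instrument strength E[F] ~= 1 + R2 (n - 2) / (1 - R2).
    """
    from bimr.instruments import first_stage_fit  # local to avoid import cycle

    snps = [SnpDef(f"snp{i}", "FTO", maf) for i, maf in enumerate(mafs)]
    var_score = sum(s.dosage_variance() for s in snps)
    mean_score = sum(s.dosage_mean() for s in snps)
    alpha = calibrate_effect(target_r2, var_score)
    noise_sd = math.sqrt(1.0 - target_r2)
    rng = np.random.default_rng(seed)
    out = np.empty(reps)
    for r in range(reps):
        geno = _simulate_full_genotypes(n, snps, rng)
        score = geno.sum(axis=1).to_numpy()
        exposure = alpha * (score - mean_score) + noise_sd * rng.standard_normal(n)
        out[r] = first_stage_fit(exposure, score).f_statistic
    return out


# ---------------------------------------------------------------------------
# structural model
# ---------------------------------------------------------------------------


def _structural_coefficients(
    params: TrueParams, var_score: float, var_g: float
) -> np.ndarray:
    """Coefficients of the latent adiposity factor and SUA on the basis
    (centered score, centered SLC2A9 dosage, U, eps_adip, eps_sua).

    Each trait loads on its own instrument in every direction (a cohort always
    carries both genetic signals); ``direction`` only switches which causal
    path(s) between the two traits are active. Residual SDs are solved so each
    latent trait has population variance exactly 1; in the reciprocal ("both")
    case the reduced form is rescaled to unit variance instead.
    """
    alpha_a = calibrate_effect(params.r2_adip_instrument, var_score)
    alpha_s = calibrate_effect(params.r2_sua_instrument, var_g)
    c_a, c_s = params.conf_adiposity, params.conf_sua
    beta = params.beta_causal
    v = np.array([var_score, var_g, 1.0, 1.0, 1.0])

    def _exogenous(alpha_sq: float, c: float, which: str, eps_idx: int, row: list) -> np.ndarray:
        resid = 1.0 - alpha_sq - c * c
        if resid <= 0.0:
            raise ValueError(
                f"variance budget exceeded for {which}: instrument R2 + "
                f"confounder loading^2 = {alpha_sq + c * c:.4f} >= 1"
            )
        out = np.array(row, dtype=float)
        out[eps_idx] = math.sqrt(resid)
        return out

    a0 = _exogenous(
        params.r2_adip_instrument, c_a, "adiposity", 3, [alpha_a, 0.0, c_a, 0.0, 0.0]
    )
    s0 = _exogenous(
        params.r2_sua_instrument, c_s, "SUA", 4, [0.0, alpha_s, c_s, 0.0, 0.0]
    )

    def _downstream(upstream: np.ndarray, own: np.ndarray, which: str, eps_idx: int) -> np.ndarray:
        # own carries the trait's instrument + confounder loadings; residual
        # absorbs what the causal term and covariances leave of the budget.
        coef = beta * upstream + own
        coef[eps_idx] = 0.0
        explained = float(coef @ (v * coef))
        if explained >= 1.0:
            raise ValueError(
                f"variance budget exceeded for {which}: structural terms "
                f"explain {explained:.4f} >= 1"
            )
        coef[eps_idx] = math.sqrt(1.0 - explained)
        return coef

    if params.direction == "null":
        adip, sua = a0, s0
    elif params.direction == "adiposity_to_sua":
        adip = a0
        sua = _downstream(a0, s0, "SUA", 4)
    elif params.direction == "sua_to_adiposity":
        sua = s0
        adip = _downstream(s0, a0, "adiposity", 3)
    else:  # both: reciprocal system, reduced form rescaled to unit variance
        if abs(beta) >= 1.0:
            raise ValueError("reciprocal direction requires |beta_causal| < 1")
        det = 1.0 - beta * beta
        adip = (a0 + beta * s0) / det
        sua = (s0 + beta * a0) / det
        adip = adip / math.sqrt(float(adip @ (v * adip)))
        sua = sua / math.sqrt(float(sua @ (v * sua)))
    return np.vstack([adip, sua])


def population_moments(config: ScenarioConfig) -> dict[str, float]:
    """Exact population moments implied by the generative model.

    Returns variances/covariances of the latent adiposity factor A, latent
    (transformed, standardized) SUA S, the adiposity allele score and the
    SLC2A9 dosage, plus the implied large-sample OLS slopes in both
    directions — the confounding-bias algebra against which estimator
    behaviour can be predicted.
    """
    snp_by_id = {s.snp_id: s for s in config.snps}
    var_score = sum(snp_by_id[i].dosage_variance() for i in config.score_snp_ids())
    var_g = snp_by_id[config.sua_snp_id()].dosage_variance()
    coef = _structural_coefficients(config.true_params, var_score, var_g)
    v = np.array([var_score, var_g, 1.0, 1.0, 1.0])
    cov = coef @ np.diag(v) @ coef.T
    adip, sua = coef
    return {
        "var_adip": float(cov[0, 0]),
        "var_sua": float(cov[1, 1]),
        "cov_adip_sua": float(cov[0, 1]),
        "var_score": var_score,
        "var_g": var_g,
        "cov_score_adip": float(adip[0] * var_score),
        "cov_score_sua": float(sua[0] * var_score),
        "cov_g_adip": float(adip[1] * var_g),
        "cov_g_sua": float(sua[1] * var_g),
        "ols_sua_on_adip": float(cov[0, 1] / cov[0, 0]),
        "ols_adip_on_sua": float(cov[0, 1] / cov[1, 1]),
    }


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohort(config: ScenarioConfig) -> Cohort:
    """Generate a full cohort under the scenario's structural model.

    Latent traits are built from the true (pre-missingness) genotypes; call
    failures and phenotype missingness are injected afterwards, so
    missingness is MCAR with respect to everything in the model.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    params = config.true_params
    snp_by_id = {s.snp_id: s for s in config.snps}

    full_geno = _simulate_full_genotypes(n, config.snps, rng)

    score_ids = config.score_snp_ids()
    g_id = config.sua_snp_id()
    score = full_geno[list(score_ids)].sum(axis=1).to_numpy()
    score_c = score - sum(snp_by_id[i].dosage_mean() for i in score_ids)
    g_c = full_geno[g_id].to_numpy() - snp_by_id[g_id].dosage_mean()
    var_score = sum(snp_by_id[i].dosage_variance() for i in score_ids)
    var_g = snp_by_id[g_id].dosage_variance()

    coef = _structural_coefficients(params, var_score, var_g)
    u = rng.standard_normal(n)
    basis = np.vstack([score_c, g_c, u, rng.standard_normal(n), rng.standard_normal(n)])
    adip, sua = coef @ basis

    # observed adiposity traits: loading on the latent factor + unique noise
    loadings = dict(DEFAULT_TRAIT_LOADINGS)
    loadings.update(params.trait_loadings)
    latent = {"sua": sua}
    for trait in ADIPOSITY_TRAITS:
        lam = loadings[trait]
        latent[trait] = lam * adip + math.sqrt(1.0 - lam * lam) * rng.standard_normal(n)

    pheno = _build_phenotypes(latent, u, n, rng, config)

    dosages = _mask_missing_calls(full_geno, config.snps, rng)
    sample_ids = pd.Index([f"S{i + 1:06d}" for i in range(n)], name="sample_id")
    dosages.index = sample_ids
    pheno.index = sample_ids

    snp_info = pd.DataFrame(
        {
            "gene": [s.gene for s in config.snps],
            "chrom": [GENE_CHROM[s.gene] for s in config.snps],
            "pos": [100_000 + 1_000 * i for i in range(len(config.snps))],
            "ref": "A",
            "alt": "G",
        },
        index=pd.Index([s.snp_id for s in config.snps], name="snp_id"),
    )
    return Cohort(dosages=dosages, pheno=pheno, snp_info=snp_info, config=config)


def _build_phenotypes(
    latent: Mapping[str, np.ndarray],
    u: np.ndarray,
    n: int,
    rng: np.random.Generator,
    config: ScenarioConfig,
) -> pd.DataFrame:
    """Covariates (loaded on the confounder U) and measurement columns.

    Covariate loadings on U are deliberately partial: adjusting for the
    measured covariates removes some but not all confounding, so crude and
    adjusted analyses differ, as they do in real cohort data.
    """
    sex = np.where(rng.random(n) < 0.474, "M", "F")  # slight female excess
    is_f = sex == "F"
    age = 53.0 + 10.7 * (0.20 * u + math.sqrt(1.0 - 0.04) * rng.standard_normal(n))
    age = np.clip(age, 35.0, 75.0)
    smoking = (rng.random(n) < _logistic(-1.0 + 0.5 * u)).astype(int)
    alcohol = (rng.random(n) < _logistic(-1.4 + 0.4 * u + 0.9 * (~is_f))).astype(int)
    diuretic = (rng.random(n) < _logistic(-4.0 + 0.6 * u + 0.03 * (age - 53.0))).astype(int)
    crea_base = np.where(is_f, 68.0, 85.0)
    creatinine = crea_base + 9.0 * (0.3 * u + math.sqrt(1.0 - 0.09) * rng.standard_normal(n))
    creatinine = np.clip(creatinine, 30.0, None)

    pheno = pd.DataFrame(
        {
            "sex": sex,
            "age_years": age,
            "smoking": smoking,
            "alcohol": alcohol,
            "diuretic": diuretic,
            "creatinine_umol_l": creatinine,
        }
    )

    for trait in ("weight", "bmi", "waist", "fat_mass", "sua"):
        col = TRAIT_COLUMNS[trait]
        z = latent[trait]
        if config.raw_scale:
            f_par, m_par = RAW_SCALE_PARAMS[col]["F"], RAW_SCALE_PARAMS[col]["M"]
            loc = np.where(is_f, f_par[0], m_par[0])
            scale = np.where(is_f, f_par[1], m_par[1])
            t = loc + scale * z
            pheno[col] = _inverse_transform(col, t)
        else:
            pheno[col] = z

    if config.missing_rate_pheno > 0.0:
        for col in MEASUREMENT_COLUMNS:
            miss = rng.random(n) < config.missing_rate_pheno
            pheno.loc[miss, col] = np.nan
    return pheno


def _inverse_transform(col: str, t: np.ndarray) -> np.ndarray:
    """Map a transformed-scale value back to raw measurement units."""
    if col in ("weight_kg", "waist_cm"):
        return np.exp(t)
    if col in ("sua_umol_l", "fat_mass_kg"):
        return np.square(np.clip(t, 0.1, None))
    if col == "bmi":
        return 1.0 / np.square(np.clip(-t, 0.05, None))
    raise ValueError(f"no inverse transform for column {col!r}")


# ---------------------------------------------------------------------------
# default scenario
# ---------------------------------------------------------------------------


def default_scenario(
    n_samples: int = 6184,
    seed: int = 0,
    direction: str = "adiposity_to_sua",
    beta_causal: float = 0.30,
    missing_rate_pheno: float = 0.002,
    with_qc_defects: bool = False,
) -> ScenarioConfig:
    """Cohort-calibrated default scenario.

    Three adiposity-gene SNPs carry the causal score (combined R-squared
    target 0.0070 on the latent factor); three further adiposity-gene SNPs
    are null candidates so the instrument search has something to reject;
    one SLC2A9 SNP explains 3.16% of SUA variance and a second is null.
    ``with_qc_defects`` appends markers violating call-rate, MAF and
    Hardy-Weinberg filters.
    """
    # Call rates are high because the per-sample 95% filter is applied over
    # just these markers (a chip-wide filter in the real study); lower rates
    # would discard most of the cohort.
    snps = [
        SnpDef("rs1121980", "FTO", 0.43, call_rate=0.990),
        SnpDef("rs17823223", "FTO", 0.30, call_rate=0.985),
        SnpDef("rs6755502", "TMEM18", 0.25, call_rate=0.990),
        SnpDef("rs7193144", "FTO", 0.40, call_rate=0.995),
        SnpDef("rs17066829", "MC4R", 0.22, call_rate=0.990),
        SnpDef("rs2860323", "TMEM18", 0.35, call_rate=0.995),
        SnpDef("rs6855911", "SLC2A9", 0.30, call_rate=0.985),
        SnpDef("rs7442295", "SLC2A9", 0.25, call_rate=0.990),
    ]
    if with_qc_defects:
        snps += [
            SnpDef("rs_low_call", "FTO", 0.30, call_rate=0.50),
            SnpDef("rs_rare", "MC4R", 0.005),
            SnpDef("rs_hwe_fail", "TMEM18", 0.30, hwe_inbreeding=0.5),
        ]
    return ScenarioConfig(
        n_samples=n_samples,
        snps=tuple(snps),
        true_params=TrueParams(direction=direction, beta_causal=beta_causal),
        missing_rate_pheno=missing_rate_pheno,
        seed=seed,
        adiposity_score_snps=("rs1121980", "rs17823223", "rs6755502"),
        sua_snp="rs6855911",
    )


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def write_cohort(cohort: Cohort, out_prefix) -> dict[str, str]:
    """Write a cohort as VCF 4.2 (GT only) + tab-delimited phenotype table.

    Dosage d counts alternate alleles: 0 -> 0/0, 1 -> 0/1, 2 -> 1/1,
    missing -> ./. . If the cohort carries its generating scenario, it is
    written alongside as YAML.
    """
    prefix = str(out_prefix)
    vcf_path = prefix + ".vcf"
    pheno_path = prefix + ".pheno.tsv"
    paths = {"vcf": vcf_path, "pheno": pheno_path}

    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    samples = list(cohort.sample_ids)
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bimr.synthetic\n")
        for chrom in sorted(set(cohort.snp_info["chrom"]), key=str):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene region">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for snp_id, row in cohort.snp_info.iterrows():
            dos = cohort.dosages[snp_id].to_numpy()
            gts = "\t".join(
                "./." if np.isnan(d) else gt_code[float(d)] for d in dos
            )
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{snp_id}\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\tGENE={row['gene']}\tGT\t{gts}\n"
            )

    cohort.pheno.to_csv(pheno_path, sep="\t", na_rep="NA", float_format="%.10g")

    if cohort.config is not None:
        cfg_path = prefix + ".scenario.yaml"
        cohort.config.to_yaml(cfg_path)
        paths["scenario"] = cfg_path
    return paths
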