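"""End-to-end bidirectional Mendelian randomization analysis.

Orchestrates QC, eGFR derivation, per-stratum instrument selection,
transformation/standardization on each analysis's complete-case sample,
crude and adjusted OLS and 2SLS fits, endogeneity tests, confounder-balance
checks, trend tests, and sex-interaction statistics, and emits the results
as tidy tables (TSV) plus a machine-readable JSON bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

import bimr
from bimr.estimation import (
    durbin_hausman,
    ols_fit,
    sex_interaction,
    tsls_fit,
)
from bimr.instruments import (
    InstrumentSpec,
    build_score,
    collapse_low_categories,
    confounder_balance,
    first_stage_fit,
    search_best_instrument,
    trend_test,
)
from bimr.preprocess import (
    QcThresholds,
    complete_cases,
    egfr_mdrd,
    qc_cohort,
    standardize,
    trait_column,
    transform_trait,
)
from bimr.synthetic import ADIPOSITY_GENES, SUA_GENE, Cohort

DIRECTIONS = ("sua_to_adiposity", "adiposity_to_sua")
STRATA = ("overall", "men", "women")

#: analysis-name -> phenotype column for the default adjustment set
ADJUSTMENT_COLUMNS = {
    "age": "age_years",
    "sex": "sex",
    "smoking": "smoking",
    "alcohol": "alcohol",
    "gfr": "gfr",
    "diuretic": "diuretic",
}


@dataclass(frozen=True)
class AnalysisConfig:
    """What to run: directions, traits, strata, models and knobs."""

    directions: tuple[str, ...] = DIRECTIONS
    traits: tuple[str, ...] = ("weight", "bmi", "waist", "fat_mass")
    strata: tuple[str, ...] = STRATA
    models: tuple[str, ...] = ("crude", "adjusted")
    adjustment: tuple[str, ...] = ("age", "sex", "smoking", "alcohol", "gfr", "diuretic")
    qc: QcThresholds = field(default_factory=QcThresholds)
    combination_size: int = 3
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for d in self.directions:
            if d not in DIRECTIONS:
                raise ValueError(f"unknown direction {d!r}")
        for s in self.strata:
            if s not in STRATA:
                raise ValueError(f"unknown stratum {s!r}")
        if not (self.directions and self.traits and self.strata and self.models):
            raise ValueError("directions, traits, strata and models must be non-empty")
        unknown = set(self.adjustment) - set(ADJUSTMENT_COLUMNS)
        if unknown:
            raise ValueError(f"unknown adjustment covariates: {sorted(unknown)}")
        if self.combination_size < 1:
            raise ValueError("combination_size must be >= 1")


@dataclass
class DirectionReport:
    """All results for one causal direction."""

    direction: str
    rows: pd.DataFrame  # one row per (trait, stratum, model, method)
    instruments: pd.DataFrame  # instrument-search summary (Table-1 shape)
    balance: pd.DataFrame  # confounder-balance screen per instrument
    trends: pd.DataFrame  # nonparametric trend of exposure across score levels
    interactions: pd.DataFrame  # sex-interaction z/p per trait and model


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _with_gfr(cohort: Cohort) -> Cohort:
    pheno = cohort.pheno.copy()
    ok = pheno["creatinine_umol_l"].notna() & pheno["age_years"].notna()
    gfr = np.full(len(pheno), np.nan)
    gfr[ok.to_numpy()] = egfr_mdrd(
        pheno.loc[ok, "creatinine_umol_l"],
        pheno.loc[ok, "age_years"],
        pheno.loc[ok, "sex"],
    )
    pheno["gfr"] = gfr
    return Cohort(cohort.dosages, pheno, cohort.snp_info, cohort.config)


def _stratum_index(cohort: Cohort, stratum: str) -> pd.Index:
    if stratum == "overall":
        return cohort.sample_ids
    sex = "M" if stratum == "men" else "F"
    return cohort.sample_ids[(cohort.pheno["sex"] == sex).to_numpy()]


def _pretransformed(cohort: Cohort) -> bool:
    # synthetic cohorts can carry traits already on the transformed z-scale
    return cohort.config is not None and not cohort.config.raw_scale


def _trait_values(cohort: Cohort, trait: str, idx: pd.Index) -> np.ndarray:
    """Transformed (not yet standardized) trait values for given samples."""
    raw = cohort.pheno.loc[idx, trait_column(trait)].to_numpy(dtype=float)
    if _pretransformed(cohort):
        return raw
    out = np.full(len(raw), np.nan)
    ok = ~np.isnan(raw)
    out[ok] = transform_trait(raw[ok], trait)
    return out


def _covariate_matrix(
    cohort: Cohort, idx: pd.Index, adjustment: Sequence[str], stratum: str
) -> tuple[np.ndarray, list[str]]:
    names: list[str] = []
    cols: list[np.ndarray] = []
    for name in adjustment:
        if name == "sex" and stratum != "overall":
            continue  # constant within a sex stratum
        col = ADJUSTMENT_COLUMNS[name]
        v = cohort.pheno.loc[idx, col]
        cols.append(
            (v == "F").to_numpy(dtype=float) if name == "sex" else v.to_numpy(dtype=float)
        )
        names.append(name)
    for col in cohort.pheno.columns:  # optional ancestry principal components
        if col.lower().startswith("pc") and col[2:].isdigit():
            cols.append(cohort.pheno.loc[idx, col].to_numpy(dtype=float))
            names.append(col)
    if not cols:
        return np.empty((len(idx), 0)), names
    return np.column_stack(cols), names


def _required_pheno_cols(
    direction: str, trait: str, model: str, adjustment: Sequence[str], stratum: str
) -> list[str]:
    cols = [trait_column(trait), trait_column("sua")]
    if model == "adjusted":
        for name in adjustment:
            if name == "sex" and stratum != "overall":
                continue
            cols.append(ADJUSTMENT_COLUMNS[name])
    return cols


def _select_instrument(
    cohort: Cohort,
    direction: str,
    trait: str,
    stratum: str,
    config: AnalysisConfig,
) -> tuple[InstrumentSpec, "pd.DataFrame"]:
    """Best-F instrument for the direction's exposure, within the stratum.

    The SUA direction uses the best single urate-gene SNP; the adiposity
    direction the best k-SNP score over the pooled adiposity-gene candidates.
    Selection is re-run within each stratum.
    """
    idx = _stratum_index(cohort, stratum)
    if direction == "sua_to_adiposity":
        exposure_trait, genes, k = "sua", (SUA_GENE,), 1
    else:
        exposure_trait, genes, k = trait, ADIPOSITY_GENES, config.combination_size
    candidates = cohort.snps_in_genes(genes)
    values = _trait_values(cohort, exposure_trait, idx)
    ok = ~np.isnan(values)
    z = np.full(len(values), np.nan)
    z[ok] = standardize(values[ok])
    spec, fit, table = search_best_instrument(
        cohort.dosages.loc[idx, candidates],
        z,
        k=k,
        trait=exposure_trait,
        stratum=stratum,
        candidates=candidates,
    )
    table.insert(0, "stratum", stratum)
    table.insert(0, "trait", exposure_trait)
    return spec, table


# ---------------------------------------------------------------------------
# direction runner
# ---------------------------------------------------------------------------


def run_direction(
    cohort: Cohort, direction: str, config: AnalysisConfig = AnalysisConfig()
) -> DirectionReport:
    """Run one causal direction across traits, strata and models.

    ``cohort`` must already be QC-filtered (see :func:`run_bidirectional`).
    Rows that fail (e.g. an instrument below the hard F floor) are emitted
    with an ``error`` status and the run continues.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    cohort = _with_gfr(cohort)

    rows: list[dict] = []
    instr_rows: list[pd.DataFrame] = []
    balance_rows: list[pd.DataFrame] = []
    trend_rows: list[dict] = []
    specs: dict[tuple[str, str], InstrumentSpec] = {}

    for stratum in config.strata:
        if direction == "sua_to_adiposity":
            # one SUA instrument per stratum, shared by all outcome traits
            try:
                spec, table = _select_instrument(cohort, direction, "", stratum, config)
            except ValueError as exc:
                for trait in config.traits:
                    rows.extend(_error_rows(direction, trait, stratum, config, str(exc)))
                continue
            instr_rows.append(table.head(5))
            for trait in config.traits:
                specs[(trait, stratum)] = spec
        else:
            for trait in config.traits:
                try:
                    spec, table = _select_instrument(cohort, direction, trait, stratum, config)
                except ValueError as exc:
                    rows.extend(_error_rows(direction, trait, stratum, config, str(exc)))
                    continue
                instr_rows.append(table.head(5))
                specs[(trait, stratum)] = spec

    for (trait, stratum), spec in specs.items():
        idx_stratum = _stratum_index(cohort, stratum)
        exposure_trait = "sua" if direction == "sua_to_adiposity" else trait
        outcome_trait = trait if direction == "sua_to_adiposity" else "sua"

        # descriptive trend of the exposure across (collapsed) score levels
        try:
            t_idx = complete_cases(
                _subset(cohort, idx_stratum),
                pheno_cols=[trait_column(exposure_trait)],
                snp_ids=list(spec.snp_ids),
            )
            score = _oriented_score(cohort, spec, t_idx)
            levels = collapse_low_categories(score) if len(spec.snp_ids) == 3 else score
            z_t, p_t = trend_test(_trait_values(cohort, exposure_trait, t_idx), levels)
            trend_rows.append(
                {
                    "direction": direction,
                    "trait": exposure_trait,
                    "stratum": stratum,
                    "z": z_t,
                    "p_value": p_t,
                }
            )
        except (ValueError, KeyError):
            pass

        for model in config.models:
            try:
                rows.extend(
                    _fit_row(
                        cohort,
                        direction,
                        trait,
                        stratum,
                        model,
                        spec,
                        config,
                        idx_stratum,
                        exposure_trait,
                        outcome_trait,
                    )
                )
            except (ValueError, KeyError) as exc:
                rows.extend(
                    _error_rows(direction, trait, stratum, config, str(exc), models=[model])
                )

        # confounder balance once per instrument (crude covariate set)
        try:
            bal_idx = complete_cases(
                _subset(cohort, idx_stratum), pheno_cols=[], snp_ids=list(spec.snp_ids)
            )
            score = _oriented_score(cohort, spec, bal_idx)
            conf_cols = [
                ADJUSTMENT_COLUMNS[a]
                for a in config.adjustment
                if not (a == "sex" and stratum != "overall")
            ]
            conf = cohort.pheno.loc[bal_idx, conf_cols].copy()
            bal = confounder_balance(score, conf)
            bal.insert(0, "stratum", stratum)
            bal.insert(0, "trait", exposure_trait)
            bal.insert(0, "direction", direction)
            balance_rows.append(bal)
        except (ValueError, KeyError):
            pass

    rows_df = pd.DataFrame(rows)
    interactions = _sex_interactions(rows_df, direction, config)
    return DirectionReport(
        direction=direction,
        rows=rows_df,
        instruments=pd.concat(instr_rows, ignore_index=True)
        if instr_rows
        else pd.DataFrame(),
        balance=pd.concat(balance_rows, ignore_index=True)
        if balance_rows
        else pd.DataFrame(),
        trends=pd.DataFrame(trend_rows),
        interactions=interactions,
    )


def _subset(cohort: Cohort, idx: pd.Index) -> Cohort:
    return Cohort(
        cohort.dosages.loc[idx], cohort.pheno.loc[idx], cohort.snp_info, cohort.config
    )


def _oriented_score(cohort: Cohort, spec: InstrumentSpec, idx: pd.Index) -> pd.Series:
    dos = cohort.dosages.loc[idx, list(spec.snp_ids)].copy()
    for snp_id in spec.snp_ids:
        if spec.orientation.get(snp_id, False):
            dos[snp_id] = 2.0 - dos[snp_id]
    return build_score(dos)


def _error_rows(direction, trait, stratum, config, message, models=None) -> list[dict]:
    out = []
    for model in models if models is not None else config.models:
        for method in ("OLS", "2SLS"):
            out.append(
                {
                    "direction": direction,
                    "trait": trait,
                    "stratum": stratum,
                    "model": model,
                    "method": method,
                    "status": f"error: {message}",
                }
            )
    return out


def _fit_row(
    cohort: Cohort,
    direction: str,
    trait: str,
    stratum: str,
    model: str,
    spec: InstrumentSpec,
    config: AnalysisConfig,
    idx_stratum: pd.Index,
    exposure_trait: str,
    outcome_trait: str,
) -> list[dict]:
    required = _required_pheno_cols(direction, trait, model, config.adjustment, stratum)
    idx = complete_cases(
        _subset(cohort, idx_stratum), pheno_cols=required, snp_ids=list(spec.snp_ids)
    )
    exposure = standardize(_trait_values(cohort, exposure_trait, idx))
    outcome = standardize(_trait_values(cohort, outcome_trait, idx))
    score = _oriented_score(cohort, spec, idx).to_numpy()

    cov = None
    if model == "adjusted":
        cov, _ = _covariate_matrix(cohort, idx, config.adjustment, stratum)
        if cov.shape[1] == 0:
            cov = None

    ols = ols_fit(outcome, exposure, covariates=cov, model=model)
    iv, first = tsls_fit(outcome, exposure, score, covariates=cov, model=model)
    haus = durbin_hausman(outcome, exposure, score, covariates=cov)
    # instrument strength is tabulated from the covariate-free first stage;
    # the partial F carries the adjusted-model instrument signal
    crude_first = first_stage_fit(exposure, score)

    base = {
        "direction": direction,
        "trait": trait,
        "stratum": stratum,
        "model": model,
        "status": "ok",
        "snp_ids": "+".join(spec.snp_ids),
        "n": len(idx),
        "first_stage_f": crude_first.f_statistic,
        "first_stage_r2": crude_first.r_squared,
        "first_stage_partial_f": first.partial_f,
        "hausman_p": haus.p_value,
        "weak_instrument": iv.weak_instrument,
    }
    out = []
    for res in (ols, iv):
        row = dict(base)
        row.update(
            method=res.method,
            beta=res.beta,
            se=res.se,
            ci_low=res.ci_low,
            ci_high=res.ci_high,
            p_value=res.p_value,
        )
        out.append(row)
    return out


def _sex_interactions(
    rows: pd.DataFrame, direction: str, config: AnalysisConfig
) -> pd.DataFrame:
    """Sex-difference z per trait/model/method when both sex strata ran."""
    if rows.empty or not {"men", "women"} <= set(config.strata):
        return pd.DataFrame()
    out = []
    ok = rows[rows.get("status", "ok") == "ok"] if "status" in rows else rows
    for (trait, model, method), grp in ok.groupby(["trait", "model", "method"]):
        men = grp[grp["stratum"] == "men"]
        women = grp[grp["stratum"] == "women"]
        if len(men) == 1 and len(women) == 1:
            m, w = men.iloc[0], women.iloc[0]
            if m["se"] > 0 and w["se"] > 0:
                z, p = sex_interaction(m["beta"], m["se"], w["beta"], w["se"])
                out.append(
                    {
                        "direction": direction,
                        "trait": trait,
                        "model": model,
                        "method": method,
                        "z": z,
                        "p_value": p,
                    }
                )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# full bidirectional run
# ---------------------------------------------------------------------------


def run_bidirectional(
    cohort: Cohort, config: AnalysisConfig = AnalysisConfig()
) -> dict:
    """QC the cohort, run every requested direction, and bundle the outputs.

    Returns a dict with per-direction reports, a combined instrument summary
    (trait, stratum, SNPs, F, R-squared), QC reports, and a run log
    (seed, package version, sample/SNP counts).
    """
    clean, qc_reports = qc_cohort(cohort, config.qc)
    reports = {d: run_direction(clean, d, config) for d in config.directions}
    instrument_table = pd.concat(
        [
            r.instruments.groupby(["trait", "stratum"], sort=False).head(1)
            for r in reports.values()
            if not r.instruments.empty
        ],
        ignore_index=True,
    ) if any(not r.instruments.empty for r in reports.values()) else pd.DataFrame()
    log = {
        "package_version": bimr.__version__,
        "seed": config.seed,
        "n_samples_input": int(cohort.n_samples),
        "n_samples_after_qc": int(clean.n_samples),
        "n_snps_input": int(cohort.dosages.shape[1]),
        "n_snps_after_qc": int(clean.dosages.shape[1]),
    }
    return {
        "directions": reports,
        "instrument_table": instrument_table,
        "qc": qc_reports,
        "log": log,
    }


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _df_records(df: pd.DataFrame) -> list[dict]:
    if df.empty:
        return []
    return json.loads(df.to_json(orient="records", double_precision=12))


def bundle_to_json(bundle: Mapping) -> str:
    """Deterministic JSON rendering of a run_bidirectional bundle."""
    payload = {"log": dict(bundle["log"]), "directions": {}}
    payload["instrument_table"] = _df_records(bundle["instrument_table"])
    for name, rep in bundle["directions"].items():
        payload["directions"][name] = {
            "rows": _df_records(rep.rows),
            "instruments": _df_records(rep.instruments),
            "balance": _df_records(rep.balance),
            "trends": _df_records(rep.trends),
            "interactions": _df_records(rep.interactions),
        }
    return json.dumps(payload, indent=2, sort_keys=True)


def write_report(bundle: Mapping, out_dir) -> dict[str, str]:
    """Write the JSON bundle plus per-direction TSV tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    json_path = out / "results.json"
    json_path.write_text(bundle_to_json(bundle))
    paths["json"] = str(json_path)
    for name, rep in bundle["directions"].items():
        for kind in ("rows", "instruments", "balance", "trends", "interactions"):
            df = getattr(rep, kind)
            if df is None or df.empty:
                continue
            p = out / f"{name}.{kind}.tsv"
            df.to_csv(p, sep="\t", index=False, float_format="%.6g")
            paths[f"{name}.{kind}"] = str(p)
    if not bundle["instrument_table"].empty:
        p = out / "instruments.tsv"
        bundle["instrument_table"].to_csv(p, sep="\t", index=False, float_format="%.6g")
        paths["instruments"] = str(p)
    return paths
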