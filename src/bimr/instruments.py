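"""Allele-score instruments: orientation, construction, strength and search.

A genetic instrument here is either a single SNP or an unweighted additive
score over k SNPs, each SNP first oriented so the counted allele associates
with higher values of the target trait (the operational definition of a
"risk allele"). Instrument strength is summarized by the first-stage
regression F-statistic, with F > 10 as the conventional adequacy threshold;
the best k-SNP combination is found by exhaustive enumeration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

WEAK_F_THRESHOLD = 10.0


@dataclass(frozen=True)
class FirstStageFit:
    """Summary of the instrument -> exposure regression."""

    slope: float
    r_squared: float
    f_statistic: float
    n: int
    partial_f: float | None = None  # instrument-block F when covariates present

    @property
    def weak(self) -> bool:
        return not self.f_statistic > WEAK_F_THRESHOLD


@dataclass(frozen=True)
class InstrumentSpec:
    """An oriented SNP set defining one instrument for one trait/stratum."""

    trait: str
    stratum: str
    snp_ids: tuple[str, ...]
    orientation: Mapping[str, bool]  # snp_id -> dosage was flipped (2 - d)
    score_type: str = "additive_score"

    def __post_init__(self) -> None:
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))
        if len(self.snp_ids) < 1:
            raise ValueError("instrument needs at least one SNP")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("instrument SNP ids must be distinct")
        if self.score_type not in ("single_snp", "additive_score"):
            raise ValueError(f"unknown score_type {self.score_type!r}")


# ---------------------------------------------------------------------------
# orientation and scoring
# ---------------------------------------------------------------------------


def orient_risk_alleles(
    dosages: pd.DataFrame, trait: np.ndarray | pd.Series
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Flip each SNP's coding (d -> 2 - d) if its in-sample slope on the trait
    is negative, so dosage counts the trait-raising allele.

    A zero slope keeps the input orientation. Orienting twice is a no-op.
    """
    y = np.asarray(trait, dtype=float)
    oriented = dosages.copy()
    flipped: dict[str, bool] = {}
    for snp_id in dosages.columns:
        d = dosages[snp_id].to_numpy(dtype=float)
        ok = ~np.isnan(d) & ~np.isnan(y)
        dd = d[ok]
        if len(np.unique(dd)) < 2:
            raise ValueError(f"{snp_id} is monomorphic in this sample; QC should drop it")
        slope = np.cov(dd, y[ok])[0, 1]  # sign equals the regression slope sign
        flip = slope < 0.0
        if flip:
            oriented[snp_id] = 2.0 - d
        flipped[snp_id] = bool(flip)
    return oriented, flipped


def build_score(oriented: pd.DataFrame) -> pd.Series:
    """Unweighted sum of oriented dosages: integer score in [0, 2k].

    With k = 3 this is the seven-category 0-6 allele score. Missing dosages
    must be removed upstream (complete-case selection)."""
    if oriented.isna().any().any():
        raise ValueError("missing dosages: apply complete-case selection first")
    score = oriented.sum(axis=1)
    return score.astype(float)


def collapse_low_categories(scores, merge_max: int = 2) -> pd.Series:
    """Merge sparse low score categories (default 0, 1, 2) into one level.

    Returns an ordered level per sample, with merged scores mapped to
    ``merge_max`` so ordering is preserved. Intended for trend displays;
    two-stage least squares always uses the raw score."""
    s = pd.Series(np.asarray(scores, dtype=float))
    if ((s < 0) | (s > 6)).any():
        raise ValueError("scores must lie in 0..6")
    return s.clip(lower=merge_max)


# ---------------------------------------------------------------------------
# first-stage statistics
# ---------------------------------------------------------------------------


def _design(x: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    cols = [np.ones_like(x), x]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != len(x):
            raise ValueError("covariates must have one row per observation")
        cols.extend(cov.T)
    return np.column_stack(cols)


def first_stage_fit(
    exposure: np.ndarray | pd.Series,
    instrument: np.ndarray | pd.Series,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> FirstStageFit:
    """Least-squares fit of the exposure on the instrument (+ covariates).

    ``f_statistic`` is the overall regression F; for the single-regressor
    crude fit it satisfies F = R2 (n-2) / (1 - R2) exactly. With covariates
    the partial F for the instrument term is reported as well.
    """
    y = np.asarray(exposure, dtype=float)
    z = np.asarray(instrument, dtype=float)
    X = _design(z, None if covariates is None else np.asarray(covariates, dtype=float))
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > {p + 1} observations, got {n}")
    beta, rss, tss = _lstsq_rss(X, y)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    k = p - 1  # regressors excluding intercept
    if rss <= tss * 1e-14:
        f = np.inf
    else:
        f = (r2 / k) / ((1.0 - r2) / (n - p))
    partial_f = None
    if covariates is not None:
        X0 = np.delete(X, 1, axis=1)
        _, rss0, _ = _lstsq_rss(X0, y)
        partial_f = float((rss0 - rss) / (rss / (n - p)))
    return FirstStageFit(
        slope=float(beta[1]),
        r_squared=float(r2),
        f_statistic=float(f),
        n=int(n),
        partial_f=partial_f,
    )


def _lstsq_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    return beta, rss, tss


# ---------------------------------------------------------------------------
# systematic combination search
# ---------------------------------------------------------------------------


def search_best_instrument(
    dosages: pd.DataFrame,
    exposure: np.ndarray | pd.Series,
    k: int = 3,
    trait: str = "trait",
    stratum: str = "overall",
    candidates: Sequence[str] | None = None,
) -> tuple[InstrumentSpec, FirstStageFit, pd.DataFrame]:
    """Exhaustive search over all C(m, k) SNP combinations for the best score.

    Candidates are pooled with no per-gene quota (the best triple may sit in a
    single gene). Per combination the SNPs are oriented on the trait, summed
    into a score and fitted; the combination with the largest first-stage F
    wins, ties broken by lexicographic snp_id order. Samples are restricted
    per combination to those complete on its SNPs and the exposure.

    Returns the winning spec, its fit, and the full search table.
    """
    cand = sorted(candidates if candidates is not None else dosages.columns)
    if len(cand) < k:
        raise ValueError(f"need at least k={k} candidates, got {len(cand)}")
    y_all = np.asarray(exposure, dtype=float)
    rows = []
    best: tuple[InstrumentSpec, FirstStageFit] | None = None
    for combo in itertools.combinations(cand, k):
        sub = dosages[list(combo)]
        ok = sub.notna().all(axis=1).to_numpy() & ~np.isnan(y_all)
        sub = sub.loc[ok]
        y = y_all[ok]
        try:
            oriented, flips = orient_risk_alleles(sub, y)
        except ValueError:
            continue  # monomorphic within this complete-case subset
        score = build_score(oriented)
        fit = first_stage_fit(y, score)
        rows.append(
            {
                "snp_ids": "+".join(combo),
                "f_statistic": fit.f_statistic,
                "r_squared": fit.r_squared,
                "n": fit.n,
            }
        )
        spec = InstrumentSpec(
            trait=trait,
            stratum=stratum,
            snp_ids=combo,
            orientation=flips,
            score_type="single_snp" if k == 1 else "additive_score",
        )
        if best is None or fit.f_statistic > best[1].f_statistic:
            best = (spec, fit)
    if best is None:
        raise ValueError("no polymorphic combination found")
    table = pd.DataFrame(rows).sort_values(
        ["f_statistic", "snp_ids"], ascending=[False, True], kind="mergesort"
    )
    return best[0], best[1], table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# trend test and confounder balance
# ---------------------------------------------------------------------------


def trend_test(values, levels) -> tuple[float, float]:
    """Wilcoxon-type test for trend across ordered groups (Cuzick, 1985).

    ``levels`` gives each observation's ordered group score. Returns the
    standardized z statistic and its two-sided normal p-value; reversing the
    level order flips the sign of z.
    """
    y = np.asarray(values, dtype=float)
    lv = np.asarray(levels, dtype=float)
    ok = ~np.isnan(y) & ~np.isnan(lv)
    y, lv = y[ok], lv[ok]
    uniq = np.unique(lv)
    if len(uniq) < 2:
        raise ValueError("need at least two ordered groups")
    n = len(y)
    ranks = stats.rankdata(y)
    t_stat = float((lv * ranks).sum())
    l_sum = float(lv.sum())
    e_t = 0.5 * (n + 1) * l_sum
    # tie-corrected variance of the rank sum
    _, counts = np.unique(y, return_counts=True)
    tie_correction = 1.0 - (counts**3 - counts).sum() / float(n**3 - n)
    var_t = (n + 1) / 12.0 * (n * float((lv**2).sum()) - l_sum**2) * tie_correction
    if var_t <= 0:
        raise ValueError("degenerate trend test: zero variance")
    z = (t_stat - e_t) / np.sqrt(var_t)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def confounder_balance(
    instrument: np.ndarray | pd.Series,
    confounders: pd.DataFrame,
    categorical_max_levels: int = 4,
) -> pd.DataFrame:
    """Association screen of an instrument against potential confounders.

    Continuous confounders are regressed on the instrument (slope + t-test p);
    categorical ones (few distinct values, or non-numeric) get a chi-square
    test of independence over instrument levels. No verdict is applied: the
    report simply flags small p-values for inspection.
    """
    z = np.asarray(instrument, dtype=float)
    rows = []
    for col in confounders.columns:
        v = confounders[col]
        numeric = pd.api.types.is_numeric_dtype(v)
        vals = pd.to_numeric(v, errors="coerce") if numeric else v
        ok = ~np.isnan(z) & v.notna().to_numpy()
        if numeric and v.dropna().nunique() > categorical_max_levels:
            fit = first_stage_fit(vals.to_numpy(dtype=float)[ok], z[ok])
            est = fit.slope
            p = float(stats.f.sf(fit.f_statistic, 1, fit.n - 2))
            kind = "continuous"
        else:
            table = pd.crosstab(pd.Series(z[ok]).round(6), v[ok])
            if table.shape[0] < 2 or table.shape[1] < 2:
                est, p, kind = np.nan, 1.0, "degenerate"
            else:
                chi2, p, _, _ = stats.chi2_contingency(table)
                est, kind = float(chi2), "categorical"
        rows.append({"confounder": col, "kind": kind, "estimate": est, "p_value": p})
    return pd.DataFrame(rows, columns=["confounder", "kind", "estimate", "p_value"])
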