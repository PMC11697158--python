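"""Bulk-cohort signature scoring and survival stratification.

A sample's signature score is the mean of per-gene Z-scores (each gene
standardised across samples) over the signature genes.  Samples are
stratified at the within-cancer-type median, compared by Kaplan-Meier /
log-rank, and the continuous score is tested in a Cox proportional-hazards
model with tumour type (as strata by default), purity, stage and age as
covariates, with Benjamini-Hochberg adjustment across the coefficient
family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.stats.multitest import multipletests

from .simulate import BulkCohortData

logger = logging.getLogger("metasig")

DEFAULT_COVARIATES = ("purity", "stage", "age")


@dataclass
class CoxFit:
    beta: pd.Series
    se: pd.Series
    hazard_ratio: pd.Series
    wald_p: pd.Series
    adjusted_p: pd.Series
    n_events: int
    converged: bool
    log_likelihood: float


@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]
    medians: dict[str, float]
    statistic: float
    p: float


def signature_zscore(c: BulkCohortData, genes: list[str]) -> pd.Series:
    """Average gene-level Z score over signature genes, per sample."""
    present = [g for g in genes if g in c.log_expr.columns]
    if not present:
        raise KeyError("no signature gene found in the cohort expression")
    if len(c.log_expr) < 2:
        raise ValueError("need at least 2 samples")
    expr = c.log_expr[present]
    sd = expr.std(ddof=0)
    usable = sd[sd > 0].index
    if len(usable) < len(present):
        logger.warning("signature_zscore: dropped %d zero-variance genes",
                       len(present) - len(usable))
    if usable.empty:
        raise ValueError("every signature gene is constant across samples")
    z = (expr[usable] - expr[usable].mean()) / sd[usable]
    return z.mean(axis=1).rename("score")


def stratify_median(scores: pd.Series, cancer_type: pd.Series) -> pd.Series:
    """Label samples high/low at the within-cancer-type median score."""
    labels = pd.Series("low", index=scores.index, name="stratum")
    for ct, grp in scores.groupby(cancer_type):
        med = grp.median()
        if (grp > med).sum() == 0:
            logger.warning("stratify_median: no sample above median in %s", ct)
        labels.loc[grp.index[grp > med]] = "high"
    return labels


def cox_fit(
    c: BulkCohortData,
    score: pd.Series,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    strata_col: str | None = "cancer_type",
    tumour_type_as_dummies: bool = False,
) -> CoxFit:
    """Cox proportional-hazards fit of survival on the continuous score.

    Tumour type enters as stratification (separate baseline hazards) by
    default; ``tumour_type_as_dummies`` switches it to dummy coding.  Wald
    p-values are BH-adjusted across the coefficient family.
    """
    clin = c.clinical
    if "tissue" in clin.columns:
        clin = clin[clin["tissue"] == "tumour"]
    df = clin[["time", "event", *covariates]].copy()
    df["score"] = score.reindex(df.index)
    strata = None
    if strata_col and strata_col in clin.columns:
        if tumour_type_as_dummies:
            df = df.join(pd.get_dummies(clin[strata_col], prefix=strata_col,
                                        drop_first=True, dtype=float))
        else:
            df[strata_col] = clin[strata_col]
            strata = strata_col
    n_events = int(df["event"].sum())
    if n_events < 10:
        raise ValueError(f"only {n_events} events; need at least 10")

    cph = CoxPHFitter()
    converged = True
    try:
        cph.fit(df, duration_col="time", event_col="event", strata=strata)
    except Exception as exc:  # convergence / separation diagnostics
        logger.warning("cox_fit did not converge cleanly: %s", exc)
        cph.fit(df, duration_col="time", event_col="event", strata=strata,
                robust=True)
        converged = False
    summary = cph.summary
    adjusted = pd.Series(
        multipletests(summary["p"].to_numpy(), method="fdr_bh")[1],
        index=summary.index,
    )
    return CoxFit(
        beta=summary["coef"],
        se=summary["se(coef)"],
        hazard_ratio=summary["exp(coef)"],
        wald_p=summary["p"],
        adjusted_p=adjusted,
        n_events=n_events,
        converged=converged,
        log_likelihood=float(cph.log_likelihood_),
    )


def km_logrank(time: pd.Series, event: pd.Series, group: pd.Series) -> KMResult:
    """Kaplan-Meier curves per group and the log-rank test across groups."""
    groups = pd.unique(group)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if int(pd.Series(event).sum()) < 1:
        raise ValueError("need at least 1 event")
    curves, medians = {}, {}
    for g in groups:
        mask = (group == g).to_numpy()
        if not mask.any():
            raise ValueError(f"group {g!r} has no subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(np.asarray(time)[mask], np.asarray(event)[mask], label=str(g))
        curves[str(g)] = kmf.survival_function_
        medians[str(g)] = float(kmf.median_survival_time_)
    res = multivariate_logrank_test(time, group, event)
    return KMResult(curves, medians, float(res.test_statistic), float(res.p_value))


def group_compare(
    scores: pd.Series,
    tissue: pd.Series,
    cancer_type: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided rank-sum test (tumour > normal) per cancer type, BH-adjusted.

    Returns one row per testable cancer type with statistic, p, q and a
    ``significant`` flag at q < ``alpha``; types lacking a tissue are
    skipped with a warning.
    """
    rows = []
    for ct in sorted(pd.unique(cancer_type)):
        mask = cancer_type == ct
        t = scores[mask & (tissue == "tumour")]
        n = scores[mask & (tissue == "normal")]
        if t.empty or n.empty:
            logger.warning("group_compare: %s lacks a tissue; skipped", ct)
            continue
        method = "exact" if min(len(t), len(n)) <= 8 else "asymptotic"
        stat, p = scipy.stats.mannwhitneyu(t, n, alternative="greater",
                                           method=method)
        rows.append({"cancer_type": ct, "statistic": stat, "p": p,
                     "n_tumour": len(t), "n_normal": len(n)})
    out = pd.DataFrame(rows).set_index("cancer_type")
    if out.empty:
        raise ValueError("no cancer type had both tissues")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = out["q"] < alpha
    return out


def stage_correlation(scores: pd.Series, stage: pd.Series,
                      cut: int = 3) -> float:
    """Point-biserial correlation between score and late stage (>= ``cut``)."""
    late = (pd.Series(stage).astype(float) >= cut).astype(float)
    if late.nunique() < 2:
        raise ValueError("both stage groups must be present")
    if pd.Series(scores).nunique() < 2:
        logger.warning("stage_correlation: constant scores; correlation undefined")
        return float("nan")
    r, _ = scipy.stats.pearsonr(scores, late)
    return float(r)
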