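"""Per-cell metastatic staging and pseudobulk differential expression.

Cells scored with the refined signature are discretised into 16 equal-width
bins and categorised low / mid / high by the bottom 20% / middle 60% /
top 20% of scores.  Differential expression between high and low cells is
assessed at the pseudobulk level: counts are summed per (sample, category)
and compared with a Welch two-sample t-test on log2-CPM.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix
from .scoring import ScoreVector

logger = logging.getLogger("metasig")

DEFAULT_N_BINS = 16
DEFAULT_Q_LOW = 0.2
DEFAULT_Q_HIGH = 0.8


def assign_stages(
    scores: ScoreVector,
    n_bins: int = DEFAULT_N_BINS,
    q_low: float = DEFAULT_Q_LOW,
    q_high: float = DEFAULT_Q_HIGH,
) -> pd.DataFrame:
    """Assign each cell a bin (1..n_bins) and a low/mid/high category.

    Bins are equal-width over [min, max] with half-open intervals (last bin
    closed).  Categories follow empirical quantiles -- bottom ``q_low`` low,
    top ``1 - q_high`` high -- with boundary ties resolved toward mid, so
    the partition is always monotone in score.
    """
    s = np.asarray(scores.score, float)
    n = s.size
    if n < 10:
        raise ValueError("need at least 10 cells to stage")
    if not 0.0 < q_low < q_high < 1.0:
        raise ValueError("need 0 < q_low < q_high < 1")

    lo, hi = s.min(), s.max()
    degenerate = hi - lo <= 0
    if degenerate:
        bins = np.ones(n, int)
        logger.warning("assign_stages: all scores identical; all cells staged mid")
    else:
        bins = np.minimum((s - lo) / (hi - lo) * n_bins, n_bins - 1).astype(int) + 1

    category = np.full(n, "mid", dtype=object)
    if not degenerate:
        srt = np.sort(s)
        n_low = int(round(q_low * n))
        n_high = int(round((1.0 - q_high) * n))
        if n_low > 0:
            category[s < srt[n_low]] = "low"
        if n_high > 0:
            category[s > srt[n - n_high - 1]] = "high"
    return pd.DataFrame(
        {"cell_id": scores.unit, "score": s, "bin": bins, "category": category}
    ).set_index("cell_id")


def pseudobulk(
    m: CountMatrix,
    stages: pd.DataFrame,
    group_by: str = "sample_id",
) -> pd.DataFrame:
    """Sum counts per (sample, category); genes x (sample, category) frame.

    The total of every pseudobulk column equals the total counts of the
    cells it aggregates, and each category must be observed in at least
    two samples for downstream testing.  Cells without a stage assignment
    (e.g. removed upstream by QC before scoring) are ignored.
    """
    staged = [c for c in m.cells if c in stages.index]
    if len(staged) < len(m.cells):
        logger.info("pseudobulk: %d cells lack a stage assignment; ignored",
                    len(m.cells) - len(staged))
        keep = np.isin(m.cells, staged)
        m = m.subset(np.ones(len(m.genes), bool), keep)
    meta = m.cell_meta
    cats = stages.loc[m.cells, "category"].to_numpy()
    groups = meta[group_by].astype(str).to_numpy()
    cols: dict[tuple[str, str], np.ndarray] = {}
    for sample in pd.unique(groups):
        for cat in ("low", "mid", "high"):
            mask = (groups == sample) & (cats == cat)
            if mask.any():
                cols[(sample, cat)] = np.asarray(
                    m.counts[:, mask].sum(axis=1)
                ).ravel().astype(np.int64)
    pb = pd.DataFrame(cols, index=m.genes)
    pb.columns = pd.MultiIndex.from_tuples(pb.columns, names=[group_by, "category"])
    for cat in ("low", "high"):
        n_samples = sum(1 for c in pb.columns if c[1] == cat)
        if 0 < n_samples < 2:
            raise ValueError(f"category {cat!r} present in only {n_samples} sample")
    return pb


def pseudobulk_de(
    pb: pd.DataFrame,
    contrast: tuple[str, str] = ("high", "low"),
) -> pd.DataFrame:
    """Welch t-test per gene on log2-CPM(+1) pseudobulk profiles.

    Returns gene, log2_fc (first contrast level minus second), statistic,
    p and BH-adjusted q.  Genes with zero variance on both sides and equal
    means get p = 1; unequal constant groups get p = 0.
    """
    a_cols = [c for c in pb.columns if c[1] == contrast[0]]
    b_cols = [c for c in pb.columns if c[1] == contrast[1]]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("need at least 2 pseudobulk samples per side")
    logcpm = np.log2(1.0 + 1e6 * pb / pb.sum(axis=0))
    a = logcpm[a_cols].to_numpy()
    b = logcpm[b_cols].to_numpy()
    stat, p = scipy.stats.ttest_ind(a, b, axis=1, equal_var=False)
    log2_fc = a.mean(axis=1) - b.mean(axis=1)
    nan = ~np.isfinite(p)
    p = np.where(nan, np.where(np.abs(log2_fc) < 1e-12, 1.0, 0.0), p)
    stat = np.where(np.isfinite(stat), stat, 0.0)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"log2_fc": log2_fc, "statistic": stat, "p": p, "q": q},
        index=pb.index,
    ).rename_axis("gene")
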