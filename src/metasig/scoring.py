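"""Rank-based gene-set scoring of cells, spots or profiles.

The score is built on the Mann-Whitney U statistic of a gene set's
expression ranks within a single unit (cell, spot or pseudo-profile):
genes are ranked by decreasing expression, ranks beyond a cap ``r_max``
are truncated to ``r_max + 1``, and

    U'(u)    = sum_{g in set} rank(g, u) - n_g (n_g + 1) / 2
    score(u) = max(0, 1 - U'(u) / (n_g * r_max))

The score lies in [0, 1], depends only on within-unit ranks (any monotone
transform of expression gives the same result) and is unaffected by which
other units are present in the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .io import LogNormMatrix

#: default rank cap; ranks deeper than this carry no signal for a
#: transcriptome-wide unit and are truncated to r_max + 1
DEFAULT_R_MAX = 1500


@dataclass
class GeneSet:
    """A named gene list with an evidence tier."""

    name: str
    genes: list[str]
    tier: str = "derived"  # single-evidence | multi-evidence | derived

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate genes")


@dataclass
class ScoreVector:
    """Per-unit scores in [0, 1] plus the parameters that produced them."""

    unit: list[str]
    score: np.ndarray
    r_max: int
    n_g_used: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"unit_id": self.unit, "score": self.score, "n_genes_used": self.n_g_used}
        )


def relative_ranks(values: np.ndarray, r_max: int) -> np.ndarray:
    """Rank one unit's expression in decreasing order with mean-tie ranks,
    truncating any rank greater than ``r_max`` to ``r_max + 1``."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite expression values")
    if r_max < 1:
        raise ValueError("r_max must be >= 1")
    ranks = scipy.stats.rankdata(-values, method="average")
    return np.where(ranks > r_max, r_max + 1.0, ranks)


def _rank_matrix(values: np.ndarray, r_max: int) -> np.ndarray:
    """Column-wise decreasing ranks with mean ties and the r_max cap.

    ``values`` is genes x units; returns an array of the same shape.
    """
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite expression values")
    ranks = scipy.stats.rankdata(-values, method="average", axis=0)
    np.minimum(ranks, r_max + 1.0, out=ranks)
    return ranks


def set_score(
    m: LogNormMatrix,
    s: GeneSet,
    r_max: int = DEFAULT_R_MAX,
) -> ScoreVector:
    """Score every unit of ``m`` for gene set ``s``.

    Only signature genes present in the matrix contribute; an empty
    intersection is an error.  Scores for one unit never depend on the
    other units in the matrix.
    """
    gene_index = {g: i for i, g in enumerate(m.genes)}
    present = [g for g in s.genes if g in gene_index]
    if not present:
        missing = [g for g in s.genes if g not in gene_index]
        raise KeyError(
            f"no gene of set {s.name!r} found in the matrix; missing e.g. {missing[:10]}"
        )
    if len(m.genes) < 2:
        raise ValueError("units must have at least 2 genes")
    return _score_dense(m.dense(), [gene_index[g] for g in present],
                        list(m.cells), r_max)


def score_profiles(
    profiles: pd.DataFrame,
    s: GeneSet,
    r_max: int = DEFAULT_R_MAX,
) -> ScoreVector:
    """Score arbitrary genes x profiles values (e.g. archetype footprints)."""
    present = [g for g in s.genes if g in profiles.index]
    if not present:
        raise KeyError(f"no gene of set {s.name!r} found among the profiles")
    idx = profiles.index.get_indexer(present)
    return _score_dense(profiles.to_numpy(float), list(idx),
                        [str(c) for c in profiles.columns], r_max)


def _score_dense(
    values: np.ndarray, sig_rows: list[int], units: list[str], r_max: int
) -> ScoreVector:
    ranks = _rank_matrix(values, r_max)
    n_g = len(sig_rows)
    u_prime = ranks[sig_rows].sum(axis=0) - n_g * (n_g + 1) / 2.0
    score = np.maximum(0.0, 1.0 - u_prime / (n_g * r_max))
    return ScoreVector(units, score, r_max, n_g)
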