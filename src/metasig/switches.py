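"""Switch-time ordering of genes along a pseudotime trajectory.

Expression is binarised at a fixed cutoff (0.2 on the log-normalised
scale) and each gene's on/off state is regressed on pseudotime with a
logistic model fitted by iteratively reweighted least squares.  The switch
time is the pseudotime where the fitted probability crosses 0.5
(t* = -beta0 / beta1), the direction is the sign of the slope, and fit
quality is McFadden's pseudo-R^2.  Genes are ranked by pseudo-R^2 and laid
out on a timeline by switch time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_CUTOFF = 0.2
DEFAULT_TOP_N = 50
MAX_ITER = 100
TOL = 1e-8
#: |beta1| beyond this is treated as complete separation
SEPARATION_CAP = 500.0


@dataclass
class SwitchFit:
    gene: str
    beta0: float
    beta1: float
    switch_time: float | None
    direction: str | None  # on | off
    pseudo_r2: float | None
    flags: set[str] = field(default_factory=set)
    log_likelihood: list[float] = field(default_factory=list)


def binarize(values: pd.DataFrame | np.ndarray, cutoff: float = DEFAULT_CUTOFF):
    """On/off states: on iff expression >= cutoff (boundary maps to on)."""
    return values >= cutoff


def fit_switch(
    states: np.ndarray,
    pseudotime: np.ndarray,
    gene: str = "",
) -> SwitchFit:
    """Logistic fit of a gene's binary state on pseudotime.

    IRLS with step-halving so the log-likelihood never decreases; complete
    separation (diverging slope) is flagged and reported with
    pseudo-R^2 = 1.  A gene observed in a single state is degenerate and
    gets no fit.
    """
    y = np.asarray(states, float).ravel()
    t = np.asarray(pseudotime, float).ravel()
    if y.size != t.size:
        raise ValueError("states and pseudotime differ in length")
    if y.size < 20:
        raise ValueError("need at least 20 cells")
    if np.ptp(t) == 0:
        raise ValueError("pseudotime is constant")
    if y.min() == y.max():
        return SwitchFit(gene, np.nan, np.nan, None, None, None, {"degenerate"})

    x = np.column_stack([np.ones_like(t), t])
    beta = np.zeros(2)
    ll = _loglik(x, y, beta)
    history = [ll]
    for _ in range(MAX_ITER):
        p = _sigmoid(x @ beta)
        w = np.maximum(p * (1.0 - p), 1e-10)
        grad = x.T @ (y - p)
        hess = x.T @ (x * w[:, None])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        # step-halving keeps the log-likelihood non-decreasing
        factor = 1.0
        for _ in range(40):
            cand = beta + factor * step
            ll_new = _loglik(x, y, cand)
            if ll_new >= ll:
                break
            factor /= 2.0
        else:
            break
        beta, improved = cand, ll_new - ll
        ll = ll_new
        history.append(ll)
        if improved < TOL and np.max(np.abs(factor * step)) < 1e-6:
            break
        if abs(beta[1]) > SEPARATION_CAP:
            break

    flags: set[str] = set()
    p_null = y.mean()
    ll0 = y.sum() * np.log(p_null) + (y.size - y.sum()) * np.log(1.0 - p_null)
    pseudo_r2 = 1.0 - ll / ll0 if ll0 < 0 else 0.0
    if abs(beta[1]) > SEPARATION_CAP or pseudo_r2 > 1.0 - 1e-9:
        flags.add("separation")
        pseudo_r2 = 1.0
    pseudo_r2 = float(np.clip(pseudo_r2, 0.0, 1.0))

    direction = "on" if beta[1] > 0 else "off" if beta[1] < 0 else None
    t_star: float | None = None
    if beta[1] != 0:
        t_star = float(-beta[0] / beta[1])
        if not t.min() <= t_star <= t.max():
            flags.add("out_of_range")
    return SwitchFit(gene, float(beta[0]), float(beta[1]), t_star, direction,
                     pseudo_r2, flags, history)


def fit_switches(
    matrix: pd.DataFrame,
    pseudotime: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
) -> list[SwitchFit]:
    """Binarise a genes x cells matrix and fit every gene."""
    states = binarize(matrix.to_numpy(float), cutoff)
    fits = []
    for i, gene in enumerate(matrix.index):
        row = states[i]
        if row.min() == row.max():
            fits.append(SwitchFit(str(gene), np.nan, np.nan, None, None, None,
                                  {"degenerate"}))
        else:
            fits.append(fit_switch(row, pseudotime, gene=str(gene)))
    return fits


def rank_switches(fits: list[SwitchFit], top_n: int = DEFAULT_TOP_N) -> pd.DataFrame:
    """Rank non-degenerate fits by pseudo-R^2 (then |slope|) and lay the
    top ``top_n`` out on a timeline ordered by switch time."""
    usable = [f for f in fits if "degenerate" not in f.flags and f.pseudo_r2 is not None]
    if not usable:
        raise ValueError("no non-degenerate switch fit to rank")
    usable.sort(key=lambda f: (-f.pseudo_r2, -abs(f.beta1), f.gene))
    top = usable[:top_n]
    df = pd.DataFrame(
        {
            "gene": [f.gene for f in top],
            "switch_time": [f.switch_time for f in top],
            "direction": [f.direction for f in top],
            "pseudo_r2": [f.pseudo_r2 for f in top],
            "beta1": [f.beta1 for f in top],
            "flags": [",".join(sorted(f.flags)) for f in top],
            "confidence_rank": np.arange(1, len(top) + 1),
        }
    )
    return df.sort_values("switch_time", na_position="last").reset_index(drop=True)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -700, 700)))


def _loglik(x: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = x @ beta
    # log(1 + exp(eta)) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())
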