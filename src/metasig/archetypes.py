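"""Per-patient archetypal analysis of single-cell expression.

Cells are first reduced to a low-dimensional PCA embedding of
gene-standardised log expression, then decomposed by principal-convex-hull
archetypal analysis: each archetype is a convex combination of cells and
each cell a convex combination of archetypes, fitted by alternating
projected-gradient minimisation of the reconstruction error

    RSS = || X - A B X ||_F^2 ,   rows of A and B on the simplex,

from a furthest-sum initialisation.  The archetype count is chosen by the
elbow of the RSS-vs-k curve.  Each archetype finally yields a gene
"footprint" (loading-weighted mean expression, z-scored across archetypes)
whose top genes constitute the archetype's expression program.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import LogNormMatrix

DEFAULT_REDUCED_DIM = 20
DEFAULT_K_MAX = 10
DEFAULT_MIN_CELLS_PER_ARCH = 5
DEFAULT_TOP_M = 200


class DegeneracyError(ValueError):
    """Raised when the input has no usable variation."""


@dataclass
class ReducedEmbedding:
    cells: list[str]
    coordinates: np.ndarray  # cells x d
    explained_variance: np.ndarray


@dataclass
class ArchetypeModel:
    k: int
    archetype_coords: np.ndarray  # k x d
    cell_loadings: np.ndarray  # cells x k, simplex rows
    archetype_weights: np.ndarray  # k x cells, simplex rows (B)
    rss: float
    rss_history: list[float]
    cells_per_archetype: np.ndarray
    converged: bool


@dataclass
class ArchetypeProgram:
    archetype_id: str
    footprint: pd.Series  # per-gene z-scored footprint
    member_genes: list[str]
    degenerate: bool = False


# ---------------------------------------------------------------------------
# PCA reduction
# ---------------------------------------------------------------------------

def reduce_pca(m: LogNormMatrix, d: int = DEFAULT_REDUCED_DIM) -> ReducedEmbedding:
    """Top-``d`` principal-component scores of gene-standardised expression.

    Genes with zero variance carry no information and are dropped before
    standardisation; a matrix with no variable gene is degenerate.
    """
    x = m.dense()  # genes x cells
    n_cells = x.shape[1]
    if n_cells <= d:
        d = max(2, n_cells - 1)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    variable = sd.ravel() > 0
    if not variable.any():
        raise DegeneracyError("all genes are constant; nothing to embed")
    z = (x[variable] - mu[variable]) / sd[variable]
    d = min(d, int(variable.sum()), n_cells)
    pca = PCA(n_components=d, svd_solver="auto", random_state=0)
    coords = pca.fit_transform(z.T)  # cells x d
    return ReducedEmbedding(list(m.cells), coords, pca.explained_variance_)


# ---------------------------------------------------------------------------
# principal convex hull fitting
# ---------------------------------------------------------------------------

def _project_simplex_rows(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row of ``v`` onto the probability simplex."""
    n, k = v.shape
    u = np.sort(v, axis=1)[:, ::-1]
    css = np.cumsum(u, axis=1) - 1.0
    ind = np.arange(1, k + 1)
    cond = u - css / ind > 0
    rho = k - np.argmax(cond[:, ::-1], axis=1) - 1  # last True index
    theta = css[np.arange(n), rho] / (rho + 1.0)
    return np.maximum(v - theta[:, None], 0.0)


def _furthest_sum(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Furthest-sum seeding: greedily pick k mutually distant cells."""
    n = x.shape[0]
    sq = np.einsum("ij,ij->i", x, x)

    def dists(j: int) -> np.ndarray:
        return np.sqrt(np.maximum(sq + sq[j] - 2.0 * (x @ x[j]), 0.0))

    idx = [int(rng.integers(n))]
    total = np.zeros(n)  # sum of distances to idx[:-1]
    while len(idx) < k:
        total += dists(idx[-1])
        cand = total.copy()
        cand[idx] = -np.inf
        idx.append(int(np.argmax(cand)))
    if k >= 2:
        # the first seed was arbitrary: re-pick it as the point furthest
        # from the k-1 greedy picks
        total += dists(idx[-1])
        total -= dists(idx[0])
        total[idx[1:]] = -np.inf
        idx[0] = int(np.argmax(total))
    return np.asarray(idx)


def _rss(x: np.ndarray, a: np.ndarray, z: np.ndarray) -> float:
    r = a @ z - x
    return float(np.einsum("ij,ij->", r, r))


def fit_archetypes(
    e: ReducedEmbedding,
    k: int,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
    min_cells_per_arch: int = DEFAULT_MIN_CELLS_PER_ARCH,
) -> ArchetypeModel:
    """Fit ``k`` archetypes by alternating projected gradient descent.

    The objective is non-increasing at every accepted step (step sizes are
    halved until the update improves the RSS).  Archetypes claimed (by
    argmax loading) by fewer than ``min_cells_per_arch`` cells are dropped
    and the loadings refit on the survivors.
    """
    x = np.asarray(e.coordinates, float)
    n, d = x.shape
    if not 2 <= k <= n:
        raise ValueError(f"k={k} must be between 2 and the number of cells ({n})")
    rng = np.random.default_rng(seed)

    seeds = _furthest_sum(x, k, rng)
    b = np.full((k, n), 1e-12)
    b[np.arange(seeds.size), seeds] = 1.0
    b = b / b.sum(axis=1, keepdims=True)
    a = np.full((n, k), 1.0 / k)

    z = b @ x
    rss = _rss(x, a, z)
    history = [rss]
    mu_a = mu_b = 1.0
    converged = False
    for _ in range(max_iter):
        # cell loadings A
        g_a = (a @ z - x) @ z.T
        scale_a = np.abs(g_a).max() + 1e-300
        for _ in range(30):
            a_new = _project_simplex_rows(a - (mu_a / scale_a) * g_a)
            rss_new = _rss(x, a_new, z)
            if rss_new <= rss:
                a, rss = a_new, rss_new
                mu_a *= 1.5
                break
            mu_a /= 2.0
        # archetype weights B
        g_b = (a.T @ (a @ z - x)) @ x.T
        scale_b = np.abs(g_b).max() + 1e-300
        for _ in range(30):
            b_new = _project_simplex_rows(b - (mu_b / scale_b) * g_b)
            rss_new = _rss(x, a, b_new @ x)
            if rss_new <= rss:
                b, rss = b_new, rss_new
                z = b @ x
                mu_b *= 1.5
                break
            mu_b /= 2.0
        history.append(rss)
        prev = history[-2]
        if prev - rss <= tol * max(prev, 1e-300):
            converged = True
            break

    # drop under-populated archetypes and refit loadings
    assign = np.argmax(a, axis=1)  # ties -> lowest index
    counts = np.bincount(assign, minlength=a.shape[1])
    keep = counts >= min_cells_per_arch
    if not keep.any():
        keep[np.argmax(counts)] = True
    if keep.sum() < a.shape[1]:
        b = b[keep]
        b = b / b.sum(axis=1, keepdims=True)
        z = b @ x
        a = _refit_loadings(x, z, a[:, keep])
        rss = _rss(x, a, z)
        history.append(rss)
        assign = np.argmax(a, axis=1)
        counts = np.bincount(assign, minlength=z.shape[0])

    return ArchetypeModel(
        k=z.shape[0],
        archetype_coords=z,
        cell_loadings=a,
        archetype_weights=b,
        rss=rss,
        rss_history=history,
        cells_per_archetype=counts,
        converged=converged,
    )


def _refit_loadings(x: np.ndarray, z: np.ndarray, a0: np.ndarray) -> np.ndarray:
    """Projected-gradient refit of simplex loadings for fixed archetypes."""
    a = _project_simplex_rows(a0)
    rss = _rss(x, a, z)
    mu = 1.0
    for _ in range(100):
        g = (a @ z - x) @ z.T
        scale = np.abs(g).max() + 1e-300
        improved = False
        for _ in range(30):
            a_new = _project_simplex_rows(a - (mu / scale) * g)
            rss_new = _rss(x, a_new, z)
            if rss_new <= rss:
                if rss - rss_new <= 1e-9 * max(rss, 1e-300):
                    a, rss = a_new, rss_new
                    return a
                a, rss = a_new, rss_new
                mu *= 1.5
                improved = True
                break
            mu /= 2.0
        if not improved:
            break
    return a


@dataclass
class SelectKResult:
    k: int
    rss_by_k: dict[int, float]
    degenerate: bool = False


def select_k(
    e: ReducedEmbedding,
    k_max: int = DEFAULT_K_MAX,
    max_iter: int = 60,
    tol: float = 1e-5,
    seed: int = 0,
) -> SelectKResult:
    """Choose the archetype count by the elbow of the RSS-vs-k curve.

    Fits k = 2..k_max (with a lighter iteration budget, since only the RSS
    profile matters here), rescales the curve to the unit square and takes
    the k of maximum perpendicular distance to the chord joining the
    endpoints.  A near-linear curve is flagged degenerate and yields k = 2.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    k_max = min(k_max, e.coordinates.shape[0])
    ks = np.arange(2, k_max + 1)
    rss = np.array([
        fit_archetypes(e, int(k), max_iter=max_iter, tol=tol, seed=seed,
                       min_cells_per_arch=1).rss
        for k in ks
    ])
    if ks.size == 1:
        return SelectKResult(int(ks[0]), dict(zip(ks.tolist(), rss.tolist())))
    span = rss[0] - rss[-1]
    if span <= 1e-12 * max(abs(rss[0]), 1.0):
        return SelectKResult(2, dict(zip(ks.tolist(), rss.tolist())), degenerate=True)
    xs = (ks - ks[0]) / (ks[-1] - ks[0])
    ys = (rss - rss[-1]) / span
    # distance to the chord from (0, 1) to (1, 0)
    dist = np.abs(xs + ys - 1.0) / np.sqrt(2.0)
    degenerate = bool(dist.max() < 1e-6)
    k_hat = 2 if degenerate else int(ks[int(np.argmax(dist))])
    return SelectKResult(k_hat, dict(zip(ks.tolist(), rss.tolist())), degenerate)


# ---------------------------------------------------------------------------
# archetype gene programs
# ---------------------------------------------------------------------------

def program_genes(
    model: ArchetypeModel,
    m: LogNormMatrix,
    top_m: int = DEFAULT_TOP_M,
    prefix: str = "arch",
) -> list[ArchetypeProgram]:
    """Derive each archetype's gene program from its expression footprint.

    footprint(g, a) = sum_c loading(c, a) expr(g, c) / sum_c loading(c, a),
    z-scored per gene across archetypes; the program is the ``top_m`` genes
    by footprint.  The z denominator carries a variance floor (the median
    per-gene spread across archetypes), a moderated statistic that stops
    near-silent genes -- whose between-archetype differences are pure
    sampling noise -- from outranking genuinely archetype-specific genes.
    Identical archetypes give an all-zero (degenerate) footprint, which is
    flagged.
    """
    a = model.cell_loadings
    if a.shape[0] != len(m.cells):
        raise ValueError("model was not fitted on the cells of this matrix")
    if top_m > len(m.genes):
        top_m = len(m.genes)
    expr = m.dense()  # genes x cells
    weights = a / np.maximum(a.sum(axis=0, keepdims=True), 1e-300)
    fp = expr @ weights  # genes x k
    mu = fp.mean(axis=1, keepdims=True)
    sd = fp.std(axis=1, keepdims=True)
    degenerate_rows = sd.ravel() <= 1e-12
    s0 = float(np.median(sd))  # variance floor: moderated z
    with np.errstate(invalid="ignore", divide="ignore"):
        fz = np.where(sd > 1e-12, (fp - mu) / (sd + s0), 0.0)
    programs = []
    gene_index = pd.Index(m.genes)
    for j in range(fp.shape[1]):
        col = pd.Series(fz[:, j], index=gene_index)
        order = np.argsort(-fz[:, j], kind="stable")[:top_m]
        programs.append(
            ArchetypeProgram(
                archetype_id=f"{prefix}{j}",
                footprint=col,
                member_genes=[m.genes[i] for i in order],
                degenerate=bool(degenerate_rows.all()),
            )
        )
    return programs
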