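"""Derivation of the core metastatic signature and its epithelial refinement.

The derivation runs per patient: QC + log-normalisation, PCA embedding,
archetypal analysis (elbow-selected k), and extraction of per-archetype
gene programs.  Archetype footprints are then scored with literature seed
gene sets; the top-scoring archetypes per patient are selected, and genes
are counted across selected archetypes.  A knee point on the sorted
frequency curve sets the inclusion threshold for the core signature, which
is finally split by cell-type specificity into an epithelial-specific
refined signature and a non-epithelial residual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.sparse as sp

from . import archetypes as arch
from .io import CountMatrix, LogNormMatrix, lognorm, qc_filter
from .scoring import DEFAULT_R_MAX, GeneSet, score_profiles

logger = logging.getLogger("metasig")

DEFAULT_TOP_QUANTILE = 0.25
DEFAULT_K_CLUSTERS = 9


@dataclass
class FrequencyTable:
    """Per-gene count of selected archetypes whose programs contain it."""

    counts: pd.Series  # gene -> archetype count, descending
    threshold: int | None = None
    knee_index: int | None = None
    degenerate: bool = False

    @property
    def sorted_counts(self) -> np.ndarray:
        return self.counts.to_numpy()


@dataclass
class SpecificityMatrix:
    """Genes x cell types specificity shares (rows sum to 1) with gene clusters."""

    shares: pd.DataFrame  # genes x cell types
    cluster_labels: pd.Series  # gene -> cluster id (1..k)
    k_clusters: int


@dataclass
class Signature:
    """An ordered gene list with derivation provenance."""

    name: str
    genes: list[str]
    stage: str  # core | refined | residual
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# archetype scoring and selection
# ---------------------------------------------------------------------------

def score_programs(
    programs: dict[str, list[arch.ArchetypeProgram]],
    seeds: list[GeneSet],
    r_max: int = DEFAULT_R_MAX,
) -> pd.DataFrame:
    """Score every archetype footprint with each seed gene set.

    ``programs`` maps patient id to that patient's archetype programs.  The
    combined score is the mean over the seed sets (the two literature
    evidence tiers), computed by the same rank-based scorer used for cells,
    applied to the footprint profile.
    """
    if not seeds:
        raise ValueError("at least one seed gene set is required")
    records = []
    for patient, progs in programs.items():
        if not progs:
            continue
        fp = pd.DataFrame({p.archetype_id: p.footprint for p in progs})
        row: dict[str, object]
        per_set = []
        for s in seeds:
            sv = score_profiles(fp, s, r_max=r_max)
            per_set.append(np.asarray(sv.score))
        combined = np.mean(per_set, axis=0)
        for j, p in enumerate(progs):
            row = {"patient_id": patient, "archetype_id": p.archetype_id,
                   "combined": combined[j]}
            for s, sc in zip(seeds, per_set):
                row[f"score_{s.name}"] = sc[j]
            records.append(row)
    return pd.DataFrame(records)


def select_archetypes(
    scores: pd.DataFrame,
    top_quantile: float = DEFAULT_TOP_QUANTILE,
) -> pd.DataFrame:
    """Keep archetypes at or above the per-patient (1 - q) score quantile."""
    if len(scores) < 4:
        raise ValueError("need at least 4 archetypes to select from")
    keep = []
    for patient, grp in scores.groupby("patient_id"):
        cutoff = grp["combined"].quantile(1.0 - top_quantile)
        sel = grp[grp["combined"] >= cutoff]
        if grp["combined"].nunique() == 1:
            logger.warning("select_archetypes: all archetypes tied in %s; keeping all", patient)
        keep.append(sel)
    return pd.concat(keep, ignore_index=True)


def gene_frequency(
    selected: pd.DataFrame,
    programs: dict[str, list[arch.ArchetypeProgram]],
) -> FrequencyTable:
    """Count, per gene, the selected archetypes whose programs contain it."""
    if selected.empty:
        raise ValueError("no selected archetypes")
    by_id = {
        (patient, p.archetype_id): p
        for patient, progs in programs.items()
        for p in progs
    }
    counts: dict[str, int] = {}
    for _, row in selected.iterrows():
        prog = by_id[(row["patient_id"], row["archetype_id"])]
        for g in prog.member_genes:
            counts[g] = counts.get(g, 0) + 1
    series = pd.Series(counts).sort_values(ascending=False, kind="stable")
    # deterministic ordering among ties
    series = series.iloc[np.lexsort((series.index, -series.to_numpy()))]
    return FrequencyTable(series)


# ---------------------------------------------------------------------------
# knee threshold and core signature
# ---------------------------------------------------------------------------

def knee_threshold(t: FrequencyTable, override: int | None = None) -> FrequencyTable:
    """Set the inclusion threshold at the knee of the sorted frequency curve.

    Each point of the curve (rank, count), rescaled to the unit square, is
    compared with the chord joining the curve's endpoints; the knee is the
    point of maximum perpendicular distance.  A knee above the chord (a
    plateau ending in a cliff) is the cliff top and its count is the
    threshold.  A knee below the chord sits in the curve's low-count tail,
    which on archetype-frequency curves is long enough to drag the
    maximum-distance point past the cliff; the tail from the knee onward
    is therefore trimmed and the search repeated until the knee lands on
    or above the chord.  Near-linear curves are flagged degenerate and
    fall back to the minimum count.  ``override`` bypasses the knee
    entirely (the published derivation used 25).
    """
    counts = t.sorted_counts
    if override is not None:
        t.threshold = int(override)
        return t
    if counts.size < 3:
        raise ValueError("knee detection needs at least 3 genes")
    if np.unique(counts).size < 3:
        t.threshold = int(counts.min())
        t.degenerate = True
        return t

    end = counts.size  # exclusive end of the segment under search
    while True:
        seg = counts[:end]
        if seg.size < 3 or np.unique(seg).size < 3:
            t.threshold = int(seg.min())
            t.degenerate = True
            return t
        x = np.linspace(0.0, 1.0, seg.size)
        span = seg[0] - seg[-1]
        y = (seg - seg[-1]) / span
        signed = x + y - 1.0
        if np.abs(signed).max() < 1e-8:
            t.threshold = int(seg.min())
            t.degenerate = True
            return t
        knee = int(np.argmax(np.abs(signed)))
        if signed[knee] >= 0 or knee == 0:
            t.knee_index = knee
            t.threshold = int(seg[knee])
            return t
        end = knee + 1  # keep the knee as the new endpoint


def core_signature(t: FrequencyTable, name: str = "core") -> Signature:
    """Genes at or above the threshold, by decreasing count then lexically."""
    if t.threshold is None:
        raise ValueError("threshold not set; run knee_threshold first")
    kept = t.counts[t.counts >= t.threshold]
    if kept.empty:
        raise ValueError(
            f"no gene reaches threshold {t.threshold}; try a lower threshold"
        )
    order = sorted(kept.index, key=lambda g: (-kept[g], g))
    return Signature(name, order, "core",
                     {"threshold": t.threshold, "knee_index": t.knee_index})


# ---------------------------------------------------------------------------
# cell-type specificity and refinement
# ---------------------------------------------------------------------------

def specificity(
    m: LogNormMatrix,
    genes: list[str],
    group_by: str = "patient_id",
    cell_type_col: str = "cell_type",
    k_clusters: int = DEFAULT_K_CLUSTERS,
) -> SpecificityMatrix:
    """Per-gene cell-type specificity shares, averaged across tumours.

    Within each tumour, a gene's share for a cell type is its mean log
    expression in that type divided by the sum over types (uniform when
    all means are zero).  Shares are averaged across tumours, re-normalised
    per gene, and the genes Ward-clustered (Euclidean) into ``k_clusters``.
    """
    meta = m.cell_meta
    if cell_type_col not in meta.columns:
        raise ValueError(f"cell metadata lacks a {cell_type_col!r} column")
    types = sorted(meta[cell_type_col].dropna().unique())
    if len(types) < 2:
        raise ValueError("need at least 2 cell types")
    gene_idx = [m.genes.index(g) for g in genes if g in m.genes]
    kept_genes = [m.genes[i] for i in gene_idx]
    if not kept_genes:
        raise ValueError("none of the requested genes are in the matrix")
    expr = np.asarray(m.values[gene_idx].todense())

    shares_sum = np.zeros((len(kept_genes), len(types)))
    n_tumours = 0
    for _, cols in meta.groupby(group_by).groups.items():
        col_pos = meta.index.get_indexer(cols)
        sub_meta = meta.iloc[col_pos]
        means = np.zeros((len(kept_genes), len(types)))
        for j, ct in enumerate(types):
            mask = (sub_meta[cell_type_col] == ct).to_numpy()
            if not mask.any():
                continue
            means[:, j] = expr[:, col_pos[mask]].mean(axis=1)
        totals = means.sum(axis=1, keepdims=True)
        shares = np.where(totals > 0, means / np.maximum(totals, 1e-300),
                          1.0 / len(types))
        shares_sum += shares
        n_tumours += 1
    avg = shares_sum / n_tumours
    avg = avg / avg.sum(axis=1, keepdims=True)

    k = min(k_clusters, len(kept_genes))
    if len(kept_genes) > 1:
        link = scipy.cluster.hierarchy.linkage(avg, method="ward")
        labels = scipy.cluster.hierarchy.fcluster(link, t=k, criterion="maxclust")
    else:
        labels = np.ones(1, int)
    return SpecificityMatrix(
        pd.DataFrame(avg, index=kept_genes, columns=types),
        pd.Series(labels, index=kept_genes),
        k,
    )


def refine(
    core: Signature,
    sm: SpecificityMatrix,
    target: str = "epithelial",
    min_mean_specificity: float | None = None,
) -> tuple[Signature, Signature]:
    """Split the core signature by cluster-level target-type specificity.

    Clusters whose mean target-type share reaches the floor are selected;
    without an explicit floor the midpoint between the lowest and highest
    cluster means is used, so a clean two-population structure splits at
    the natural gap and a homogeneous one keeps everything.
    """
    if target not in sm.shares.columns:
        raise ValueError(f"cell type {target!r} not in specificity matrix")
    cluster_means = sm.shares[target].groupby(sm.cluster_labels).mean()
    floor = (
        min_mean_specificity
        if min_mean_specificity is not None
        else (cluster_means.max() + cluster_means.min()) / 2.0
    )
    chosen = cluster_means.index[cluster_means >= floor]
    if chosen.empty:
        raise ValueError(
            "no cluster passes the specificity floor; per-cluster means: "
            + ", ".join(f"{c}: {v:.3f}" for c, v in cluster_means.items())
        )
    selected_genes = set(sm.cluster_labels.index[sm.cluster_labels.isin(chosen)])
    refined = [g for g in core.genes if g in selected_genes]
    residual = [g for g in core.genes if g not in selected_genes]
    prov = {"parent": core.name, "target": target,
            "clusters": [int(c) for c in chosen],
            "cluster_means": {int(c): float(v) for c, v in cluster_means.items()}}
    return (
        Signature(f"{core.name}_refined", refined, "refined", prov),
        Signature(f"{core.name}_residual", residual, "residual", prov),
    )


# ---------------------------------------------------------------------------
# end-to-end derivation
# ---------------------------------------------------------------------------

@dataclass
class DerivationResult:
    core: Signature
    refined: Signature
    residual: Signature
    frequency: FrequencyTable
    specificity: SpecificityMatrix
    archetype_scores: pd.DataFrame
    selected: pd.DataFrame
    k_by_patient: dict[str, int]


def derive_signature(
    matrices: list[CountMatrix],
    seed_sets: list[GeneSet],
    reduced_dim: int = arch.DEFAULT_REDUCED_DIM,
    k_max: int = arch.DEFAULT_K_MAX,
    top_m: int = arch.DEFAULT_TOP_M,
    r_max: int = DEFAULT_R_MAX,
    top_quantile: float = DEFAULT_TOP_QUANTILE,
    threshold_override: int | None = None,
    k_clusters: int = DEFAULT_K_CLUSTERS,
    target_cell_type: str = "epithelial",
    seed: int = 0,
    run_qc: bool = True,
) -> DerivationResult:
    """Run the whole derivation on a multi-patient cohort."""
    programs: dict[str, list[arch.ArchetypeProgram]] = {}
    norm_by_patient: dict[str, LogNormMatrix] = {}
    k_by_patient: dict[str, int] = {}
    for m in matrices:
        patient = str(m.cell_meta["patient_id"].iloc[0])
        filtered = qc_filter(m) if run_qc else m
        norm = lognorm(filtered)
        emb = arch.reduce_pca(norm, d=reduced_dim)
        k_hat = arch.select_k(emb, k_max=k_max, seed=seed).k
        model = arch.fit_archetypes(emb, k_hat, seed=seed)
        programs[patient] = arch.program_genes(model, norm, top_m=top_m,
                                               prefix=f"{patient}:arch")
        norm_by_patient[patient] = norm
        k_by_patient[patient] = model.k

    scores = score_programs(programs, seed_sets, r_max=r_max)
    selected = select_archetypes(scores, top_quantile=top_quantile)
    freq = knee_threshold(gene_frequency(selected, programs),
                          override=threshold_override)
    core = core_signature(freq)

    concat = _concat_lognorm(list(norm_by_patient.values()), core.genes)
    sm = specificity(concat, core.genes, k_clusters=k_clusters)
    refined, residual = refine(core, sm, target=target_cell_type)
    return DerivationResult(core, refined, residual, freq, sm, scores,
                            selected, k_by_patient)


def _concat_lognorm(mats: list[LogNormMatrix], genes: list[str]) -> LogNormMatrix:
    """Column-concatenate per-patient matrices restricted to ``genes``."""
    blocks, cells, metas = [], [], []
    for m in mats:
        idx = [m.genes.index(g) for g in genes]
        blocks.append(m.values[idx])
        cells.extend(m.cells)
        metas.append(m.cell_meta)
    return LogNormMatrix(list(genes), cells, sp.hstack(blocks, format="csr"),
                         pd.concat(metas))


# ---------------------------------------------------------------------------
# packaged signature fixtures
# ---------------------------------------------------------------------------

def load_packaged_signature(stage: str = "refined") -> Signature:
    """Load the packaged signature gene lists.

    The published derivation produced a 286-gene core signature split into
    a 177-gene epithelial-refined subset and a 109-gene residual.  The
    original supplementary gene lists are not redistributable here, so the
    packaged lists are synthetic stand-ins with the same cardinalities
    (177 / 109 / 286), generated symbol-like identifiers only.
    """
    files = {
        "refined": ["synthetic_refined_177.txt"],
        "residual": ["synthetic_residual_109.txt"],
        "core": ["synthetic_refined_177.txt", "synthetic_residual_109.txt"],
    }
    if stage not in files:
        raise ValueError(f"stage must be one of {sorted(files)}")
    genes: list[str] = []
    for fname in files[stage]:
        text = resources.files("metasig.data").joinpath(fname).read_text()
        genes.extend(
            line.split("#", 1)[0].strip()
            for line in text.splitlines()
            if line.split("#", 1)[0].strip()
        )
    return Signature(f"packaged_{stage}", genes, stage,
                     {"source": "synthetic stand-in fixture"})
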