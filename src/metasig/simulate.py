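"""Synthetic multi-patient cohorts with a planted metastatic program.

Every input the pipeline consumes can be generated here with known ground
truth: a multi-patient, multi-cancer-type scRNA-seq cohort carrying a
shared "metastatic program" expressed on a continuous low-to-high
intensity gradient; a bulk cohort whose survival hazard depends on the
signature score; a spatial grid with stroma / tumour-body / invasive-edge
regions where the edge is program-enriched; and pseudotime panels with
sigmoidal on/off genes.

Counts are negative-binomial (Gamma-Poisson) with log-normally drawn
gene-level means and a shared dispersion -- the standard overdispersion
model for UMI data, adequate for the rank-based scoring downstream.  The
planted program splits into an epithelial-specific half and a
tumour-microenvironment half that is also expressed by fibroblasts, so
that the specificity refinement stage has a real distinction to find.
Mitochondrial genes are simulated under an "MT-" prefix and a small
fraction of debris cells is included so the QC filter is exercised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, write_counts

DEFAULT_CELL_TYPE_FRACTIONS = {
    "epithelial": 0.45,
    "fibroblast": 0.25,
    "immune": 0.20,
    "endothelial": 0.10,
}

N_MITO_GENES = 13
#: expression of a cell-type-restricted gene outside its host types,
#: relative to the host-type mean (leaky but near-silent)
OFF_TYPE_LEAK = 0.05
#: fraction of simulated cells that are low-depth debris (QC fodder)
DEBRIS_FRACTION = 0.02
#: log-normal sigma of per-patient gene-mean heterogeneity
PATIENT_SIGMA = 0.25


class ParameterError(ValueError):
    """Raised when a simulation parameter is invalid; names the field."""


@dataclass
class SimConfig:
    """Study conditions for the pan-cancer single-cell simulation."""

    n_patients: int = 12
    n_cancer_types: int = 4
    cells_per_patient: int = 1500
    n_genes: int = 2000
    cell_type_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CELL_TYPE_FRACTIONS)
    )
    program_size: int = 150
    program_cell_fraction: float = 0.3
    program_log2_effect: float = 2.0
    nb_dispersion: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_patients", "n_cancer_types", "cells_per_patient",
                     "n_genes", "program_size"):
            if int(getattr(self, name)) <= 0:
                raise ParameterError(f"{name} must be a positive count")
        if self.program_size >= self.n_genes:
            raise ParameterError("program_size must be smaller than n_genes")
        total = sum(self.cell_type_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(
                f"cell_type_fractions must sum to 1 (got {total})"
            )
        if any(v < 0 for v in self.cell_type_fractions.values()):
            raise ParameterError("cell_type_fractions must be non-negative")
        if not 0.0 <= self.program_cell_fraction <= 1.0:
            raise ParameterError("program_cell_fraction must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ParameterError("nb_dispersion must be positive")
        if "epithelial" not in self.cell_type_fractions:
            raise ParameterError("cell_type_fractions must include 'epithelial'")


@dataclass
class GroundTruth:
    """Planted truth shared by all generators (unused fields stay empty)."""

    program_genes: set[str] = field(default_factory=set)
    program_cells: set[str] = field(default_factory=set)
    epithelial_specific_genes: set[str] = field(default_factory=set)
    bulk_log_hazard_ratio: float | None = None
    switch_times: dict[str, float] = field(default_factory=dict)
    de_genes: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "program_genes": sorted(self.program_genes),
            "program_cells": sorted(self.program_cells),
            "epithelial_specific_genes": sorted(self.epithelial_specific_genes),
            "bulk_log_hazard_ratio": self.bulk_log_hazard_ratio,
            "switch_times": self.switch_times,
            "de_genes": self.de_genes,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _nb_counts(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mean)
    return rng.poisson(lam).astype(np.int32)


def _gene_names(n_genes: int) -> list[str]:
    mito = [f"MT-G{i + 1}" for i in range(min(N_MITO_GENES, n_genes))]
    rest = [f"G{i + 1:05d}" for i in range(n_genes - len(mito))]
    return mito + rest


# ---------------------------------------------------------------------------
# pan-cancer single-cell cohort
# ---------------------------------------------------------------------------

def gen_pan_cancer(cfg: SimConfig) -> tuple[list[CountMatrix], GroundTruth]:
    """Simulate one count matrix per patient with a planted shared program.

    Program genes have their negative-binomial mean multiplied by
    ``2 ** (program_log2_effect * u)`` in program cells, where the per-cell
    intensity ``u`` is uniform in [0, 1], so scores form a low-to-high
    continuum rather than two clean groups.  Half the program genes are
    epithelial-restricted; the other half is shared with fibroblasts.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_genes)
    n_mito = sum(g.startswith("MT-") for g in genes)

    # baseline gene means: log-normal, mitochondria elevated to ~8% of UMIs
    base_mean = rng.lognormal(mean=np.log(0.5), sigma=1.0, size=cfg.n_genes)
    non_mito_total = base_mean[n_mito:].sum()
    base_mean[:n_mito] = 0.08 * non_mito_total / (0.92 * max(n_mito, 1))

    # plant the program on non-mitochondrial genes with solid baselines
    candidates = np.arange(n_mito, cfg.n_genes)
    program_idx = rng.choice(candidates, size=cfg.program_size, replace=False)
    base_mean[program_idx] = rng.lognormal(np.log(1.0), 0.5, cfg.program_size)
    half = cfg.program_size // 2
    epi_idx = program_idx[:half]          # epithelial-restricted half
    tme_idx = program_idx[half:]          # shared with fibroblasts

    cell_types = list(cfg.cell_type_fractions)
    type_probs = np.array([cfg.cell_type_fractions[t] for t in cell_types])
    cancer_types = [f"cancer{1 + i % cfg.n_cancer_types}" for i in range(cfg.n_patients)]

    matrices: list[CountMatrix] = []
    truth = GroundTruth(
        program_genes={genes[i] for i in program_idx},
        epithelial_specific_genes={genes[i] for i in epi_idx},
    )

    for p in range(cfg.n_patients):
        patient = f"P{p + 1:02d}"
        n = cfg.cells_per_patient
        types = rng.choice(len(cell_types), size=n, p=type_probs)
        is_epi = types == cell_types.index("epithelial")
        is_fib = (
            types == cell_types.index("fibroblast")
            if "fibroblast" in cell_types
            else np.zeros(n, bool)
        )

        # patient-specific expression heterogeneity around the shared baseline
        patient_mean = base_mean * rng.lognormal(0.0, PATIENT_SIGMA, cfg.n_genes)
        mean = np.repeat(patient_mean[:, None], n, axis=1)
        # cell-type restriction of the planted halves
        mean[np.ix_(epi_idx, ~is_epi)] *= OFF_TYPE_LEAK
        mean[np.ix_(tme_idx, ~(is_epi | is_fib))] *= OFF_TYPE_LEAK

        # planted program: a continuous intensity in epithelial program cells
        epi_cells = np.flatnonzero(is_epi)
        n_prog = int(round(cfg.program_cell_fraction * epi_cells.size))
        prog_cells = rng.choice(epi_cells, size=n_prog, replace=False)
        intensity = rng.uniform(0.0, 1.0, size=n_prog)
        boost = 2.0 ** (cfg.program_log2_effect * intensity)
        mean[np.ix_(program_idx, prog_cells)] *= boost[None, :]

        # per-cell depth variation, mito variability and a debris tail
        depth = rng.lognormal(0.0, 0.15, size=n)
        debris = rng.random(n) < DEBRIS_FRACTION
        depth[debris] *= 0.05
        mean *= depth[None, :]
        mean[:n_mito] *= rng.gamma(4.0, 0.25, size=n)[None, :]

        counts = _nb_counts(mean, cfg.nb_dispersion, rng)
        cells = [f"{patient}-C{i + 1:05d}" for i in range(n)]
        meta = pd.DataFrame(
            {
                "cell_id": cells,
                "patient_id": patient,
                "sample_id": patient,
                "cancer_type": cancer_types[p],
                "cell_type": [cell_types[t] for t in types],
            }
        ).set_index("cell_id")
        matrices.append(CountMatrix(genes, cells, sp.csr_matrix(counts), meta))
        truth.program_cells.update(cells[i] for i in prog_cells)

    return matrices, truth


def gen_seed_lists(
    truth: GroundTruth,
    genes: list[str],
    seed: int = 0,
    single_size: int = 400,
    multi_size: int = 200,
    coverage: float = 0.6,
) -> tuple[list[str], list[str]]:
    """Literature-style seed gene lists: noisy supersets of the planted
    program (a broad single-evidence list and a smaller multi-evidence one),
    padded with random decoys."""
    rng = np.random.default_rng(seed)
    program = sorted(truth.program_genes)
    others = sorted(set(genes) - truth.program_genes)
    lists = []
    for size, cov in ((single_size, min(1.0, coverage + 0.1)), (multi_size, coverage)):
        n_true = min(int(round(cov * len(program))), size)
        n_decoy = min(size - n_true, len(others))
        chosen = list(rng.choice(program, size=n_true, replace=False))
        decoys = list(rng.choice(others, size=n_decoy, replace=False))
        lists.append(sorted(chosen + decoys))
    return lists[0], lists[1]


# ---------------------------------------------------------------------------
# bulk cohort with survival
# ---------------------------------------------------------------------------

def gen_bulk_cohort(
    n_samples: int,
    signature: list[str],
    beta: float,
    censor_rate: float,
    seed: int = 0,
    n_background_genes: int = 300,
    baseline_hazard: float = 0.1,
    n_normal: int = 0,
    tumour_shift: float = 1.0,
    stage_effect: float = 0.35,
) -> tuple["BulkCohortData", GroundTruth]:
    """Simulate a bulk cohort whose hazard depends on the signature score.

    Each tumour sample carries a latent program activity that loads on the
    signature genes; survival times are exponential with hazard
    ``baseline_hazard * exp(beta * z)`` where ``z`` is the sample's
    signature Z-score (mean of per-gene z-scores, as the scorer computes
    it).  Optional normal samples lack the tumour activity shift, and a
    weak positive stage-score association is planted via ``stage_effect``.
    """
    if not np.isfinite(beta):
        raise ParameterError("beta must be finite")
    if not 0.0 <= censor_rate < 1.0:
        raise ParameterError("censor_rate must be in [0, 1)")
    if n_samples < 2:
        raise ParameterError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)

    genes = list(signature) + [f"BG{i + 1:04d}" for i in range(n_background_genes)]
    n_total = n_samples + n_normal
    tissue = np.array(["tumour"] * n_samples + ["normal"] * n_normal)
    shift = np.where(tissue == "tumour", tumour_shift if n_normal else 0.0, 0.0)
    activity = rng.normal(0.0, 1.0, n_total) + shift

    base = rng.normal(5.0, 1.0, len(genes))
    expr = base[None, :] + rng.normal(0.0, 0.6, (n_total, len(genes)))
    expr[:, : len(signature)] += 0.8 * activity[:, None]
    samples = [f"S{i + 1:04d}" for i in range(n_total)]
    log_expr = pd.DataFrame(expr, index=samples, columns=genes)

    # the score the downstream fit will use, computed on tumour samples
    tumour_expr = log_expr.iloc[:n_samples, : len(signature)]
    z = (tumour_expr - tumour_expr.mean()) / tumour_expr.std(ddof=0)
    score = z.mean(axis=1).to_numpy()

    hazard = baseline_hazard * np.exp(beta * score)
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        lam_c = baseline_hazard * censor_rate / (1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / lam_c, size=n_samples)
    else:
        t_cens = np.full(n_samples, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    # normals get placeholder follow-up; survival analysis uses tumours only
    time_all = np.concatenate([time, rng.exponential(10.0, n_normal)])
    event_all = np.concatenate([event, np.zeros(n_normal, int)])

    late = rng.random(n_total) < _sigmoid(stage_effect * activity)
    clinical = pd.DataFrame(
        {
            "sample_id": samples,
            "time": np.maximum(time_all, 1e-6),
            "event": event_all,
            "cancer_type": [f"cancer{1 + i % 4}" for i in range(n_total)],
            "purity": rng.uniform(0.3, 1.0, n_total),
            "stage": np.where(late, rng.integers(3, 5, n_total), rng.integers(1, 3, n_total)),
            "age": rng.normal(60.0, 10.0, n_total),
            "tissue": tissue,
        }
    ).set_index("sample_id")

    truth = GroundTruth(bulk_log_hazard_ratio=beta, program_genes=set(signature))
    return BulkCohortData(log_expr, clinical), truth


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class BulkCohortData:
    """Samples x genes log expression plus clinical annotations."""

    log_expr: pd.DataFrame  # samples x genes
    clinical: pd.DataFrame  # indexed by sample, time/event/covariates

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.log_expr.to_csv(outdir / "expression.tsv", sep="\t")
        self.clinical.to_csv(outdir / "clinical.tsv", sep="\t")


# ---------------------------------------------------------------------------
# spatial slide
# ---------------------------------------------------------------------------

@dataclass
class SpatialSlide:
    """Spot grid with region annotations and a genes x spots count matrix."""

    spots: pd.DataFrame  # spot_id, x, y, region
    genes: list[str]
    counts: sp.csr_matrix  # genes x spots

    REGIONS = ("stroma", "tumour body", "invasive edge")

    def write(self, outdir: str | Path) -> None:
        import scipy.io

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.spots.to_csv(outdir / "spots.tsv", sep="\t", index=False)
        scipy.io.mmwrite(outdir / "counts.mtx", sp.coo_matrix(self.counts), field="integer")
        pd.Series(self.genes).to_csv(outdir / "genes.tsv", sep="\t", header=False, index=False)


def gen_spatial_slide(
    grid: tuple[int, int] = (30, 30),
    edge_effect: float = 1.5,
    seed: int = 0,
    n_genes: int = 500,
    program_size: int = 100,
    nb_dispersion: float = 0.3,
) -> tuple[SpatialSlide, GroundTruth]:
    """Simulate a spot grid with stroma / tumour body / invasive edge.

    The tumour body is a central disc, the invasive edge the surrounding
    annulus.  Program-gene means are multiplied by ``2 ** edge_effect`` in
    edge spots and by ``2 ** (edge_effect / 2)`` in the body, reproducing
    the stroma < body < edge ordering.
    """
    nx, ny = grid
    if nx < 10 or ny < 10:
        raise ParameterError("grid must be at least 10 x 10")
    rng = np.random.default_rng(seed)

    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    xs, ys = xs.ravel(), ys.ravel()
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    r = np.hypot(xs - cx, ys - cy)
    r_body = 0.30 * min(nx, ny)
    r_edge = 0.42 * min(nx, ny)
    region = np.where(r <= r_body, "tumour body",
                      np.where(r <= r_edge, "invasive edge", "stroma"))

    genes = [f"SG{i + 1:04d}" for i in range(n_genes)]
    program_idx = rng.choice(n_genes, size=program_size, replace=False)
    base = rng.lognormal(np.log(1.0), 0.8, n_genes)
    mean = np.repeat(base[:, None], xs.size, axis=1)
    in_edge = region == "invasive edge"
    in_body = region == "tumour body"
    mean[np.ix_(program_idx, in_edge)] *= 2.0 ** edge_effect
    mean[np.ix_(program_idx, in_body)] *= 2.0 ** (edge_effect / 2.0)
    mean *= rng.lognormal(0.0, 0.15, xs.size)[None, :]

    counts = _nb_counts(mean, nb_dispersion, rng)
    spots = pd.DataFrame(
        {
            "spot_id": [f"spot{i + 1:04d}" for i in range(xs.size)],
            "x": xs,
            "y": ys,
            "region": region,
        }
    )
    truth = GroundTruth(program_genes={genes[i] for i in program_idx})
    return SpatialSlide(spots, genes, sp.csr_matrix(counts)), truth


# ---------------------------------------------------------------------------
# pseudotime panel
# ---------------------------------------------------------------------------

def gen_pseudotime_panel(
    n_cells: int,
    switch_spec: dict[str, tuple[float, str, float]],
    seed: int = 0,
    n_null_genes: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, GroundTruth]:
    """Simulate log expression along pseudotime with sigmoidal switches.

    Each switch gene's on-probability follows a logistic curve
    ``sigmoid(steepness * (t - t_star))`` (reversed for "off" genes); null
    genes toggle with probability 0.5 regardless of pseudotime.  "On"
    observations exceed the standard binarisation cutoff of 0.2; "off"
    observations fall below it.
    """
    rng = np.random.default_rng(seed)
    for gene, (t_star, direction, steepness) in switch_spec.items():
        if not 0.0 < t_star < 1.0:
            raise ParameterError(f"t_star for {gene} must be in (0, 1)")
        if direction not in ("on", "off"):
            raise ParameterError(f"direction for {gene} must be 'on' or 'off'")
    t = rng.uniform(0.0, 1.0, n_cells)

    rows, names = [], []
    truth = GroundTruth()
    for gene, (t_star, direction, steepness) in switch_spec.items():
        sgn = 1.0 if direction == "on" else -1.0
        p_on = _sigmoid(sgn * steepness * (t - t_star))
        on = rng.random(n_cells) < p_on
        expr = np.where(
            on,
            np.maximum(rng.normal(1.2, 0.3, n_cells), 0.25),
            rng.uniform(0.0, 0.15, n_cells),
        )
        rows.append(expr)
        names.append(gene)
        truth.switch_times[gene] = t_star
    for i in range(n_null_genes):
        on = rng.random(n_cells) < 0.5
        expr = np.where(
            on,
            np.maximum(rng.normal(1.2, 0.3, n_cells), 0.25),
            rng.uniform(0.0, 0.15, n_cells),
        )
        rows.append(expr)
        names.append(f"NULL{i + 1:03d}")

    cells = [f"cell{i + 1:05d}" for i in range(n_cells)]
    matrix = pd.DataFrame(np.vstack(rows) if rows else np.empty((0, n_cells)),
                          index=names, columns=cells)
    return matrix, t, truth


# ---------------------------------------------------------------------------
# cohort writer
# ---------------------------------------------------------------------------

def write_cohort(matrices: list[CountMatrix], truth: GroundTruth, outdir: str | Path) -> None:
    """Write one MTX triplet directory per patient plus ground truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for m in matrices:
        patient = m.cell_meta["patient_id"].iloc[0]
        write_counts(m, outdir / str(patient), fmt="mtx")
    truth.to_json(outdir / "ground_truth.json")
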