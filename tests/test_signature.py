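"""Signature derivation: archetype scoring, frequency knee, specificity split."""

import numpy as np
import pandas as pd
import pytest

import metasig as ms
from metasig.archetypes import ArchetypeProgram
from metasig.signature import (
    FrequencyTable,
    core_signature,
    gene_frequency,
    knee_threshold,
    load_packaged_signature,
    refine,
    score_programs,
    select_archetypes,
    specificity,
)
from tests.conftest import make_lognorm


def make_program(arch_id, footprint: pd.Series, top: int | None = None) -> ArchetypeProgram:
    order = footprint.sort_values(ascending=False).index.tolist()
    return ArchetypeProgram(arch_id, footprint, order[: (top or len(order))])


def knee_oracle(counts):
    """Independent implementation of the recursive max-distance knee:
    plain loops, trimming the tail left of any below-chord maximum."""
    counts = list(counts)
    end = len(counts)
    while True:
        seg = counts[:end]
        if len(seg) < 3 or len(set(seg)) < 3 or seg[0] == seg[-1]:
            return min(seg)
        best, best_d = None, -1.0
        span = seg[0] - seg[-1]
        for i, c in enumerate(seg):
            x = i / (len(seg) - 1)
            y = (c - seg[-1]) / span
            d = abs(x + y - 1.0)
            if d > best_d:
                best, best_d = i, d
        x = best / (len(seg) - 1)
        y = (seg[best] - seg[-1]) / span
        if x + y - 1.0 >= 0 or best == 0:
            return seg[best]
        end = best + 1


class TestScorePrograms:
    def test_seed_set_at_top_scores_one(self):
        genes = [f"g{i}" for i in range(30)]
        fp = pd.Series(np.linspace(3, 0.1, 30), index=genes)
        progs = {"P1": [make_program("P1:a0", fp)]}
        seeds = [ms.GeneSet("s", genes[:5])]
        out = score_programs(progs, seeds, r_max=30)
        assert out["combined"].iloc[0] == pytest.approx(1.0)

    def test_random_footprints_score_half(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(1000)]
        progs = {"P1": [make_program(f"P1:a{j}", pd.Series(rng.normal(size=1000), index=genes))
                        for j in range(500)]}
        seeds = [ms.GeneSet("s", list(rng.choice(genes, 20, replace=False)))]
        out = score_programs(progs, seeds, r_max=1000)
        assert out["combined"].mean() == pytest.approx(0.5, abs=0.05)

    def test_two_evidence_tiers_averaged(self):
        genes = [f"g{i}" for i in range(20)]
        fp = pd.Series(np.linspace(2, 0, 20), index=genes)
        progs = {"P1": [make_program("P1:a0", fp)]}
        s_hi = ms.GeneSet("multi", genes[:3], "multi-evidence")
        s_lo = ms.GeneSet("single", genes[-3:], "single-evidence")
        out = score_programs(progs, [s_hi, s_lo], r_max=20)
        expected = (out["score_multi"] + out["score_single"]) / 2
        np.testing.assert_allclose(out["combined"], expected)


class TestSelectArchetypes:
    def _scores(self, values, patient="P1"):
        return pd.DataFrame({
            "patient_id": patient,
            "archetype_id": [f"a{i}" for i in range(len(values))],
            "combined": values,
        })

    def test_quarter_of_eight_is_two(self):
        out = select_archetypes(self._scores([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]))
        assert len(out) == 2
        assert set(out["archetype_id"]) == {"a6", "a7"}

    def test_all_tied_keeps_all(self):
        out = select_archetypes(self._scores([0.5] * 6))
        assert len(out) == 6

    def test_selection_is_within_patient(self):
        df = pd.concat([self._scores([0.1, 0.2, 0.3, 0.4], "P1"),
                        self._scores([0.6, 0.7, 0.8, 0.9], "P2")], ignore_index=True)
        out = select_archetypes(df)
        assert set(out["patient_id"]) == {"P1", "P2"}


class TestGeneFrequency:
    def test_enumerated_counts(self):
        progs = {
            "P1": [make_program("P1:a0", pd.Series({"A": 2.0, "B": 1.0, "Z": -1.0}), top=2),
                   make_program("P1:a1", pd.Series({"B": 2.0, "C": 1.0, "Z": -1.0}), top=2)],
            "P2": [make_program("P2:a0", pd.Series({"B": 2.0, "Z": -1.0}), top=1)],
        }
        selected = pd.DataFrame({
            "patient_id": ["P1", "P1", "P2"],
            "archetype_id": ["P1:a0", "P1:a1", "P2:a0"],
            "combined": [1.0, 1.0, 1.0],
        })
        t = gene_frequency(selected, progs)
        assert t.counts.to_dict() == {"B": 3, "A": 1, "C": 1}
        assert t.counts.index[0] == "B"


class TestKneeThreshold:
    def test_worked_cliff_example(self):
        counts = [100, 98, 96, 94, 10, 9, 8]
        t = knee_threshold(FrequencyTable(pd.Series(counts, index=list("abcdefg"))))
        assert t.threshold == 94
        assert t.threshold == knee_oracle(counts)

    def test_matches_oracle_on_random_curves(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            block = np.sort(rng.integers(8, 20, rng.integers(3, 30)))[::-1]
            tail = np.sort(rng.integers(1, 6, rng.integers(3, 200)))[::-1]
            counts = np.concatenate([block, tail])
            t = knee_threshold(FrequencyTable(
                pd.Series(counts, index=[f"g{i}" for i in range(counts.size)])))
            assert t.threshold == knee_oracle(counts)

    def test_linear_curve_degenerate(self):
        counts = [10, 9, 8, 7, 6, 5]
        t = knee_threshold(FrequencyTable(pd.Series(counts, index=list("abcdef"))))
        assert t.degenerate
        assert t.threshold == 5

    def test_override_bypasses_knee(self):
        t = knee_threshold(FrequencyTable(pd.Series([30, 2, 1], index=list("abc"))),
                           override=25)
        assert t.threshold == 25

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            knee_threshold(FrequencyTable(pd.Series([5, 1], index=list("ab"))))


class TestCoreSignature:
    def test_threshold_one_keeps_all(self):
        t = FrequencyTable(pd.Series({"B": 3, "A": 1, "C": 1}), threshold=1)
        assert core_signature(t).genes == ["B", "A", "C"]

    def test_enumerated_cut(self):
        t = FrequencyTable(pd.Series({"B": 3, "A": 1, "C": 1}), threshold=2)
        assert core_signature(t).genes == ["B"]

    def test_empty_result_raises(self):
        t = FrequencyTable(pd.Series({"B": 3}), threshold=10)
        with pytest.raises(ValueError, match="threshold"):
            core_signature(t)


class TestSpecificity:
    def _matrix(self, means_by_type, n_per=30, seed=0):
        """Two tumours; each gene's expression is constant at the given
        per-type mean."""
        rng = np.random.default_rng(seed)
        types = list(means_by_type[next(iter(means_by_type))].keys())
        cols, meta_rows = [], []
        for pat in ("T1", "T2"):
            for ct in types:
                for i in range(n_per):
                    cols.append([means_by_type[g][ct] for g in means_by_type])
                    meta_rows.append((f"{pat}-{ct}-{i}", pat, ct))
        vals = np.array(cols).T
        meta = pd.DataFrame(meta_rows, columns=["cell_id", "patient_id", "cell_type"]
                            ).set_index("cell_id")
        return make_lognorm(vals, genes=list(means_by_type),
                            cells=meta.index.tolist(), meta=meta)

    def test_exclusive_gene_share_one(self):
        m = self._matrix({"gE": {"epithelial": 2.0, "fibroblast": 0.0},
                          "gF": {"epithelial": 0.0, "fibroblast": 1.0}})
        sm = specificity(m, ["gE", "gF"], k_clusters=2)
        assert sm.shares.loc["gE", "epithelial"] == pytest.approx(1.0)
        assert sm.shares.loc["gE", "fibroblast"] == pytest.approx(0.0)

    def test_hand_computed_shares(self):
        m = self._matrix({"g": {"a": 2.0, "b": 1.0, "c": 1.0, "d": 0.0},
                          "h": {"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0}})
        sm = specificity(m, ["g", "h"], k_clusters=2)
        np.testing.assert_allclose(sm.shares.loc["g"],
                                   [0.5, 0.25, 0.25, 0.0], atol=1e-9)
        np.testing.assert_allclose(sm.shares.loc["h"], [0.25] * 4, atol=1e-9)

    def test_rows_sum_to_one(self, small_cohort):
        _, matrices, truth = small_cohort
        m = ms.lognorm(ms.qc_filter(matrices[0]))
        genes = sorted(truth.program_genes)[:20]
        sm = specificity(m, genes, k_clusters=3)
        np.testing.assert_allclose(sm.shares.sum(axis=1), 1.0, atol=1e-9)


class TestRefine:
    def test_planted_halves_split(self):
        rng = np.random.default_rng(5)
        epi = {f"E{i}": {"epithelial": 2.0 + rng.uniform(0, 0.5),
                         "fibroblast": 0.05} for i in range(10)}
        fib = {f"F{i}": {"epithelial": 0.05,
                         "fibroblast": 1.5 + rng.uniform(0, 0.5)} for i in range(10)}
        m = TestSpecificity()._matrix({**epi, **fib})
        core = ms.Signature("core", list(epi) + list(fib), "core")
        sm = specificity(m, core.genes, k_clusters=4)
        refined, residual = refine(core, sm, target="epithelial")
        assert set(refined.genes) == set(epi)
        assert set(residual.genes) == set(fib)
        assert sorted(refined.genes + residual.genes) == sorted(core.genes)

    def test_homogeneous_core_all_refined(self):
        epi = {f"E{i}": {"epithelial": 2.0, "fibroblast": 0.0} for i in range(8)}
        m = TestSpecificity()._matrix(epi)
        core = ms.Signature("core", list(epi), "core")
        sm = specificity(m, core.genes, k_clusters=2)
        refined, residual = refine(core, sm, target="epithelial")
        assert refined.genes == core.genes
        assert residual.genes == []

    def test_impossible_floor_reports_means(self):
        epi = {f"E{i}": {"epithelial": 1.0, "fibroblast": 1.0} for i in range(6)}
        m = TestSpecificity()._matrix(epi)
        core = ms.Signature("core", list(epi), "core")
        sm = specificity(m, core.genes, k_clusters=2)
        with pytest.raises(ValueError, match="floor"):
            refine(core, sm, target="epithelial", min_mean_specificity=0.99)


class TestPackagedLists:
    def test_cardinalities(self):
        refined = load_packaged_signature("refined")
        residual = load_packaged_signature("residual")
        core = load_packaged_signature("core")
        assert len(refined) == 177
        assert len(residual) == 109
        assert len(core) == 286
        assert set(core.genes) == set(refined.genes) | set(residual.genes)
        assert not set(refined.genes) & set(residual.genes)
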