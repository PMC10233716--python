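"""Peak-to-gene assignment, the FPKM DE rule, and target-set algebra."""

import numpy as np
import pandas as pd
import pytest

import circuitcall as cc
from circuitcall import GeneAnnotation, Peak, PeakSet
from circuitcall.targets import (
    NEAREST_DOWNSTREAM,
    NEAREST_UPSTREAM,
    PROMOTER,
    build_cluster_gene_set,
)

from conftest import make_annotation, make_peakset


def ann_from(pairs):
    return GeneAnnotation(
        pd.DataFrame(
            [{"gene_id": g, "chrom": "chr1", "strand": "+", "tss": t} for g, t in pairs]
        )
    )


def assignment_oracle(ps, ann, w=2000):
    """Brute force over all gene-summit pairs."""
    out = {}
    for p in ps:
        sub = ann.table[ann.table["chrom"] == p.chrom]
        if sub.empty:
            continue
        prom = sub[(sub["tss"] - p.summit).abs() <= w]
        if len(prom):
            for g in prom["gene_id"]:
                out.setdefault(g, set()).add((p.name, PROMOTER))
            continue
        left = sub[sub["tss"] <= p.summit]
        if len(left):
            best = left[left["tss"] == left["tss"].max()]["gene_id"].min()
            out.setdefault(best, set()).add((p.name, NEAREST_UPSTREAM))
        right = sub[sub["tss"] > p.summit]
        if len(right):
            best = right[right["tss"] == right["tss"].min()]["gene_id"].min()
            out.setdefault(best, set()).add((p.name, NEAREST_DOWNSTREAM))
    return out


class TestAssignment:
    def test_summit_at_window_edge_is_promoter(self):
        ann = ann_from([("a", 10_000)])
        ps = PeakSet("x", [Peak("chr1", 11_900, 12_100, 11_999, name="p")])
        res = cc.assign_peaks_to_genes(ps, ann)
        assert res.by_gene["a"].peaks[0][1] == PROMOTER

    def test_non_promoter_summit_assigns_both_neighbours(self):
        ann = ann_from([("a", 10_000), ("b", 45_000)])
        ps = PeakSet("x", [Peak("chr1", 14_900, 15_100, 15_000, name="p")])
        res = cc.assign_peaks_to_genes(ps, ann)
        assert set(res.by_gene) == {"a", "b"}
        assert res.by_gene["a"].modes == {NEAREST_UPSTREAM}
        assert res.by_gene["b"].modes == {NEAREST_DOWNSTREAM}

    def test_chrom_without_genes_flags_unassigned(self):
        ann = ann_from([("a", 10_000)])
        ps = PeakSet("x", [Peak("chr2", 0, 200, 100, name="p")])
        res = cc.assign_peaks_to_genes(ps, ann)
        assert [p.name for p in res.unassigned] == ["p"]

    def test_matches_exhaustive_oracle(self, rng):
        ann = make_annotation(rng, n_genes=40)
        ps = make_peakset(rng, n=250)
        res = cc.assign_peaks_to_genes(ps, ann)
        got = {g: {(p.name, m) for p, m in ga.peaks} for g, ga in res.by_gene.items()}
        assert got == assignment_oracle(ps, ann)

    def test_every_summit_assigned_when_chrom_has_genes(self, rng):
        ann = make_annotation(rng, n_genes=40)
        ps = make_peakset(rng, n=150)
        res = cc.assign_peaks_to_genes(ps, ann)
        assigned = {p.name for ga in res.by_gene.values() for p, _ in ga.peaks}
        assert assigned | {p.name for p in res.unassigned} == {p.name for p in ps}


def expr_from(gene_values, conditions=("WT", "KO"), reps=2):
    """gene_values: gene -> {condition: mean} with identical replicates."""
    cols = {}
    for cond in conditions:
        for r in range(1, reps + 1):
            cols[f"{cond}.r{r}"] = [gene_values[g][cond] for g in gene_values]
    return cc.ExpressionMatrix(
        pd.DataFrame(cols, index=pd.Index(list(gene_values), name="gene_id"))
    )


class TestDECalling:
    def test_fourfold_change_passes(self):
        expr = expr_from({"a": {"WT": 8.0, "KO": 2.0}})
        de = cc.call_de_genes(expr, "WT", "KO")
        row = de.loc["a"]
        assert row["log2fc"] == pytest.approx(np.log2(8.1 / 2.1))
        assert row["direction"] == "activated"
        assert bool(row["passed_filter"])

    def test_low_expression_fails_fpkm_filter(self):
        expr = expr_from({"a": {"WT": 0.5, "KO": 0.05}})
        de = cc.call_de_genes(expr, "WT", "KO")
        assert not bool(de.loc["a", "passed_filter"])

    def test_small_fold_change_fails(self):
        expr = expr_from({"a": {"WT": 4.0, "KO": 3.0}})
        de = cc.call_de_genes(expr, "WT", "KO")
        assert abs(de.loc["a", "log2fc"]) < 1
        assert not bool(de.loc["a", "passed_filter"])

    def test_missing_condition_is_an_error(self):
        expr = expr_from({"a": {"WT": 4.0, "KO": 3.0}})
        with pytest.raises(ValueError, match="replicate"):
            cc.call_de_genes(expr, "WT", "EKO")

    def test_scale_invariance(self, rng):
        values = {f"g{i}": {"WT": float(v), "KO": float(w)}
                  for i, (v, w) in enumerate(rng.uniform(10, 100, size=(30, 2)))}
        e1 = expr_from(values)
        e2 = cc.ExpressionMatrix(e1.values * 7.0)
        d1 = cc.call_de_genes(e1, "WT", "KO")
        d2 = cc.call_de_genes(e2, "WT", "KO")
        assert np.abs(d1["log2fc"] - d2["log2fc"]).max() < 0.01

    def test_direction_antisymmetric_under_condition_swap(self, rng):
        values = {f"g{i}": {"WT": float(v), "KO": float(w)}
                  for i, (v, w) in enumerate(rng.uniform(2, 100, size=(30, 2)))}
        expr = expr_from(values)
        fwd = cc.call_de_genes(expr, "WT", "KO")
        rev = cc.call_de_genes(expr, "KO", "WT")
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        flipped = fwd["direction"].map(
            {"activated": "repressed", "repressed": "activated"})
        nonzero = fwd["log2fc"] != 0
        assert (rev.loc[nonzero, "direction"] == flipped[nonzero]).all()


class TestDirectTargets:
    def test_empty_bound_set_gives_empty_targets(self):
        expr = expr_from({"a": {"WT": 8.0, "KO": 2.0}})
        de = cc.call_de_genes(expr, "WT", "KO")
        ts = cc.call_direct_targets(set(), de, "T")
        assert len(ts) == 0

    def test_de_but_unbound_gene_excluded(self):
        expr = expr_from({"a": {"WT": 8.0, "KO": 2.0}, "b": {"WT": 40.0, "KO": 10.0}})
        de = cc.call_de_genes(expr, "WT", "KO")
        ts = cc.call_direct_targets({"a"}, de, "T")
        assert set(ts.activated) == {"a"}

    def test_activated_and_repressed_disjoint(self):
        expr = expr_from({"a": {"WT": 8.0, "KO": 2.0}, "b": {"WT": 2.0, "KO": 8.0}})
        de = cc.call_de_genes(expr, "WT", "KO")
        ts = cc.call_direct_targets({"a", "b"}, de, "T")
        assert ts.activated == frozenset({"a"})
        assert ts.repressed == frozenset({"b"})
        assert not (ts.activated & ts.repressed)


class TestSetAlgebra:
    def test_identical_sets_have_empty_symmetric_difference(self):
        t = cc.target_set_algebra({"A": {"x", "y"}, "B": {"x", "y"}})
        assert t.exclusive_counts() == {("A", "B"): 2}
        assert t.intersection_size == 2

    def test_disjoint_sets(self):
        t = cc.target_set_algebra({"A": {"x"}, "B": {"y", "z"}})
        assert t.pairwise[("A", "B")] == 0
        assert t.union_size == 3

    def test_inclusion_exclusion_on_random_sets(self, rng):
        universe = [f"g{i}" for i in range(100)]
        sets = {
            lbl: set(rng.choice(universe, size=int(rng.integers(20, 60)), replace=False))
            for lbl in "ABC"
        }
        t = cc.target_set_algebra(sets)
        total = sum(len(v) for v in t.exclusive.values())
        assert total == t.union_size == len(sets["A"] | sets["B"] | sets["C"])
        ie = (
            len(sets["A"]) + len(sets["B"]) + len(sets["C"])
            - t.pairwise[("A", "B")] - t.pairwise[("A", "C")] - t.pairwise[("B", "C")]
            + t.intersection_size
        )
        assert ie == t.union_size


class TestClusterGeneSet:
    def test_union_arithmetic(self):
        de1 = pd.DataFrame({"passed_filter": [True] * 3 + [False]},
                           index=["a", "b", "c", "x"])
        de2 = pd.DataFrame({"passed_filter": [True] * 4},
                           index=["d", "e", "f", "g"])
        out = build_cluster_gene_set({"a", "b", "c", "d", "e", "f", "g"}, de1, de2)
        assert out == {"a", "b", "c", "d", "e", "f", "g"} - {"x"}

    def test_nested_de_lists_collapse_to_superset(self):
        de1 = pd.DataFrame({"passed_filter": [True, True]}, index=["a", "b"])
        de2 = pd.DataFrame({"passed_filter": [True]}, index=["a"])
        assert build_cluster_gene_set({"a", "b"}, de1, de2) == {"a", "b"}
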