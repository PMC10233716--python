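"""Direct-target inference: peak-to-gene assignment and the FPKM DE rule.

A gene is *bound* by a TF when a peak summit falls inside its promoter
window (TSS +/- ``W_PROM``) or when it is the nearest promoter up- or
downstream of a non-promoter summit (both neighbours are assigned, in
genomic coordinate orientation).  A bound gene that is differentially
expressed between WT and the matching TF knockout is a putative *direct
target* of that TF.

Differential expression is a pure threshold rule on replicate-averaged
FPKM: a gene must exceed ``fpkm_min`` in at least one sample of the
comparison and have ``|log2((mean_WT + pc) / (mean_KO + pc))| > lfc_min``.
No statistical test is applied; there are no p-values to correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, GeneAnnotation, PeakSet, W_PROM

PROMOTER = "promoter"
NEAREST_UPSTREAM = "nearest_upstream"
NEAREST_DOWNSTREAM = "nearest_downstream"


@dataclass
class GeneAssignment:
    gene_id: str
    peaks: list = field(default_factory=list)  # (Peak, mode) pairs

    @property
    def modes(self):
        return {m for _, m in self.peaks}


@dataclass
class AssignmentResult:
    by_gene: dict              # gene_id -> GeneAssignment
    unassigned: list           # peaks on chromosomes without genes

    @property
    def bound_genes(self) -> set:
        return set(self.by_gene)


def assign_peaks_to_genes(ps: PeakSet, ann: GeneAnnotation, w: int = W_PROM) -> AssignmentResult:
    """Assign every peak summit to its gene(s).

    Summits within any promoter window (|summit - tss| <= w) assign to all
    such genes with mode ``promoter``.  Every remaining summit assigns to
    the gene with the nearest TSS to its left and the gene with the nearest
    TSS to its right (genomic orientation), when each exists; ties at equal
    TSS break to the smallest gene_id.
    """
    if len(ann) == 0:
        raise ValueError("annotation is empty")
    by_gene: dict = {}
    unassigned = []

    def add(gene_id, peak, mode):
        ga = by_gene.setdefault(gene_id, GeneAssignment(gene_id))
        ga.peaks.append((peak, mode))

    for p in ps:
        arrays = ann.chrom_arrays(p.chrom)
        if arrays is None:
            unassigned.append(p)
            continue
        tss, gids = arrays
        prom_genes = ann.genes_in_window(p.chrom, p.summit - w, p.summit + w)
        if prom_genes:
            for g in prom_genes:
                add(g, p, PROMOTER)
            continue
        # nearest TSS at or left of the summit
        i = int(np.searchsorted(tss, p.summit, side="right")) - 1
        if i >= 0:
            left_tss = int(tss[i])
            lo = int(np.searchsorted(tss, left_tss, side="left"))
            hi = int(np.searchsorted(tss, left_tss, side="right"))
            add(min(gids[lo:hi]), p, NEAREST_UPSTREAM)
        # nearest TSS strictly right of the summit
        j = int(np.searchsorted(tss, p.summit, side="right"))
        if j < len(tss):
            right_tss = int(tss[j])
            lo = int(np.searchsorted(tss, right_tss, side="left"))
            hi = int(np.searchsorted(tss, right_tss, side="right"))
            add(min(gids[lo:hi]), p, NEAREST_DOWNSTREAM)
    return AssignmentResult(by_gene=by_gene, unassigned=unassigned)


ACTIVATED = "activated"   # WT > KO
REPRESSED = "repressed"   # WT < KO


def call_de_genes(
    expr: ExpressionMatrix,
    wt: str,
    ko: str,
    day: int | None = None,
    fpkm_min: float = 1.0,
    lfc_min: float = 1.0,
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Threshold-rule differential expression between two conditions.

    Returns a DataFrame indexed by gene_id with columns ``mean_wt``,
    ``mean_ko``, ``max_fpkm`` (over all samples of the comparison),
    ``log2fc`` (WT over KO, pseudocounted), ``direction`` and
    ``passed_filter``.
    """
    wt_cols = expr.select_samples(wt, day)
    ko_cols = expr.select_samples(ko, day)
    if not wt_cols or not ko_cols:
        raise ValueError(
            f"need >= 1 replicate per condition, got {len(wt_cols)} for {wt!r} "
            f"and {len(ko_cols)} for {ko!r} (day={day})"
        )
    mean_wt = expr.values[wt_cols].mean(axis=1)
    mean_ko = expr.values[ko_cols].mean(axis=1)
    max_fpkm = expr.values[wt_cols + ko_cols].max(axis=1)
    log2fc = np.log2((mean_wt + pseudocount) / (mean_ko + pseudocount))
    direction = np.where(log2fc > 0, ACTIVATED, REPRESSED)
    passed = (max_fpkm > fpkm_min) & (np.abs(log2fc) > lfc_min)
    return pd.DataFrame(
        {
            "mean_wt": mean_wt,
            "mean_ko": mean_ko,
            "max_fpkm": max_fpkm,
            "log2fc": log2fc,
            "direction": direction,
            "passed_filter": passed,
        }
    )


@dataclass(frozen=True)
class DirectTargetSet:
    """Putative direct targets of one TF: bound AND differentially expressed."""

    tf: str
    activated: frozenset
    repressed: frozenset
    day: int | None = None

    @property
    def all_targets(self) -> frozenset:
        return self.activated | self.repressed

    def __len__(self):
        return len(self.activated) + len(self.repressed)


def call_direct_targets(
    bound: set, de: pd.DataFrame, tf: str, day: int | None = None
) -> DirectTargetSet:
    """Intersect a TF's bound-gene set with its DE table."""
    passed = de.loc[de["passed_filter"]]
    act = frozenset(passed.index[passed["direction"] == ACTIVATED]) & frozenset(bound)
    rep = frozenset(passed.index[passed["direction"] == REPRESSED]) & frozenset(bound)
    return DirectTargetSet(tf=tf, activated=act, repressed=rep, day=day)


@dataclass
class TargetOverlapTable:
    """Exclusive-region and pairwise overlap counts for labelled gene sets."""

    labels: list
    exclusive: dict        # frozenset(labels present) -> sorted member list
    pairwise: dict         # (label_a, label_b) -> intersection count
    union_size: int
    intersection_size: int

    def exclusive_counts(self) -> dict:
        return {tuple(sorted(k)): len(v) for k, v in self.exclusive.items()}

    def as_dict(self) -> dict:
        return {
            "labels": self.labels,
            "exclusive": {"+".join(sorted(k)): len(v) for k, v in self.exclusive.items()},
            "pairwise": {f"{a}&{b}": n for (a, b), n in sorted(self.pairwise.items())},
            "union": self.union_size,
            "intersection": self.intersection_size,
        }


def target_set_algebra(sets: dict) -> TargetOverlapTable:
    """All exclusive regions and pairwise intersections of >= 2 gene sets.

    ``sets`` maps label -> iterable of gene ids (a DirectTargetSet is
    accepted and flattened to its full target set).
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    flat = {}
    for label, s in sets.items():
        if isinstance(s, DirectTargetSet):
            flat[label] = set(s.all_targets)
        else:
            flat[label] = set(s)
    labels = sorted(flat)
    universe = set().union(*flat.values())
    exclusive: dict = {}
    for g in universe:
        sig = frozenset(lbl for lbl in labels if g in flat[lbl])
        exclusive.setdefault(sig, []).append(g)
    exclusive = {k: sorted(v) for k, v in exclusive.items()}
    pairwise = {
        (a, b): len(flat[a] & flat[b]) for a, b in combinations(labels, 2)
    }
    inter = set(flat[labels[0]])
    for lbl in labels[1:]:
        inter &= flat[lbl]
    return TargetOverlapTable(
        labels=labels,
        exclusive=exclusive,
        pairwise=pairwise,
        union_size=len(universe),
        intersection_size=len(inter),
    )


def build_cluster_gene_set(
    tf_bound: set, de_single_ko: pd.DataFrame, de_dko: pd.DataFrame
) -> set:
    """Gene universe for expression clustering.

    Union of (bound AND DE in the single KO) with (bound AND DE in the
    double KO), both against the same WT.
    """
    bound = set(tf_bound)
    de1 = set(de_single_ko.index[de_single_ko["passed_filter"]])
    de2 = set(de_dko.index[de_dko["passed_filter"]])
    return (bound & de1) | (bound & de2)
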