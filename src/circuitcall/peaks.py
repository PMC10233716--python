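"""Peak-set algebra: KO-controlled filtering, overlaps, distance summaries.

Knockout cells for a TF should carry no genuine binding of that TF, so any
WT peak that coincides with a (leniently called) peak in the matching KO
sample is treated as a false positive and discarded.  "Coincides" uses the
same summit-distance convention as peak-set overlap: two peaks overlap iff
their summits lie within ``D_OVERLAP`` (default 300 bp) on the same
chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    D_DISTAL,
    D_OVERLAP,
    INF,
    W_PROM,
    GeneAnnotation,
    PeakSet,
    distance_to_nearest_tss,
)

#: MACS2 q-value tiers used for the WT ChIP samples of each factor, and the
#: lenient tier applied to every factor in its matching KO sample.
DEFAULT_QVALUE_TABLE = {
    "T": 1e-4,
    "SMAD15": 5e-4,
    "SMAD2": 1e-7,
    "EOMES": 5e-4,
    "OCT4": 1e-4,
    "SOX2": 1e-4,
    "NANOG": 1e-4,
}
KO_QVALUE = 1e-2


def _has_summit_within(summits_by_chrom: dict, chrom: str, summit: int, d: float) -> bool:
    arr = summits_by_chrom.get(chrom)
    if arr is None or len(arr) == 0:
        return False
    i = int(np.searchsorted(arr, summit))
    for j in (i - 1, i):
        if 0 <= j < len(arr) and abs(int(arr[j]) - summit) < d:
            return True
    return False


def filter_ko_false_positives(wt: PeakSet, ko: PeakSet, d: int = D_OVERLAP):
    """Discard WT peaks whose summit lies within ``d`` bp of any KO summit.

    Returns ``(retained, discarded)`` as two PeakSets partitioning ``wt``.
    With an empty KO set this is the identity on ``wt``.
    """
    if d < 0:
        raise ValueError(f"summit-distance threshold must be >= 0, got {d}")
    ko_summits = ko.summits_by_chrom()
    retained, discarded = [], []
    for p in wt:
        if _has_summit_within(ko_summits, p.chrom, p.summit, d):
            discarded.append(p)
        else:
            retained.append(p)
    return (
        PeakSet(f"{wt.label}", retained),
        PeakSet(f"{wt.label}.ko_discarded", discarded),
    )


def apply_qvalue_cutoff(ps: PeakSet, tf: str, table: dict | None = None) -> PeakSet:
    """Retain peaks with q-value <= the per-TF cutoff.

    Peaks lacking a q-value are retained with a warning; an unknown TF is an
    error (a silent default would hide a mislabeled input).
    """
    table = DEFAULT_QVALUE_TABLE if table is None else table
    if tf not in table:
        raise KeyError(f"no q-value cutoff declared for TF {tf!r}")
    cutoff = table[tf]
    kept = []
    n_missing = 0
    for p in ps:
        if p.qvalue is None:
            n_missing += 1
            kept.append(p)
        elif p.qvalue <= cutoff:
            kept.append(p)
    if n_missing:
        warnings.warn(
            f"{ps.label}: {n_missing} peaks lack a q-value and were retained",
            stacklevel=2,
        )
    return PeakSet(ps.label, kept)


@dataclass
class VennResult:
    """Per-set overlap counts between two peak sets.

    Membership is per-peak ("any opposite-set summit within d"), so counts
    are reported per input set: ``both_a`` counts A-peaks matched by B and
    ``both_b`` counts B-peaks matched by A; the two may differ when one peak
    matches several opposite peaks.
    """

    labels: tuple
    a_only: int
    both_a: int
    both_b: int
    b_only: int
    membership_a: list = field(default_factory=list, repr=False)
    membership_b: list = field(default_factory=list, repr=False)

    def as_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "a_only": self.a_only,
            "both_a": self.both_a,
            "both_b": self.both_b,
            "b_only": self.b_only,
        }


def overlap_peaksets(a: PeakSet, b: PeakSet, d: int = D_OVERLAP) -> VennResult:
    """Two-set summit-distance overlap (peaks overlap iff summits < d apart)."""
    if d < 0:
        raise ValueError(f"summit-distance threshold must be >= 0, got {d}")
    b_summits = b.summits_by_chrom()
    a_summits = a.summits_by_chrom()
    mem_a = [_has_summit_within(b_summits, p.chrom, p.summit, d) for p in a]
    mem_b = [_has_summit_within(a_summits, p.chrom, p.summit, d) for p in b]
    both_a = int(sum(mem_a))
    both_b = int(sum(mem_b))
    return VennResult(
        labels=(a.label, b.label),
        a_only=len(a) - both_a,
        both_a=both_a,
        both_b=both_b,
        b_only=len(b) - both_b,
        membership_a=mem_a,
        membership_b=mem_b,
    )


#: Default symmetric bin edges (bp) for summit-to-nearest-TSS histograms.
DEFAULT_BIN_EDGES = (
    -INF, -100_000, -50_000, -10_000, -2_000, 0, 2_000, 10_000, 50_000, 100_000, INF,
)


@dataclass
class DistanceHistogram:
    """Binned summit-to-nearest-TSS distances for one peak set."""

    bin_edges: tuple
    counts: np.ndarray
    n_assigned: int
    n_unassigned: int
    frac_promoter: float       # |distance| <= W_PROM
    frac_promoter_far: float   # |distance| > W_PROM
    frac_distal: float         # |distance| > D_DISTAL

    def as_dict(self) -> dict:
        return {
            "bin_edges": [e for e in self.bin_edges],
            "counts": self.counts.tolist(),
            "n_assigned": self.n_assigned,
            "n_unassigned": self.n_unassigned,
            "frac_promoter": self.frac_promoter,
            "frac_promoter_far": self.frac_promoter_far,
            "frac_distal": self.frac_distal,
        }


def promoter_distance_histogram(
    ps: PeakSet,
    ann: GeneAnnotation,
    edges=DEFAULT_BIN_EDGES,
    w_prom: int = W_PROM,
    d_distal: int = D_DISTAL,
) -> DistanceHistogram:
    """Distances between peak summits and their nearest gene TSS, binned.

    Peaks on chromosomes without genes are excluded from the histogram and
    counted separately as unassigned.
    """
    if len(ann) == 0:
        raise ValueError("annotation is empty")
    dists = []
    n_unassigned = 0
    for p in ps:
        gene, dist = distance_to_nearest_tss(p, ann)
        if gene is None:
            n_unassigned += 1
        else:
            dists.append(dist)
    dists = np.asarray(dists, dtype=float)
    edges_arr = np.asarray(edges, dtype=float)
    counts, _ = np.histogram(dists, bins=edges_arr)
    n = len(dists)
    if n:
        absd = np.abs(dists)
        frac_prom = float((absd <= w_prom).mean())
        frac_far = float((absd > w_prom).mean())
        frac_distal = float((absd > d_distal).mean())
    else:
        frac_prom = frac_far = frac_distal = float("nan")
    return DistanceHistogram(
        bin_edges=tuple(edges),
        counts=counts,
        n_assigned=n,
        n_unassigned=n_unassigned,
        frac_promoter=frac_prom,
        frac_promoter_far=frac_far,
        frac_distal=frac_distal,
    )
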