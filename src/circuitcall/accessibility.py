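"""Differential chromatin accessibility and TF-occupancy classification.

The DA caller is a deliberately simple, fully documented rule operating on
counts-per-million (CPM): a region is differentially accessible between WT
and KO when the pseudocounted log2 ratio of mean CPM exceeds a threshold,
the region is adequately covered, and every WT/KO replicate pair agrees on
the sign of the change.  "Activated" means more accessible in WT
(WT > KO); "repressed" the reverse.

Occupancy classification asks, for each DA region, which ChIP summits fall
inside the region interval, and maps the answer onto six disjoint groups:
three Smad groups (Smad1/5-solo, Smad1/5/2, Smad2-solo), full pluripotency
co-occupancy (OSN = Oct4+Sox2+Nanog), partial pluripotency occupancy
(O/S/N = any one or two), or none.  Smad occupancy takes precedence over
pluripotency occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneAnnotation, Region, RegionCountMatrix, PeakSet

ACTIVATED = "activated"   # WT > KO
REPRESSED = "repressed"   # WT < KO

# the six disjoint occupancy groups
SMAD15_SOLO = "SMAD15_SOLO"
SMAD152 = "SMAD152"
SMAD2_SOLO = "SMAD2_SOLO"
OSN = "OSN"
OSN_PARTIAL = "OSN_PARTIAL"
NONE = "NONE"
OCCUPANCY_GROUPS = (SMAD15_SOLO, SMAD152, SMAD2_SOLO, OSN, OSN_PARTIAL, NONE)


@dataclass(frozen=True)
class DARegion:
    region: Region
    log2fc: float            # WT over KO, on mean CPM
    direction: str
    mean_cpm_wt: float
    mean_cpm_ko: float
    occupancy: str | None = None


def call_da_regions(
    counts: RegionCountMatrix,
    wt: str,
    ko: str,
    day: int | None = None,
    lfc_min: float = 1.0,
    min_mean: float = 10.0,
    pseudocount: float = 0.5,
) -> list:
    """Call differentially accessible regions between two conditions.

    A region is DA iff (i) |log2((meanCPM_WT + pc)/(meanCPM_KO + pc))| >=
    ``lfc_min``, (ii) max(meanCPM_WT, meanCPM_KO) >= ``min_mean``, and
    (iii) the pseudocounted log-ratio has the same sign for every WT x KO
    replicate pair.
    """
    wt_cols = counts.select_samples(wt, day)
    ko_cols = counts.select_samples(ko, day)
    if not wt_cols or not ko_cols:
        raise ValueError(f"no samples for {wt!r} or {ko!r} (day={day})")
    cpm = counts.cpm()
    mean_wt = cpm[wt_cols].mean(axis=1)
    mean_ko = cpm[ko_cols].mean(axis=1)
    log2fc = np.log2((mean_wt + pseudocount) / (mean_ko + pseudocount))
    # sign consistency over all WT x KO replicate pairs
    consistent = pd.Series(True, index=cpm.index)
    for wcol in wt_cols:
        for kcol in ko_cols:
            pair_lfc = np.log2((cpm[wcol] + pseudocount) / (cpm[kcol] + pseudocount))
            consistent &= np.sign(pair_lfc) == np.sign(log2fc)
    is_da = (
        (np.abs(log2fc) >= lfc_min)
        & (np.maximum(mean_wt, mean_ko) >= min_mean)
        & consistent
    )
    out = []
    for region in counts.regions:
        rid = region.region_id
        if not bool(is_da[rid]):
            continue
        lfc = float(log2fc[rid])
        out.append(
            DARegion(
                region=region,
                log2fc=lfc,
                direction=ACTIVATED if lfc > 0 else REPRESSED,
                mean_cpm_wt=float(mean_wt[rid]),
                mean_cpm_ko=float(mean_ko[rid]),
            )
        )
    return out


def occupying_tfs(region: Region, peaksets: dict) -> set:
    """Labels of TFs with at least one peak summit inside ``region``.

    A ChIP peak occupies an accessibility region iff its summit coordinate
    lies within the region interval [start, end).
    """
    hits = set()
    for label, ps in peaksets.items():
        summits = ps.summits_by_chrom().get(region.chrom)
        if summits is None:
            continue
        i = int(np.searchsorted(summits, region.start, side="left"))
        j = int(np.searchsorted(summits, region.end - 1, side="right"))
        if j > i:
            hits.add(label)
    return hits


def classify_da_occupancy(das: list, chip: dict, pluri: dict) -> list:
    """Assign each DA region to one of the six occupancy groups.

    ``chip`` maps {"smad15": PeakSet, "smad2": PeakSet}; ``pluri`` maps any
    subset of {"oct4", "sox2", "nanog"} to PeakSets (may be empty).  Smad
    occupancy takes precedence: both Smads -> SMAD152, one -> its solo
    group; otherwise all three pluripotency factors -> OSN, one or two ->
    OSN_PARTIAL, none -> NONE.  The labels partition the input.
    """
    chip = {k.lower(): v for k, v in chip.items()}
    pluri = {k.lower(): v for k, v in pluri.items()}
    out = []
    for da in das:
        smads = occupying_tfs(da.region, chip)
        if {"smad15", "smad2"} <= smads:
            group = SMAD152
        elif "smad15" in smads:
            group = SMAD15_SOLO
        elif "smad2" in smads:
            group = SMAD2_SOLO
        else:
            n_pluri = len(occupying_tfs(da.region, pluri))
            if n_pluri == 3:
                group = OSN
            elif n_pluri >= 1:
                group = OSN_PARTIAL
            else:
                group = NONE
        out.append(replace(da, occupancy=group))
    return out


def activated_fraction_by_group(labeled: list) -> pd.DataFrame:
    """Per-occupancy-group counts and fraction of activated (WT>KO) regions.

    Empty groups report n=0 with an undefined (NaN) fraction.
    """
    rows = []
    for group in OCCUPANCY_GROUPS:
        members = [da for da in labeled if da.occupancy == group]
        n = len(members)
        n_act = sum(1 for da in members if da.direction == ACTIVATED)
        rows.append(
            {
                "group": group,
                "n": n,
                "n_activated": n_act,
                "fraction_activated": (n_act / n) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def quantify_density(
    regions: list,
    reads_by_sample: dict,
    library_sizes: dict,
    extend: int = 0,
) -> pd.DataFrame:
    """Normalized read density per region and sample.

    density(r, s) = (# reads of s overlapping r) / (region length in kb x
    library size in millions).  A read overlaps a region iff they share at
    least one base; ``extend`` symmetrically widens each read by that many
    bp on both sides before overlap testing (fragment-extension emulation,
    default off).

    ``reads_by_sample`` maps sample -> {chrom: (starts, ends)} with starts
    sorted ascending (the layout produced by ``read_reads_bed``).  The
    result is invariant under uniform scaling of reads and library sizes.
    """
    for r in regions:
        if r.length <= 0:
            raise ValueError(f"zero-length region {r.region_id}")
    samples = sorted(reads_by_sample)
    data = np.zeros((len(regions), len(samples)))
    for sj, sample in enumerate(samples):
        lib_m = library_sizes[sample] / 1e6
        if lib_m <= 0:
            raise ValueError(f"library size must be > 0 for sample {sample}")
        per_chrom = {}
        for chrom, (starts, ends) in reads_by_sample[sample].items():
            starts = np.sort(np.asarray(starts, dtype=np.int64) - extend)
            ends = np.sort(np.asarray(ends, dtype=np.int64) + extend)
            per_chrom[chrom] = (starts, ends)
        for ri, r in enumerate(regions):
            arrs = per_chrom.get(r.chrom)
            if arrs is None:
                continue
            starts_sorted, ends_sorted = arrs
            # reads with start < region.end, minus reads fully left of region
            n = int(np.searchsorted(starts_sorted, r.end, side="left")) - int(
                np.searchsorted(ends_sorted, r.start, side="right")
            )
            data[ri, sj] = n / ((r.length / 1000.0) * lib_m)
    return pd.DataFrame(data, index=[r.region_id for r in regions], columns=samples)


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    df: int
    degenerate: str | None = None  # "identical_pairs" or "zero_variance"


def paired_t_test(x, y) -> PairedTResult:
    """Paired two-tailed Student's t-test on differences d = x - y.

    t = mean(d) / (sd(d) / sqrt(n)) with df = n - 1 and a two-tailed p from
    the t distribution.  Identical pairs (all d = 0) return t = 0, p = 1,
    flagged; nonzero constant differences have sd = 0 and report p at the
    machine floor, flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    n = len(x)
    if n < 2:
        raise ValueError("paired t-test requires n >= 2")
    d = x - y
    sd = float(np.std(d, ddof=1))
    md = float(np.mean(d))
    if sd == 0.0:
        if md == 0.0:
            return PairedTResult(t=0.0, p=1.0, df=n - 1, degenerate="identical_pairs")
        t = np.inf if md > 0 else -np.inf
        return PairedTResult(
            t=float(t), p=float(np.nextafter(0, 1)), df=n - 1, degenerate="zero_variance"
        )
    t = md / (sd / sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return PairedTResult(t=float(t), p=p, df=n - 1)


#: TSS-distance classes for DA-region midpoints.
PROXIMAL = "proximal"        # <= 2 kb
INTERMEDIATE = "2-10kb"
DISTAL = "distal"            # > 10 kb


def tss_distance_classes(
    das: list, ann: GeneAnnotation, proximal_max: int = 2000, distal_min: int = 10_000
) -> pd.DataFrame:
    """Classify DA-region midpoints by distance to the nearest TSS.

    Classes: proximal (<= 2 kb), intermediate (2-10 kb), distal (> 10 kb).
    Regions on chromosomes without genes are classed as unassigned.
    """
    rows = []
    for da in das:
        r = da.region
        arrays = ann.chrom_arrays(r.chrom)
        if arrays is None:
            rows.append({"region_id": r.region_id, "distance": np.nan, "klass": "unassigned"})
            continue
        tss, _ = arrays
        mid = r.midpoint
        i = int(np.searchsorted(tss, mid))
        best = np.inf
        for j in (i - 1, i):
            if 0 <= j < len(tss):
                best = min(best, abs(int(tss[j]) - mid))
        if best <= proximal_max:
            klass = PROXIMAL
        elif best <= distal_min:
            klass = INTERMEDIATE
        else:
            klass = DISTAL
        rows.append({"region_id": r.region_id, "distance": float(best), "klass": klass})
    return pd.DataFrame(rows).set_index("region_id")
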