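"""Synthetic multi-omic data with planted regulatory structure.

The generator emulates the design of a knockout-anchored differentiation
study: WT and knockout (Smad4, Eomes, T, Eomes/T double) cells across a
four-day time course, with

- ChIP-seq peak sets per TF and genotype, including planted co-occupancy
  (summit separation < 300 bp) and planted false-positive peaks that
  reappear in the matching KO sample;
- an expression table whose planted direct-target genes carry
  multiplicative fold-change effects (2**lfc_effect) in WT versus the
  matching KO, with lognormal replicate noise;
- accessibility regions whose planted differential-accessibility effects
  are tied to their TF-occupancy group, with Poisson counts, and a
  transient opening profile across the time course;
- a truth table recording every planted entity, used only by tests.

With all noise parameters at zero the downstream pipeline recovers the
planted truth exactly; the construction guarantees this by choosing
decoy differentially-expressed genes only among genes provably unbound
under the package's own assignment rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import core
from .core import (
    GeneAnnotation,
    ExpressionMatrix,
    Peak,
    PeakSet,
    Region,
    RegionCountMatrix,
)
from .accessibility import (
    ACTIVATED,
    REPRESSED,
    SMAD15_SOLO,
    SMAD152,
    SMAD2_SOLO,
    OSN,
    OSN_PARTIAL,
    NONE,
)
from .targets import assign_peaks_to_genes

#: genotype labels
WT = "WT"
S4KO = "S4KO"   # Smad4 KO: disables both Smad arms
EKO = "EKO"     # Eomes KO
TKO = "TKO"     # T (brachyury) KO
DKO = "dKO"     # Eomes/T double KO

#: which KO genotype anchors each TF's peak filtering and DE comparison
TF_KO_GENOTYPE = {"SMAD15": S4KO, "SMAD2": S4KO, "EOMES": EKO, "T": TKO}
PLURI_TFS = ("OCT4", "SOX2", "NANOG")


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults mirror the emulated study: two biological replicates, a
    day 0-3 time course with the WT-vs-KO comparison at day 2, planted
    fold-change effects of 2**2 = 4x, Poisson accessibility counts at a
    baseline depth of ~50 reads per region, and lognormal expression
    noise of 0.25 on the log2 scale.
    """

    seed: int = 0
    n_chroms: int = 6
    chrom_length: int = 2_600_000
    n_genes: int = 600
    peak_width: int = 400
    region_width: int = 600
    # distal co-occupancy loci (each also becomes an accessibility region)
    co_occupancy: dict = field(default_factory=lambda: {
        SMAD152: 40, SMAD15_SOLO: 30, SMAD2_SOLO: 30,
        OSN: 20, OSN_PARTIAL: 20, NONE: 20,
    })
    frac_smad4_dependent: float = 0.9   # fraction of a TF's peaks that vanish in its KO
    ko_leak_rate: float = 0.05          # P(a KO-dependent peak still appears in KO)
    n_direct_targets: dict = field(default_factory=lambda: {
        "SMAD15": 25, "SMAD2": 25, "EOMES": 20, "T": 20,
    })
    frac_activated: float = 0.7
    n_bound_not_de: int = 10            # per TF: bound genes without expression effect
    n_decoy_de: int = 12                # per comparison: DE genes provably unbound
    n_cooperative: int = 10             # T-bound genes DE only in the double KO
    n_extra_distal: int = 10            # per non-Smad TF: extra enhancer peaks
    n_ko_only: int = 3                  # per TF: peaks present only in the KO sample
    lfc_effect: float = 2.0
    lfc_noise_sd: float = 0.25
    fpkm_log2_mean: float = 3.32        # baseline FPKM median ~10
    fpkm_log2_sd: float = 1.0
    da_effect_lfc: float = 2.0
    da_depth: float = 50.0
    frac_regions_da: float = 0.6
    da_activated_frac: dict = field(default_factory=lambda: {
        SMAD15_SOLO: 0.9, SMAD152: 0.9, SMAD2_SOLO: 0.85,
        OSN: 0.2, OSN_PARTIAL: 0.25, NONE: 0.5,
    })
    n_replicates: int = 2
    timepoints: tuple = (0, 1, 2, 3)
    day: int = 2                        # comparison day
    timecourse_profile: tuple = (0.35, 0.7, 1.0, 0.6)  # opening shape, peaks at day 2
    emit_reads: bool = False
    read_length: int = 50
    reads_background: int = 200         # background reads per chromosome per sample

    def validate(self) -> None:
        for name in ("frac_smad4_dependent", "ko_leak_rate", "frac_activated",
                     "frac_regions_da"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name, v in self.da_activated_frac.items():
            if not 0 <= v <= 1:
                raise ValueError(f"da_activated_frac[{name}] must be in [0, 1]")
        if self.lfc_effect <= 0 or self.da_effect_lfc <= 0:
            raise ValueError("effect sizes must be > 0")
        if self.lfc_noise_sd < 0:
            raise ValueError("lfc_noise_sd must be >= 0")
        if min(self.n_genes, self.n_chroms, self.n_replicates) <= 0:
            raise ValueError("counts must be positive")
        if len(self.timecourse_profile) != len(self.timepoints):
            raise ValueError("timecourse_profile must match timepoints")


@dataclass
class TruthTables:
    """Planted ground truth; consumed only by tests and recovery metrics."""

    direct_targets: dict          # tf -> {gene: direction}
    discarded_peaks: dict         # tf -> sorted list of WT peak names that KO filtering must remove
    overlap_pairs: list           # [smad15 peak name, smad2 peak name] co-placed pairs
    region_groups: dict           # region_id -> occupancy group (all regions)
    da_regions: dict              # region_id -> {"direction": ...} (planted DA only)
    cluster_genes: list           # planted union for expression clustering
    decoy_de: dict                # genotype -> {gene: direction}

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path) -> "TruthTables":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SimResult:
    outdir: Path
    paths: dict
    truth: TruthTables
    config: SimConfig


def _place_genes(cfg: SimConfig, rng) -> pd.DataFrame:
    """Evenly spaced TSSs with jitter; separation >> promoter width."""
    rows = []
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1
    idx = 1
    for c in range(cfg.n_chroms):
        n = per_chrom[c]
        chrom = f"chr{c + 1}"
        spacing = cfg.chrom_length // (n + 1)
        for g in range(n):
            jitter = int(rng.integers(-spacing // 8, spacing // 8 + 1))
            tss = (g + 1) * spacing + jitter
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append({"gene_id": f"g{idx:04d}", "chrom": chrom,
                         "strand": strand, "tss": tss})
            idx += 1
    return pd.DataFrame(rows)


def _make_peak(tf, chrom, summit, width, q, name, chrom_len) -> Peak:
    start = max(0, summit - width // 2)
    end = min(chrom_len, start + width)
    if summit >= end:
        end = summit + 1
    return Peak(chrom, start, end, summit, score=10.0, qvalue=q, name=name)


def simulate(config: SimConfig, outdir) -> SimResult:
    """Emit the full synthetic dataset plus truth tables to ``outdir``.

    Identical config (including seed) produces byte-identical files.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    chrom_sizes = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)}
    paths["chrom_sizes"] = outdir / "chrom.sizes"
    core.write_chrom_sizes(chrom_sizes, paths["chrom_sizes"])

    gene_df = _place_genes(cfg, rng)
    ann = GeneAnnotation(gene_df, chrom_sizes)
    paths["annotation"] = outdir / "annotation.tsv"
    core.write_annotation(ann, paths["annotation"])

    # gene order per chromosome, for "right neighbour" lookups
    ordered = ann.table.sort_values(["chrom", "tss"])
    next_gene = {}
    for _, sub in ordered.groupby("chrom"):
        gids = sub["gene_id"].tolist()
        for a, b in zip(gids, gids[1:]):
            next_gene[a] = b
    tss_of = dict(zip(ann.table["gene_id"], ann.table["tss"]))
    chrom_of = dict(zip(ann.table["gene_id"], ann.table["chrom"]))

    # ----- choose effect genes (targets, silent-bound, cooperative) -------
    pool = list(rng.permutation(np.asarray(ann.gene_ids, dtype=object)))

    def take(n):
        if len(pool) < n:
            raise ValueError("gene pool exhausted; increase n_genes")
        out = [pool.pop() for _ in range(n)]
        return out

    targets, bound_not_de = {}, {}
    for tf in TF_KO_GENOTYPE:
        genes = take(cfg.n_direct_targets[tf])
        n_act = int(round(cfg.frac_activated * len(genes)))
        targets[tf] = {
            g: (ACTIVATED if i < n_act else REPRESSED) for i, g in enumerate(genes)
        }
        bound_not_de[tf] = take(cfg.n_bound_not_de)
    cooperative = take(cfg.n_cooperative)
    effect_genes = set(cooperative)
    for tf in targets:
        effect_genes |= set(targets[tf])

    # ----- distal locus anchors -------------------------------------------
    # a locus at tss + ~13 kb binds exactly {anchor, next gene} under the
    # both-neighbours rule, so anchors avoid effect genes on both sides
    eligible = [
        g for g in pool
        if g in next_gene and g not in effect_genes and next_gene[g] not in effect_genes
    ]
    eligible = list(rng.permutation(np.asarray(eligible, dtype=object)))

    def take_anchor():
        if not eligible:
            raise ValueError("anchor pool exhausted; increase n_genes or shrink peak counts")
        return eligible.pop()

    def new_locus():
        g = take_anchor()
        offset = int(rng.integers(11_000, 15_001))
        return chrom_of[g], tss_of[g] + offset

    # ----- peaks -----------------------------------------------------------
    counters = {}

    def name_for(tf):
        counters[tf] = counters.get(tf, 0) + 1
        return f"{tf}_{counters[tf]:05d}"

    def wt_q():
        return 10.0 ** -float(rng.uniform(8, 12))

    def ko_q():
        return 10.0 ** -float(rng.uniform(2.2, 4))

    wt_peaks = {tf: [] for tf in TF_KO_GENOTYPE}
    ko_peaks = {tf: [] for tf in TF_KO_GENOTYPE}
    pluri_peaks = {tf: [] for tf in PLURI_TFS}
    dependent = {tf: [] for tf in TF_KO_GENOTYPE}   # peaks absent from KO (modulo leak)
    overlap_pairs = []
    regions = []
    region_groups = {}
    region_counter = 0

    def add_dependent(tf, chrom, summit):
        p = _make_peak(tf, chrom, summit, cfg.peak_width, wt_q(), name_for(tf),
                       cfg.chrom_length)
        wt_peaks[tf].append(p)
        dependent[tf].append(p)
        return p

    def add_region(chrom, pos, group):
        nonlocal region_counter
        region_counter += 1
        rid = f"r{region_counter:04d}"
        half = cfg.region_width // 2
        regions.append(Region(chrom, pos - half, pos + half, rid))
        region_groups[rid] = group

    # co-occupancy loci: each becomes an accessibility region
    for group in (SMAD152, SMAD15_SOLO, SMAD2_SOLO, OSN, OSN_PARTIAL, NONE):
        for _ in range(cfg.co_occupancy.get(group, 0)):
            chrom, pos = new_locus()
            add_region(chrom, pos, group)
            if group == SMAD152:
                p15 = add_dependent("SMAD15", chrom, pos)
                delta = int(rng.integers(-280, 281))
                p2 = add_dependent("SMAD2", chrom, pos + delta)
                overlap_pairs.append([p15.name, p2.name])
            elif group == SMAD15_SOLO:
                add_dependent("SMAD15", chrom, pos)
            elif group == SMAD2_SOLO:
                add_dependent("SMAD2", chrom, pos)
            elif group == OSN:
                for i, f in enumerate(PLURI_TFS):
                    summit = pos + (i - 1) * 80
                    pluri_peaks[f].append(
                        _make_peak(f, chrom, summit, cfg.peak_width, wt_q(),
                                   name_for(f), cfg.chrom_length))
            elif group == OSN_PARTIAL:
                k = 1 + int(rng.integers(0, 2))
                chosen = list(rng.choice(np.asarray(PLURI_TFS, dtype=object), size=k,
                                         replace=False))
                for i, f in enumerate(chosen):
                    pluri_peaks[f].append(
                        _make_peak(f, chrom, pos + i * 80, cfg.peak_width, wt_q(),
                                   name_for(f), cfg.chrom_length))

    # promoter peaks at target and silent-bound genes
    for tf in TF_KO_GENOTYPE:
        for g in list(targets[tf]) + bound_not_de[tf]:
            summit = tss_of[g] + int(rng.integers(-1500, 1501))
            add_dependent(tf, chrom_of[g], max(0, summit))
    for g in cooperative:                       # T-bound, DE only in the double KO
        summit = tss_of[g] + int(rng.integers(-1500, 1501))
        add_dependent("T", chrom_of[g], max(0, summit))
    for tf in ("EOMES", "T"):                   # extra distal enhancer peaks
        for _ in range(cfg.n_extra_distal):
            chrom, pos = new_locus()
            add_dependent(tf, chrom, pos)

    # false positives: present in WT and (shifted) in the KO sample
    discarded_truth = {tf: [] for tf in TF_KO_GENOTYPE}
    f = cfg.frac_smad4_dependent
    for tf in TF_KO_GENOTYPE:
        n_fp = 0 if f >= 1 else int(round(len(dependent[tf]) * (1 - f) / f))
        for _ in range(n_fp):
            chrom, pos = new_locus()
            p = _make_peak(tf, chrom, pos, cfg.peak_width, wt_q(), name_for(tf),
                           cfg.chrom_length)
            wt_peaks[tf].append(p)
            shift = int(rng.integers(-100, 101))
            ko_peaks[tf].append(
                _make_peak(tf, chrom, pos + shift, cfg.peak_width, ko_q(),
                           name_for(tf) + "ko", cfg.chrom_length))
            discarded_truth[tf].append(p.name)
        # leak: a KO-dependent peak that nonetheless appears in the KO sample
        for p in dependent[tf]:
            if rng.random() < cfg.ko_leak_rate:
                ko_peaks[tf].append(
                    _make_peak(tf, p.chrom, p.summit + int(rng.integers(-100, 101)),
                               cfg.peak_width, ko_q(), p.name + "leak",
                               cfg.chrom_length))
                discarded_truth[tf].append(p.name)
        for _ in range(cfg.n_ko_only):          # KO-sample noise at fresh loci
            chrom, pos = new_locus()
            ko_peaks[tf].append(
                _make_peak(tf, chrom, pos, cfg.peak_width, ko_q(), name_for(tf) + "ko",
                           cfg.chrom_length))

    for tf in TF_KO_GENOTYPE:
        ps = PeakSet(f"{tf}.WT", wt_peaks[tf])
        paths[f"peaks_{tf}_WT"] = outdir / f"peaks_{tf}_WT.narrowPeak"
        core.write_narrowpeak(ps, paths[f"peaks_{tf}_WT"])
        ko_geno = TF_KO_GENOTYPE[tf]
        kps = PeakSet(f"{tf}.{ko_geno}", ko_peaks[tf])
        paths[f"peaks_{tf}_KO"] = outdir / f"peaks_{tf}_{ko_geno}.narrowPeak"
        core.write_narrowpeak(kps, paths[f"peaks_{tf}_KO"])
    for tf in PLURI_TFS:
        ps = PeakSet(f"{tf}.ESC", pluri_peaks[tf])
        paths[f"peaks_{tf}_ESC"] = outdir / f"peaks_{tf}_ESC.narrowPeak"
        core.write_narrowpeak(ps, paths[f"peaks_{tf}_ESC"])

    # ----- decoy DE genes: provably unbound under the assignment rule ------
    bound_by_tf = {
        tf: assign_peaks_to_genes(PeakSet(tf, dependent[tf]), ann).bound_genes
        for tf in TF_KO_GENOTYPE
    }
    all_bound = set().union(*bound_by_tf.values())
    neutral = [g for g in pool if g not in all_bound]
    neutral = list(rng.permutation(np.asarray(neutral, dtype=object)))
    decoy_de = {}
    for geno in (S4KO, EKO, TKO, DKO):
        chosen = [neutral.pop() for _ in range(min(cfg.n_decoy_de, len(neutral)))]
        decoy_de[geno] = {
            g: (ACTIVATED if rng.random() < cfg.frac_activated else REPRESSED)
            for g in chosen
        }

    # ----- expression -------------------------------------------------------
    genes = ann.gene_ids
    base = 2.0 ** rng.normal(cfg.fpkm_log2_mean, cfg.fpkm_log2_sd, size=len(genes))
    base = pd.Series(base, index=genes)
    # planted effects: (gene, genotype) -> direction
    effects: dict = {}
    for tf, tf_targets in targets.items():
        for g, direction in tf_targets.items():
            effects[(g, TF_KO_GENOTYPE[tf])] = direction
            if tf in ("EOMES", "T"):            # single-KO effects persist in the dKO
                effects[(g, DKO)] = direction
    for g in cooperative:
        effects[(g, DKO)] = ACTIVATED
    for geno, decoys in decoy_de.items():
        for g, direction in decoys.items():
            effects[(g, geno)] = direction
    effect_gene_ids = {g for g, _ in effects}
    base.loc[base.index.isin(effect_gene_ids) & (base < 2.0)] = 2.0

    amp = 2.0 ** cfg.lfc_effect
    wt_mult = pd.Series(1.0, index=genes)
    for (g, _), direction in effects.items():
        if direction == ACTIVATED:
            wt_mult[g] = amp
    cols = {}
    for geno in (WT, S4KO, EKO, TKO, DKO):
        mult = wt_mult.copy()
        if geno != WT:
            for (g, gg), direction in effects.items():
                if gg != geno:
                    continue
                mult[g] = 1.0 if direction == ACTIVATED else amp
        mean = base * mult
        for r in range(1, cfg.n_replicates + 1):
            noise = 2.0 ** rng.normal(0.0, cfg.lfc_noise_sd, size=len(genes))
            cols[f"{geno}.d{cfg.day}.r{r}"] = (mean * noise).to_numpy()
    expr = ExpressionMatrix(pd.DataFrame(cols, index=pd.Index(genes, name="gene_id")))
    paths["expression"] = outdir / "expression.tsv"
    core.write_expression(expr, paths["expression"])

    # ----- accessibility counts --------------------------------------------
    regions = sorted(regions, key=lambda r: (r.chrom, r.start))
    rates = np.clip(rng.gamma(25.0, cfg.da_depth / 25.0, size=len(regions)), 15.0, None)
    base_rate = pd.Series(rates, index=[r.region_id for r in regions])
    da_truth = {}
    for group in (SMAD152, SMAD15_SOLO, SMAD2_SOLO, OSN, OSN_PARTIAL, NONE):
        members = [rid for rid, g in region_groups.items() if g == group]
        members.sort()
        n_da = int(round(cfg.frac_regions_da * len(members)))
        if n_da == 0:
            continue
        chosen = list(rng.choice(np.asarray(members, dtype=object), size=n_da,
                                 replace=False))
        p_act = cfg.da_activated_frac.get(group, 0.5)
        for rid in chosen:
            da_truth[rid] = {
                "direction": ACTIVATED if rng.random() < p_act else REPRESSED
            }

    da_amp = 2.0 ** cfg.da_effect_lfc
    profile = dict(zip(cfg.timepoints, cfg.timecourse_profile))

    def wt_rate(rid, t):
        b = base_rate[rid]
        if rid in da_truth and da_truth[rid]["direction"] == ACTIVATED:
            return b * da_amp ** profile[t]
        return b

    def ko_rate(rid):
        b = base_rate[rid]
        if rid in da_truth and da_truth[rid]["direction"] == REPRESSED:
            return b * da_amp
        return b

    count_cols = {}
    for t in cfg.timepoints:
        for r in range(1, cfg.n_replicates + 1):
            lam = np.array([wt_rate(rr.region_id, t) for rr in regions])
            count_cols[f"{WT}.d{t}.r{r}"] = rng.poisson(lam)
    for r in range(1, cfg.n_replicates + 1):
        lam = np.array([ko_rate(rr.region_id) for rr in regions])
        count_cols[f"{S4KO}.d{cfg.day}.r{r}"] = rng.poisson(lam)
    counts_df = pd.DataFrame(
        count_cols, index=pd.Index([r.region_id for r in regions], name="region_id")
    )
    lib = pd.Series(1e6, index=counts_df.columns)
    rcm = RegionCountMatrix(regions, counts_df, lib)
    paths["regions"] = outdir / "regions.bed"
    paths["region_counts"] = outdir / "region_counts.tsv"
    core.write_region_counts(rcm, paths["regions"], paths["region_counts"])

    # ----- optional read intervals for density quantification ---------------
    if cfg.emit_reads:
        lib_sizes = {}
        for t in cfg.timepoints:
            sample = f"{WT}.d{t}"
            by_chrom: dict = {}
            total = 0
            for rr in regions:
                n = int(rng.poisson(wt_rate(rr.region_id, t)))
                if n:
                    starts = rng.integers(rr.start, max(rr.start + 1,
                                                        rr.end - cfg.read_length), size=n)
                    lst = by_chrom.setdefault(rr.chrom, [])
                    lst.extend((int(s), int(s) + cfg.read_length) for s in starts)
                    total += n
            for chrom in chrom_sizes:
                n = cfg.reads_background
                starts = rng.integers(0, cfg.chrom_length - cfg.read_length, size=n)
                lst = by_chrom.setdefault(chrom, [])
                lst.extend((int(s), int(s) + cfg.read_length) for s in starts)
                total += n
            arrs = {
                c: (np.array([s for s, _ in sorted(v)]), np.array(sorted(e for _, e in v)))
                for c, v in by_chrom.items()
            }
            paths[f"reads_{sample}"] = outdir / f"reads_{sample}.bed"
            core.write_reads_bed(arrs, paths[f"reads_{sample}"])
            lib_sizes[sample] = total
        paths["read_library_sizes"] = outdir / "read_library_sizes.json"
        Path(paths["read_library_sizes"]).write_text(
            json.dumps(lib_sizes, sort_keys=True) + "\n")

    # ----- truth ------------------------------------------------------------
    cluster_genes = sorted(set(targets["T"]) | set(cooperative))
    truth = TruthTables(
        direct_targets={tf: dict(sorted(targets[tf].items())) for tf in targets},
        discarded_peaks={tf: sorted(v) for tf, v in discarded_truth.items()},
        overlap_pairs=sorted(overlap_pairs),
        region_groups=dict(sorted(region_groups.items())),
        da_regions=dict(sorted(da_truth.items())),
        cluster_genes=cluster_genes,
        decoy_de={g: dict(sorted(v.items())) for g, v in decoy_de.items()},
    )
    paths["truth"] = outdir / "truth.json"
    truth.save(paths["truth"])
    return SimResult(outdir=outdir, paths=paths, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# Fixed worked example: a hand-enumerable 20-gene, 3-TF micro-dataset
# ---------------------------------------------------------------------------

def emit_worked_example(outdir) -> dict:
    """Write a fixed 20-gene, 3-TF micro-dataset with hand-checked outputs.

    One chromosome; 20 genes at TSS = 20 kb + 40 kb * i; SMAD15, SMAD2 and
    T peak sets with one planted false positive each (reappearing in the
    matching KO sample); exact (noise-free) expression encoding both the DE
    comparisons and seven duplicated clustering archetypes; four
    accessibility regions of which three are differentially accessible.
    The expected outputs stored in ``expected.json`` were enumerated by
    hand from these coordinates and values.  Rerunning produces identical
    bytes.  Returns the path dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    chrom_sizes = {"chr1": 1_000_000}
    paths["chrom_sizes"] = outdir / "chrom.sizes"
    core.write_chrom_sizes(chrom_sizes, paths["chrom_sizes"])

    tss = {f"g{i:02d}": 20_000 + 40_000 * (i - 1) for i in range(1, 21)}
    ann_df = pd.DataFrame(
        [{"gene_id": g, "chrom": "chr1", "strand": "+" if i % 2 else "-", "tss": t}
         for i, (g, t) in enumerate(tss.items())]
    )
    ann = GeneAnnotation(ann_df, chrom_sizes)
    paths["annotation"] = outdir / "annotation.tsv"
    core.write_annotation(ann, paths["annotation"])

    def pk(tf, summit, i, q):
        return Peak("chr1", summit - 200, summit + 200, summit, score=10.0,
                    qvalue=q, name=f"{tf}_{i:02d}")

    qw, qk = 1e-8, 5e-3
    wt_sets = {
        # promoters of g01..g05, one distal locus, one false positive at g13's TSS
        "SMAD15": [pk("SMAD15", s, i + 1, qw) for i, s in enumerate(
            [20_000, 60_000, 100_000, 140_000, 180_000, 50_000, 500_000])],
        # promoters of g03..g07, a co-placed distal locus, a solo distal locus,
        # and a false positive
        "SMAD2": [pk("SMAD2", s, i + 1, qw) for i, s in enumerate(
            [100_000, 140_000, 180_000, 220_000, 260_000, 50_150, 315_000, 600_000])],
        # promoters of g08..g12 and a false positive at g18's TSS
        "T": [pk("T", s, i + 1, qw) for i, s in enumerate(
            [300_000, 340_000, 380_000, 420_000, 460_000, 700_000])],
    }
    ko_sets = {
        "SMAD15": ("S4KO", [pk("SMAD15ko", 500_050, 1, qk)]),
        "SMAD2": ("S4KO", [pk("SMAD2ko", 600_100, 1, qk)]),
        "T": ("TKO", [pk("Tko", 700_080, 1, qk)]),
    }
    for tf, peaks_list in wt_sets.items():
        paths[f"peaks_{tf}_WT"] = outdir / f"peaks_{tf}_WT.narrowPeak"
        core.write_narrowpeak(PeakSet(f"{tf}.WT", peaks_list), paths[f"peaks_{tf}_WT"])
        geno, kolist = ko_sets[tf]
        paths[f"peaks_{tf}_KO"] = outdir / f"peaks_{tf}_{geno}.narrowPeak"
        core.write_narrowpeak(PeakSet(f"{tf}.{geno}", kolist), paths[f"peaks_{tf}_KO"])

    # expression over (WT, S4KO, EKO, TKO, dKO), day 2, 2 exact replicates.
    # g01..g14 follow seven duplicated archetypes over (WT, EKO, TKO, dKO);
    # the S4KO column encodes the Smad DE plan; g13 and g18 are DE decoys
    # whose binding is removed by KO filtering (or absent entirely).
    prof = {  # gene -> (WT, S4KO, EKO, TKO, dKO)
        "g01": (40, 10, 10, 10, 10), "g02": (40, 10, 10, 10, 10),
        "g03": (40, 160, 10, 40, 10), "g04": (40, 40, 10, 40, 10),
        "g05": (40, 40, 40, 10, 10), "g06": (40, 40, 40, 10, 10),
        "g07": (40, 40, 40, 40, 10), "g08": (40, 40, 40, 40, 10),
        "g09": (10, 10, 40, 40, 40), "g10": (10, 10, 40, 40, 40),
        "g11": (10, 10, 10, 10, 40), "g12": (10, 10, 10, 10, 40),
        "g13": (10, 2.4, 40, 10, 40), "g14": (10, 10, 40, 10, 40),
    }
    for i in range(15, 21):
        g = f"g{i:02d}"
        prof[g] = (10, 10, 10, 10, 10)
    prof["g18"] = (10, 10, 10, 2.4, 10)
    genos = (WT, S4KO, EKO, TKO, DKO)
    cols = {}
    for j, geno in enumerate(genos):
        for r in (1, 2):
            cols[f"{geno}.d2.r{r}"] = [float(prof[g][j]) for g in sorted(prof)]
    expr = ExpressionMatrix(
        pd.DataFrame(cols, index=pd.Index(sorted(prof), name="gene_id")))
    paths["expression"] = outdir / "expression.tsv"
    core.write_expression(expr, paths["expression"])

    # accessibility: four regions; r03 deliberately falls short of the DA rule
    regions = [
        Region("chr1", 19_700, 20_300, "r01"),    # SMAD15 summit only
        Region("chr1", 99_700, 100_300, "r02"),   # SMAD15 + SMAD2 summits
        Region("chr1", 219_700, 220_300, "r03"),  # SMAD2 summit only, not DA
        Region("chr1", 799_700, 800_300, "r04"),  # no summits
    ]
    counts = pd.DataFrame(
        {
            "WT.d2.r1": [400, 800, 100, 50],
            "WT.d2.r2": [440, 820, 104, 54],
            "S4KO.d2.r1": [95, 190, 98, 210],
            "S4KO.d2.r2": [105, 210, 102, 190],
        },
        index=pd.Index([r.region_id for r in regions], name="region_id"),
    )
    rcm = RegionCountMatrix(regions, counts, pd.Series(1e6, index=counts.columns))
    paths["regions"] = outdir / "regions.bed"
    paths["region_counts"] = outdir / "region_counts.tsv"
    core.write_region_counts(rcm, paths["regions"], paths["region_counts"])

    cluster_genes = [f"g{i:02d}" for i in range(1, 15)]
    paths["cluster_genes"] = outdir / "cluster_genes.txt"
    Path(paths["cluster_genes"]).write_text("\n".join(cluster_genes) + "\n")

    pipeline_config = {
        "seed": 0,
        "day": 2,
        "output_dir": "out",
        "chrom_sizes": "chrom.sizes",
        "annotation": "annotation.tsv",
        "expression": "expression.tsv",
        "parameters": {
            "w_prom": 2000, "d_ov": 300, "d_distal": 10000,
            "fpkm_min": 1.0, "lfc_min": 1.0, "pseudocount": 0.1,
            "da_lfc_min": 1.0, "da_min_mean": 10.0, "da_pseudocount": 0.5,
            "k": 7, "n_restarts": 25,
        },
        "qvalues": {"SMAD15": 5e-4, "SMAD2": 1e-7, "T": 1e-4},
        "ko_qvalue": 1e-2,
        "tfs": {
            "SMAD15": {"wt": "peaks_SMAD15_WT.narrowPeak",
                       "ko": "peaks_SMAD15_S4KO.narrowPeak", "ko_condition": "S4KO"},
            "SMAD2": {"wt": "peaks_SMAD2_WT.narrowPeak",
                      "ko": "peaks_SMAD2_S4KO.narrowPeak", "ko_condition": "S4KO"},
            "T": {"wt": "peaks_T_WT.narrowPeak",
                  "ko": "peaks_T_TKO.narrowPeak", "ko_condition": "TKO"},
        },
        "overlaps": [["SMAD15", "SMAD2"]],
        "accessibility": {
            "regions": "regions.bed", "counts": "region_counts.tsv",
            "wt": "WT", "ko": "S4KO",
            "chip": {"smad15": "SMAD15", "smad2": "SMAD2"}, "pluri": {},
        },
        "clustering": {
            "genes": "cluster_genes.txt",
            "genotypes": ["WT", "EKO", "TKO", "dKO"],
        },
    }
    import yaml

    paths["config"] = outdir / "config.yaml"
    Path(paths["config"]).write_text(
        yaml.safe_dump(pipeline_config, sort_keys=True))

    # hand-enumerated expectations for the coordinates and values above
    expected = {
        "peaks": {
            "SMAD15": {"retained": 6, "discarded": 1},
            "SMAD2": {"retained": 7, "discarded": 1},
            "T": {"retained": 5, "discarded": 1},
        },
        "venn": {
            "SMAD15|SMAD2": {"a_only": 2, "both_a": 4, "both_b": 4, "b_only": 3},
        },
        "direct_targets": {
            "SMAD15": {"activated": ["g01", "g02"], "repressed": ["g03"]},
            "SMAD2": {"activated": ["g01", "g02"], "repressed": ["g03"]},
            "T": {"activated": [], "repressed": ["g09", "g10"]},
        },
        "bound_genes": {
            "SMAD15": ["g01", "g02", "g03", "g04", "g05"],
            "SMAD2": ["g01", "g02", "g03", "g04", "g05", "g06", "g07", "g08", "g09"],
            "T": ["g08", "g09", "g10", "g11", "g12"],
        },
        "da_regions": {
            "r01": {"direction": "activated", "occupancy": "SMAD15_SOLO"},
            "r02": {"direction": "activated", "occupancy": "SMAD152"},
            "r04": {"direction": "repressed", "occupancy": "NONE"},
        },
        "cluster_sizes": [2, 2, 2, 2, 2, 2, 2],
    }
    paths["expected"] = outdir / "expected.json"
    Path(paths["expected"]).write_text(json.dumps(expected, indent=1, sort_keys=True) + "\n")
    return paths


# ---------------------------------------------------------------------------
# Planted expression archetypes for clustering tests
# ---------------------------------------------------------------------------

#: Seven response archetypes over (WT, Eomes-KO, T-KO, double-KO): 1 = high.
ARCHETYPE_SHAPES = (
    (1, 0, 0, 0),   # requires both factors: down in every KO
    (1, 0, 1, 0),   # Eomes-dependent only
    (1, 1, 0, 0),   # T-dependent only
    (1, 1, 1, 0),   # redundant: only the double KO loses expression
    (0, 1, 1, 1),   # repressed by both factors
    (0, 0, 0, 1),   # repressed, double KO only
    (0, 1, 0, 1),   # repressed, Eomes-dependent
)


def simulate_archetype_expression(
    n_per_cluster: int = 30,
    separation: float = 4.0,
    noise_sd: float = 1.0,
    n_replicates: int = 2,
    seed: int = 0,
    genotypes=(WT, EKO, TKO, DKO),
    day: int = 3,
):
    """Expression matrix with seven planted profile archetypes.

    Per-gene log2 profiles are ``base + separation * noise_sd * zshape +
    N(0, noise_sd)`` per genotype, where ``zshape`` is the archetype's
    standardized (zero-mean, unit-variance) profile; archetype amplitudes
    are thus ``separation`` standard deviations of the within-cluster
    noise.  Returns ``(ExpressionMatrix, truth_labels)`` with labels 1..7.
    """
    rng = np.random.default_rng(seed)
    amp = separation * noise_sd
    rows, labels, gene_ids = [], [], []
    for k, shape in enumerate(ARCHETYPE_SHAPES, start=1):
        s = np.asarray(shape, dtype=float)
        zshape = (s - s.mean()) / s.std()
        for i in range(n_per_cluster):
            g = f"a{k}_{i:03d}"
            gene_ids.append(g)
            labels.append(k)
            b = rng.normal(3.0, 0.5)
            prof = b + amp * zshape + rng.normal(0.0, noise_sd, size=len(genotypes))
            rows.append(prof)
    prof_mat = np.vstack(rows)
    cols = {}
    for j, geno in enumerate(genotypes):
        for r in range(1, n_replicates + 1):
            rep_noise = rng.normal(0.0, 0.1, size=len(gene_ids))
            cols[f"{geno}.d{day}.r{r}"] = 2.0 ** (prof_mat[:, j] + rep_noise)
    expr = ExpressionMatrix(
        pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id")))
    truth = pd.Series(labels, index=pd.Index(gene_ids, name="gene_id"), name="archetype")
    return expr, truth
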