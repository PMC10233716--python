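"""End-to-end pipeline: peaks -> targets -> accessibility -> clustering.

A single YAML config declares every input path and threshold; the run
emits per-stage TSV/JSON outputs plus a machine-readable report whose
counts are internally consistent and whose serialized form is
byte-stable across reruns (same config + inputs -> identical report).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import core
from .accessibility import (
    activated_fraction_by_group,
    call_da_regions,
    classify_da_occupancy,
    tss_distance_classes,
)
from .clustering import cluster_targets
from .peaks import (
    KO_QVALUE,
    apply_qvalue_cutoff,
    filter_ko_false_positives,
    overlap_peaksets,
    promoter_distance_histogram,
)
from .targets import (
    assign_peaks_to_genes,
    build_cluster_gene_set,
    call_de_genes,
    call_direct_targets,
    target_set_algebra,
)

log = logging.getLogger("circuitcall")

DEFAULT_PARAMETERS = {
    "w_prom": 2000,
    "d_ov": 300,
    "d_distal": 10000,
    "fpkm_min": 1.0,
    "lfc_min": 1.0,
    "pseudocount": 0.1,
    "da_lfc_min": 1.0,
    "da_min_mean": 10.0,
    "da_pseudocount": 0.5,
    "k": 7,
    "n_restarts": 25,
}


@dataclass
class PipelineConfig:
    base_dir: Path
    raw: dict
    parameters: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        params = dict(DEFAULT_PARAMETERS)
        params.update(raw.get("parameters", {}))
        return cls(base_dir=path.parent, raw=raw, parameters=params)

    def path(self, rel) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else self.base_dir / p

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    @property
    def day(self):
        return self.raw.get("day")


def validate_config(path) -> list:
    """Exhaustive validation without executing; returns a list of errors."""
    errors = []
    try:
        cfg = PipelineConfig.from_yaml(path)
    except Exception as exc:  # unparseable file is a single fatal error
        return [f"cannot parse config: {exc}"]
    raw = cfg.raw
    for key in ("annotation", "expression"):
        if key not in raw:
            errors.append(f"missing required key {key!r}")
        elif not cfg.path(raw[key]).exists():
            errors.append(f"{key}: file not found: {cfg.path(raw[key])}")
    if "chrom_sizes" in raw and not cfg.path(raw["chrom_sizes"]).exists():
        errors.append(f"chrom_sizes: file not found: {cfg.path(raw['chrom_sizes'])}")
    p = cfg.parameters
    if p.get("d_ov", 0) < 0:
        errors.append("D_ov must be >= 0")
    if p.get("w_prom", 0) < 0:
        errors.append("w_prom must be >= 0")
    for name in ("fpkm_min", "lfc_min", "da_lfc_min", "da_min_mean"):
        if p.get(name, 0) < 0:
            errors.append(f"{name} must be >= 0")
    if p.get("k", 1) < 1:
        errors.append("k must be >= 1")
    tfs = raw.get("tfs", {})
    for tf, spec in tfs.items():
        for role in ("wt", "ko"):
            if role not in spec:
                errors.append(f"tfs.{tf}: missing {role!r} peak file")
            elif not cfg.path(spec[role]).exists():
                errors.append(f"tfs.{tf}.{role}: file not found: {cfg.path(spec[role])}")
        if "ko_condition" not in spec:
            errors.append(f"tfs.{tf}: missing ko_condition")
    for tf in raw.get("qvalues", {}):
        if tf not in tfs:
            errors.append(f"qvalues: unknown TF key {tf!r}")
    for pair in raw.get("overlaps", []):
        for tf in pair:
            if tf not in tfs:
                errors.append(f"overlaps: unknown TF {tf!r}")
    acc = raw.get("accessibility")
    if acc:
        for key in ("regions", "counts"):
            if key not in acc:
                errors.append(f"accessibility: missing {key!r}")
            elif not cfg.path(acc[key]).exists():
                errors.append(f"accessibility.{key}: file not found: {cfg.path(acc[key])}")
        for label, ref in {**acc.get("chip", {}), **acc.get("pluri", {})}.items():
            if ref not in tfs and not cfg.path(ref).exists():
                errors.append(
                    f"accessibility: {label!r} is neither a configured TF nor a file: {ref}"
                )
    clu = raw.get("clustering")
    if clu and "genes" in clu and isinstance(clu["genes"], str):
        if not cfg.path(clu["genes"]).exists():
            errors.append(f"clustering.genes: file not found: {cfg.path(clu['genes'])}")
    return errors


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage, message):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages in order; returns the run report.

    Stage order: peak filtering -> overlaps -> target inference ->
    accessibility -> clustering.  Every stage's outputs are written before
    the next stage reads its own inputs; any failure aborts with the stage
    name and the offending input.
    """
    raw = config.raw
    params = config.parameters
    outdir = config.path(raw.get("output_dir", "out"))
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": dict(sorted(params.items())), "seed": config.seed,
                    "input_hashes": {}, "stages": {}}

    def hash_input(key, path):
        report["input_hashes"][key] = _sha256(path)

    # ---- stage: inputs -----------------------------------------------------
    stage = "inputs"
    try:
        chrom_sizes = None
        if "chrom_sizes" in raw:
            chrom_sizes = core.read_chrom_sizes(config.path(raw["chrom_sizes"]))
            hash_input("chrom_sizes", config.path(raw["chrom_sizes"]))
        ann = core.read_annotation(config.path(raw["annotation"]), chrom_sizes)
        hash_input("annotation", config.path(raw["annotation"]))
        expr = core.read_expression(config.path(raw["expression"]))
        hash_input("expression", config.path(raw["expression"]))
    except FileNotFoundError as exc:
        raise StageError(stage, f"missing input: {exc.filename}") from exc
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    qtable = raw.get("qvalues", {})
    ko_q = float(raw.get("ko_qvalue", KO_QVALUE))
    day = config.day

    # ---- stage: peaks ------------------------------------------------------
    stage = "peaks"
    retained: dict = {}
    report["stages"]["peaks"] = {}
    for tf, spec in sorted(raw.get("tfs", {}).items()):
        try:
            wt = core.read_narrowpeak(config.path(spec["wt"]), f"{tf}.WT", chrom_sizes)
            hash_input(f"peaks.{tf}.wt", config.path(spec["wt"]))
            ko = core.read_narrowpeak(config.path(spec["ko"]), f"{tf}.KO", chrom_sizes)
            hash_input(f"peaks.{tf}.ko", config.path(spec["ko"]))
        except FileNotFoundError as exc:
            raise StageError(stage, f"missing input: {exc.filename}") from exc
        except core.FormatError as exc:
            raise StageError(stage, str(exc)) from exc
        if tf in qtable:
            wt = apply_qvalue_cutoff(wt, tf, {tf: float(qtable[tf])})
        ko = apply_qvalue_cutoff(ko, tf, {tf: ko_q})
        kept, dropped = filter_ko_false_positives(wt, ko, d=params["d_ov"])
        retained[tf] = kept
        hist = promoter_distance_histogram(kept, ann, w_prom=params["w_prom"],
                                           d_distal=params["d_distal"])
        report["stages"]["peaks"][tf] = {
            "n_wt": len(wt), "retained": len(kept), "discarded": len(dropped),
            "frac_promoter_far": hist.frac_promoter_far,
            "frac_distal": hist.frac_distal,
        }
        core.write_narrowpeak(kept, outdir / f"retained_{tf}.narrowPeak")
        core.write_narrowpeak(dropped, outdir / f"discarded_{tf}.narrowPeak")
        log.info("peaks[%s]: %d retained, %d discarded", tf, len(kept), len(dropped))

    # ---- stage: overlaps ---------------------------------------------------
    stage = "overlaps"
    report["stages"]["overlaps"] = {}
    for pair in raw.get("overlaps", []):
        a, b = pair
        if a not in retained or b not in retained:
            raise StageError(stage, f"overlap pair ({a}, {b}) not among configured TFs")
        venn = overlap_peaksets(retained[a], retained[b], d=params["d_ov"])
        report["stages"]["overlaps"][f"{a}|{b}"] = venn.as_dict()

    # ---- stage: targets ----------------------------------------------------
    stage = "targets"
    report["stages"]["targets"] = {}
    target_sets = {}
    for tf, spec in sorted(raw.get("tfs", {}).items()):
        try:
            de = call_de_genes(expr, wt="WT", ko=spec["ko_condition"], day=day,
                               fpkm_min=params["fpkm_min"], lfc_min=params["lfc_min"],
                               pseudocount=params["pseudocount"])
        except ValueError as exc:
            raise StageError(stage, f"{tf}: {exc}") from exc
        assignment = assign_peaks_to_genes(retained[tf], ann, w=params["w_prom"])
        targets = call_direct_targets(assignment.bound_genes, de, tf, day=day)
        target_sets[tf] = targets
        rows = [{"gene_id": g, "direction": "activated"} for g in sorted(targets.activated)]
        rows += [{"gene_id": g, "direction": "repressed"} for g in sorted(targets.repressed)]
        tsv = outdir / f"targets_{tf}.tsv"
        pd.DataFrame(rows, columns=["gene_id", "direction"]).to_csv(
            tsv, sep="\t", index=False, lineterminator="\n")
        report["stages"]["targets"][tf] = {
            "bound_genes": len(assignment.bound_genes),
            "de_genes": int(de["passed_filter"].sum()),
            "activated": len(targets.activated),
            "repressed": len(targets.repressed),
            "total": len(targets),
        }
    if len(target_sets) >= 2:
        algebra = target_set_algebra(target_sets)
        report["stages"]["targets"]["overlap_table"] = algebra.as_dict()
        (outdir / "target_venn.json").write_text(
            json.dumps(algebra.as_dict(), indent=1, sort_keys=True) + "\n")

    # ---- stage: accessibility ---------------------------------------------
    stage = "accessibility"
    acc = raw.get("accessibility")
    if acc:
        try:
            rcm = core.read_region_counts(config.path(acc["regions"]),
                                          config.path(acc["counts"]))
            hash_input("region_counts", config.path(acc["counts"]))
        except FileNotFoundError as exc:
            raise StageError(stage, f"missing input: {exc.filename}") from exc
        except core.FormatError as exc:
            raise StageError(stage, str(exc)) from exc

        def resolve_peakset(ref, label):
            if ref in retained:
                return retained[ref]
            return core.read_narrowpeak(config.path(ref), label, chrom_sizes)

        chip = {k: resolve_peakset(v, k) for k, v in acc.get("chip", {}).items()}
        pluri = {k: resolve_peakset(v, k) for k, v in acc.get("pluri", {}).items()}
        das = call_da_regions(rcm, wt=acc.get("wt", "WT"), ko=acc["ko"],
                              day=acc.get("day", day), lfc_min=params["da_lfc_min"],
                              min_mean=params["da_min_mean"],
                              pseudocount=params["da_pseudocount"])
        labeled = classify_da_occupancy(das, chip, pluri)
        fractions = activated_fraction_by_group(labeled)
        klasses = tss_distance_classes(labeled, ann, proximal_max=params["w_prom"],
                                       distal_min=params["d_distal"])
        rows = [{
            "region_id": da.region.region_id, "chrom": da.region.chrom,
            "start": da.region.start, "end": da.region.end,
            "log2fc": round(da.log2fc, 6), "direction": da.direction,
            "occupancy": da.occupancy,
            "tss_class": klasses.loc[da.region.region_id, "klass"],
        } for da in labeled]
        pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end", "log2fc",
                                    "direction", "occupancy", "tss_class"]).to_csv(
            outdir / "da_regions.tsv", sep="\t", index=False, lineterminator="\n")
        group_counts = {g: int(fractions.loc[g, "n"]) for g in fractions.index}
        report["stages"]["accessibility"] = {
            "n_regions": len(rcm.regions),
            "n_da": len(labeled),
            "groups": group_counts,
            "fraction_activated": {
                g: (None if fractions.loc[g, "n"] == 0
                    else round(float(fractions.loc[g, "fraction_activated"]), 6))
                for g in fractions.index
            },
            "tss_classes": klasses["klass"].value_counts().sort_index().to_dict(),
        }
        (outdir / "da_group_summary.json").write_text(
            json.dumps(report["stages"]["accessibility"], indent=1, sort_keys=True) + "\n")

    # ---- stage: clustering -------------------------------------------------
    stage = "clustering"
    clu = raw.get("clustering")
    if clu:
        genes_spec = clu.get("genes")
        if isinstance(genes_spec, str):
            gene_path = config.path(genes_spec)
            if not gene_path.exists():
                raise StageError(stage, f"missing input: {gene_path}")
            genes = [g for g in gene_path.read_text().split() if g]
        elif isinstance(genes_spec, dict):
            tf = genes_spec["tf"]
            if tf not in retained:
                raise StageError(stage, f"clustering TF {tf!r} not configured")
            bound = assign_peaks_to_genes(retained[tf], ann, w=params["w_prom"]).bound_genes
            de1 = call_de_genes(expr, "WT", genes_spec["single_ko"], day=day,
                                fpkm_min=params["fpkm_min"], lfc_min=params["lfc_min"],
                                pseudocount=params["pseudocount"])
            de2 = call_de_genes(expr, "WT", genes_spec["dko"], day=day,
                                fpkm_min=params["fpkm_min"], lfc_min=params["lfc_min"],
                                pseudocount=params["pseudocount"])
            genes = sorted(build_cluster_gene_set(bound, de1, de2))
        else:
            raise StageError(stage, "clustering.genes must be a file path or a rule mapping")
        try:
            cr = cluster_targets(expr, genes, clu["genotypes"], k=params["k"],
                                 seed=config.seed, n_restarts=params["n_restarts"],
                                 day=day)
        except (ValueError, KeyError) as exc:
            raise StageError(stage, str(exc)) from exc
        cr.labels.to_frame().to_csv(outdir / "cluster_labels.tsv", sep="\t",
                                    lineterminator="\n")
        cr.profiles.round(6).to_csv(outdir / "cluster_profiles.tsv", sep="\t",
                                    lineterminator="\n")
        report["stages"]["clustering"] = {
            "n_genes": len(genes),
            "k": cr.k,
            "sizes": {int(k): int(v) for k, v in cr.sizes().items()},
            "inertia": round(cr.inertia, 6),
        }

    report_text = json.dumps(report, indent=1, sort_keys=True) + "\n"
    (outdir / "report.json").write_text(report_text)
    report["report_sha256"] = hashlib.sha256(report_text.encode()).hexdigest()
    return report
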