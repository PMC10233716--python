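"""K-means clustering of direct-target expression across genotypes.

Genes bound by a TF and differentially expressed in its single and/or
double knockout are clustered (k = 7 by default) on their per-gene
z-scored mean expression profiles across genotypes (WT, single KOs, dKO),
then each cluster is characterized by how consistently its genes respond
to each knockout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core import ExpressionMatrix

#: Default number of expression clusters.
DEFAULT_K = 7


@dataclass
class ClusterResult:
    labels: pd.Series          # gene_id -> cluster index in 1..k
    profiles: pd.DataFrame     # cluster x genotype mean z-scored profile
    inertia: float
    k: int
    constant_genes: list       # genes whose profile was constant (z -> 0)

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def _zscore_rows(mat: pd.DataFrame):
    """Per-gene z-score across columns; constant rows fall back to zeros."""
    mu = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=0)
    constant = sd == 0
    sd_safe = sd.mask(constant, 1.0)
    z = mat.sub(mu, axis=0).div(sd_safe, axis=0)
    z.loc[constant] = 0.0
    return z, list(mat.index[constant])


def cluster_targets(
    expr: ExpressionMatrix,
    genes,
    genotypes,
    k: int = DEFAULT_K,
    seed: int = 0,
    n_restarts: int = 25,
    day: int | None = None,
    log_pseudocount: float = 1.0,
) -> ClusterResult:
    """Best-of-restarts Lloyd k-means on standardized genotype-mean profiles.

    Genotype means are log2-transformed (``log2(mean + log_pseudocount)``,
    the usual compression for FPKM-scale heatmaps) and then z-scored per
    gene.  Clusters are renumbered 1..k by descending mean (z-scored) WT
    expression so that reported labels are stable across internal label
    permutations.  Deterministic given (seed, n_restarts).
    """
    genes = [g for g in genes]
    if len(genes) < k:
        raise ValueError(f"k={k} exceeds number of genes ({len(genes)})")
    missing = [g for g in genes if g not in expr.values.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing[:5]}")
    means = pd.DataFrame(
        {geno: expr.condition_means(geno, day).loc[genes] for geno in genotypes}
    )
    log_means = np.log2(means + log_pseudocount)
    z, constant_genes = _zscore_rows(log_means)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed, algorithm="lloyd")
    raw = km.fit_predict(z.to_numpy())
    # canonical renumbering: cluster 1 has the highest mean WT z-score
    wt_col = genotypes[0]
    order = (
        pd.Series(z[wt_col].to_numpy(), index=raw)
        .groupby(level=0)
        .mean()
        .sort_values(ascending=False)
        .index.tolist()
    )
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([remap[r] for r in raw], index=pd.Index(genes, name="gene_id"), name="cluster")
    profiles = z.groupby(labels).mean()
    profiles.index.name = "cluster"
    return ClusterResult(
        labels=labels,
        profiles=profiles,
        inertia=float(km.inertia_),
        k=k,
        constant_genes=constant_genes,
    )


# rule-based cluster tags
BOTH_REQUIRED = "both-required"
EITHER_SUFFICIENT = "either-sufficient"
EOMES_ONLY = "Eomes-only"
T_ONLY = "T-only"
REPRESSED_TAG = "repressed"
MIXED = "mixed"


def characterize_clusters(
    cr: ClusterResult,
    de_tables: dict,
    single_kos=("EKO", "TKO"),
    dko: str = "dKO",
    frac_threshold: float = 0.75,
    lfc_min: float = 1.0,
) -> pd.DataFrame:
    """Annotate clusters by knockout response.

    ``de_tables`` maps genotype label -> DE table (WT vs that KO).  For each
    cluster the fraction of genes down in each single KO (log2fc >= lfc_min,
    i.e. lower in the KO) and in the dKO is computed, plus the fraction up
    in the dKO, and a rule-based tag is assigned:

    - both-required: down in both single KOs and in the dKO;
    - Eomes-only / T-only: down in exactly that single KO and in the dKO;
    - either-sufficient: down in the dKO only (single KOs compensate);
    - repressed: up in the dKO;
    - mixed: anything else.

    Fractions compare against ``frac_threshold`` (default 0.75).
    """
    eko, tko = single_kos

    def frac(genes, genotype, sign):
        lfc = de_tables[genotype]["log2fc"].reindex(genes)
        if sign > 0:
            return float((lfc >= lfc_min).mean())
        return float((lfc <= -lfc_min).mean())

    rows = []
    for cluster, genes in cr.labels.groupby(cr.labels).groups.items():
        genes = list(genes)
        f_eko = frac(genes, eko, +1)
        f_tko = frac(genes, tko, +1)
        f_dko = frac(genes, dko, +1)
        f_dko_up = frac(genes, dko, -1)
        thr = frac_threshold
        if f_dko_up >= thr:
            tag = REPRESSED_TAG
        elif f_dko >= thr and f_eko >= thr and f_tko >= thr:
            tag = BOTH_REQUIRED
        elif f_dko >= thr and f_eko >= thr and f_tko < thr:
            tag = EOMES_ONLY
        elif f_dko >= thr and f_tko >= thr and f_eko < thr:
            tag = T_ONLY
        elif f_dko >= thr:
            tag = EITHER_SUFFICIENT
        else:
            tag = MIXED
        rows.append(
            {
                "cluster": cluster,
                "n": len(genes),
                f"frac_down_{eko}": f_eko,
                f"frac_down_{tko}": f_tko,
                f"frac_down_{dko}": f_dko,
                f"frac_up_{dko}": f_dko_up,
                "tag": tag,
            }
        )
    return pd.DataFrame(rows).set_index("cluster").sort_index()
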