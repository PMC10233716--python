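"""Shared fixtures: randomized genomic fixtures and session-scoped datasets."""

import numpy as np
import pandas as pd
import pytest

from circuitcall import GeneAnnotation, Peak, PeakSet
from circuitcall.simulate import SimConfig, emit_worked_example, simulate


def make_annotation(rng, n_genes=40, n_chroms=2, chrom_length=1_000_000):
    """Random TSS table; gene ids shuffled so sort order is exercised."""
    rows = []
    for i in range(n_genes):
        rows.append(
            {
                "gene_id": f"g{i:03d}",
                "chrom": f"chr{1 + int(rng.integers(n_chroms))}",
                "strand": "+" if rng.random() < 0.5 else "-",
                "tss": int(rng.integers(0, chrom_length)),
            }
        )
    df = pd.DataFrame(rows).sample(frac=1.0, random_state=int(rng.integers(2**31)))
    sizes = {f"chr{c + 1}": chrom_length for c in range(n_chroms)}
    return GeneAnnotation(df, sizes)


def make_peakset(rng, label="ps", n=150, n_chroms=2, chrom_length=1_000_000, width=200):
    peaks = []
    for i in range(n):
        chrom = f"chr{1 + int(rng.integers(n_chroms))}"
        start = int(rng.integers(0, chrom_length - width))
        summit = start + int(rng.integers(0, width))
        q = 10.0 ** -float(rng.uniform(1, 10))
        peaks.append(
            Peak(chrom, start, start + width, summit, score=float(rng.uniform(1, 50)),
                 qvalue=q, name=f"{label}_{i:04d}")
        )
    return PeakSet(label, peaks)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def worked_example(tmp_path_factory):
    d = tmp_path_factory.mktemp("worked_example")
    return emit_worked_example(d)


@pytest.fixture(scope="session")
def sim_noise_free(tmp_path_factory):
    d = tmp_path_factory.mktemp("sim_noise_free")
    cfg = SimConfig(seed=11, lfc_noise_sd=0.0, ko_leak_rate=0.0, da_effect_lfc=2.0)
    return simulate(cfg, d)


@pytest.fixture(scope="session")
def sim_noisy(tmp_path_factory):
    d = tmp_path_factory.mktemp("sim_noisy")
    cfg = SimConfig(seed=7, lfc_noise_sd=0.25, ko_leak_rate=0.0, n_replicates=2)
    return simulate(cfg, d)
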