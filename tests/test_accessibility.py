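"""DA calling, occupancy classification, density, and the paired t-test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import circuitcall as cc
from circuitcall import Peak, PeakSet, Region
from circuitcall.accessibility import (
    ACTIVATED,
    NONE,
    OCCUPANCY_GROUPS,
    OSN,
    OSN_PARTIAL,
    REPRESSED,
    SMAD15_SOLO,
    SMAD152,
    SMAD2_SOLO,
    occupying_tfs,
)

from conftest import make_annotation


def rcm_from(rows, columns=("WT.d2.r1", "WT.d2.r2", "KO.d2.r1", "KO.d2.r2"), lib=1e6):
    regions = [Region("chr1", 1000 * i, 1000 * i + 500, rid) for i, rid in enumerate(rows)]
    counts = pd.DataFrame(
        {c: [rows[rid][j] for rid in rows] for j, c in enumerate(columns)},
        index=pd.Index(list(rows), name="region_id"),
    )
    return cc.RegionCountMatrix(regions, counts, pd.Series(lib, index=counts.columns))


class TestDACalling:
    def test_fourfold_region_is_activated(self):
        rcm = rcm_from({"r1": (40, 44, 9, 11)})
        (da,) = cc.call_da_regions(rcm, "WT", "KO")
        assert da.direction == ACTIVATED
        assert da.log2fc == pytest.approx(2.0, abs=0.1)

    def test_flat_region_not_called(self):
        rcm = rcm_from({"r1": (10, 12, 10, 11)})
        assert cc.call_da_regions(rcm, "WT", "KO") == []

    def test_direction_flips_under_condition_swap(self):
        rcm = rcm_from({"r1": (40, 44, 9, 11), "r2": (9, 11, 40, 44)})
        fwd = {d.region.region_id: d.direction for d in cc.call_da_regions(rcm, "WT", "KO")}
        rev = {d.region.region_id: d.direction for d in cc.call_da_regions(rcm, "KO", "WT")}
        assert fwd == {"r1": ACTIVATED, "r2": REPRESSED}
        assert rev == {"r1": REPRESSED, "r2": ACTIVATED}

    def test_replicate_sign_disagreement_vetoes(self):
        # mean ratio exceeds the threshold but one replicate pair disagrees
        rcm = rcm_from({"r1": (200, 8, 20, 22)})
        assert cc.call_da_regions(rcm, "WT", "KO") == []

    def test_low_coverage_filtered(self):
        rcm = rcm_from({"r1": (8, 8, 1, 1)})
        assert cc.call_da_regions(rcm, "WT", "KO", min_mean=10) == []


def _ps(label, summits):
    return PeakSet(label, [Peak("chr1", s - 100, s + 100, s) for s in summits])


class TestOccupancy:
    CHIP = {"smad15": _ps("smad15", [1100, 5100]), "smad2": _ps("smad2", [1200, 9100])}
    PLURI = {
        "oct4": _ps("oct4", [13_100]),
        "sox2": _ps("sox2", [13_200, 17_100]),
        "nanog": _ps("nanog", [13_300]),
    }

    def _da(self, rid, start):
        return cc.DARegion(Region("chr1", start, start + 500, rid), 1.5, ACTIVATED, 40, 10)

    def test_six_group_assignment(self):
        das = [self._da(f"r{i}", s) for i, s in enumerate([1000, 5000, 9000, 13_000, 17_000, 21_000])]
        labeled = cc.classify_da_occupancy(das, self.CHIP, self.PLURI)
        groups = [d.occupancy for d in labeled]
        assert groups == [SMAD152, SMAD15_SOLO, SMAD2_SOLO, OSN, OSN_PARTIAL, NONE]

    def test_groups_partition_random_regions(self, rng):
        das = [self._da(f"r{i}", int(rng.integers(0, 30_000))) for i in range(60)]
        labeled = cc.classify_da_occupancy(das, self.CHIP, self.PLURI)
        assert all(d.occupancy in OCCUPANCY_GROUPS for d in labeled)
        assert len(labeled) == len(das)
        frac = cc.activated_fraction_by_group(labeled)
        assert int(frac["n"].sum()) == len(das)

    def test_summit_in_region_rule(self):
        r = Region("chr1", 1000, 1500, "r")
        inside = {"x": _ps("x", [1499])}
        outside = {"x": _ps("x", [1500])}
        assert occupying_tfs(r, inside) == {"x"}
        assert occupying_tfs(r, outside) == set()

    def test_activated_fraction_arithmetic(self):
        das = [self._da(f"r{i}", 1000) for i in range(4)]
        das[3] = cc.DARegion(das[3].region, -1.5, REPRESSED, 10, 40)
        labeled = cc.classify_da_occupancy(das, self.CHIP, {})
        frac = cc.activated_fraction_by_group(labeled)
        assert frac.loc[SMAD152, "n"] == 4
        assert frac.loc[SMAD152, "fraction_activated"] == pytest.approx(0.75)
        assert np.isnan(frac.loc[OSN, "fraction_activated"])


def density_oracle(regions, reads_by_sample, library_sizes, extend=0):
    out = {}
    for sample, by_chrom in reads_by_sample.items():
        for r in regions:
            n = 0
            for chrom, (starts, ends) in by_chrom.items():
                if chrom != r.chrom:
                    continue
                for s, e in zip(starts, ends):
                    if s - extend < r.end and e + extend > r.start:
                        n += 1
            out[(r.region_id, sample)] = n / ((r.length / 1000) * (library_sizes[sample] / 1e6))
    return out


def random_reads(rng, n, chrom_length=50_000, length=50):
    starts = np.sort(rng.integers(0, chrom_length - length, size=n))
    return {"chr1": (starts, starts + length)}


class TestDensity:
    def test_no_overlapping_reads_is_zero(self):
        regions = [Region("chr1", 1000, 2000, "r")]
        reads = {"s1": {"chr1": (np.array([5000]), np.array([5050]))}}
        dm = cc.quantify_density(regions, reads, {"s1": 1e6})
        assert dm.loc["r", "s1"] == 0.0

    def test_invariant_under_uniform_scaling(self, rng):
        regions = [Region("chr1", i * 2000, i * 2000 + 800, f"r{i}") for i in range(10)]
        reads = {"s1": random_reads(rng, 500)}
        dm1 = cc.quantify_density(regions, reads, {"s1": 1e6})
        starts, ends = reads["s1"]["chr1"]
        doubled = {"s1": {"chr1": (np.sort(np.concatenate([starts, starts])),
                                   np.sort(np.concatenate([ends, ends])))}}
        dm2 = cc.quantify_density(regions, doubled, {"s1": 2e6})
        pd.testing.assert_frame_equal(dm1, dm2)

    def test_matches_per_read_oracle(self, rng):
        regions = [Region("chr1", int(s), int(s) + 700, f"r{i}")
                   for i, s in enumerate(rng.integers(0, 45_000, size=15))]
        reads = {"s1": random_reads(rng, 400), "s2": random_reads(rng, 300)}
        libs = {"s1": 2e6, "s2": 1e6}
        dm = cc.quantify_density(regions, reads, libs)
        oracle = density_oracle(regions, reads, libs)
        for r in regions:
            for s in ("s1", "s2"):
                assert dm.loc[r.region_id, s] == pytest.approx(oracle[(r.region_id, s)])

    def test_zero_length_region_rejected(self):
        with pytest.raises(ValueError):
            Region("chr1", 100, 100, "r")


class TestPairedT:
    def test_closed_form_example(self):
        # d = (1, 2, 3): t = mean/ (sd/sqrt(3)) = 2*sqrt(3)
        res = cc.paired_t_test([2, 4, 6], [1, 2, 3])
        assert res.t == pytest.approx(2 * np.sqrt(3), abs=1e-9)
        assert res.df == 2
        assert res.p == pytest.approx(0.0742, abs=5e-4)

    def test_identical_pairs_flagged_p_one(self):
        res = cc.paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0
        assert res.degenerate == "identical_pairs"

    def test_constant_nonzero_difference_floors_p(self):
        res = cc.paired_t_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res.degenerate == "zero_variance"
        assert 0 < res.p < 1e-300

    def test_antisymmetry(self, rng):
        x = rng.normal(5, 1, size=10)
        y = rng.normal(4, 1, size=10)
        f = cc.paired_t_test(x, y)
        r = cc.paired_t_test(y, x)
        assert f.t == pytest.approx(-r.t)
        assert f.p == pytest.approx(r.p)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            cc.paired_t_test([1.0], [2.0])

    def test_agrees_with_scipy_reference(self, rng):
        for _ in range(10):
            x = rng.normal(0, 1, size=8)
            y = rng.normal(0.5, 1, size=8)
            mine = cc.paired_t_test(x, y)
            ref = stats.ttest_rel(x, y)
            assert mine.t == pytest.approx(ref.statistic)
            assert mine.p == pytest.approx(ref.pvalue)


class TestTSSClasses:
    def test_midpoint_at_tss_is_proximal(self, rng):
        ann = make_annotation(rng, n_genes=5, n_chroms=1)
        tss = int(ann.table["tss"].iloc[0])
        da = cc.DARegion(Region("chr1", tss - 250, tss + 250, "r"), 1.5, ACTIVATED, 40, 10)
        out = cc.tss_distance_classes([da], ann)
        assert out.loc["r", "klass"] == "proximal"

    def test_far_midpoint_is_distal(self):
        ann = cc.GeneAnnotation(
            pd.DataFrame({"gene_id": ["a"], "chrom": ["chr1"], "strand": ["+"], "tss": [1000]})
        )
        da = cc.DARegion(Region("chr1", 50_700, 51_300, "r"), 1.5, ACTIVATED, 40, 10)
        out = cc.tss_distance_classes([da], ann)
        assert out.loc["r", "klass"] == "distal"

    def test_class_counts_match_oracle(self, rng):
        ann = make_annotation(rng, n_genes=30)
        das = []
        for i in range(80):
            start = int(rng.integers(0, 900_000))
            chrom = f"chr{1 + int(rng.integers(2))}"
            das.append(cc.DARegion(Region(chrom, start, start + 600, f"r{i}"),
                                   1.0, ACTIVATED, 40, 10))
        out = cc.tss_distance_classes(das, ann)
        for da in das:
            mid = da.region.midpoint
            best = min(
                abs(row.tss - mid)
                for row in ann.table.itertuples() if row.chrom == da.region.chrom
            )
            expected = ("proximal" if best <= 2000
                        else "2-10kb" if best <= 10_000 else "distal")
            assert out.loc[da.region.region_id, "klass"] == expected
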