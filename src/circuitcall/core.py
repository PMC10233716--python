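"""Core genomic data types and file I/O.

All in-memory coordinates are 0-based, half-open ``[start, end)``.  The
narrowPeak and BED dialects on disk are already 0-based half-open, so no
shifting occurs at file boundaries; any 1-based conversion would live in a
reader/writer, never in analysis code.

The types here are deliberately thin: a :class:`Peak` is the atom of all
ChIP-seq logic (every overlap and gene-assignment rule in this package is
*summit*-based), a :class:`GeneAnnotation` is a pre-distilled table of one
transcription start site (TSS) per gene, and the two matrix classes wrap
pandas DataFrames with the sample metadata the downstream comparisons need
(condition = genotype, replicate index, differentiation day).
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

INF = math.inf

#: Promoter half-width in bp: a summit within TSS +/- W_PROM is
#: promoter-associated.
W_PROM = 2000

#: Summit-distance threshold in bp below which two peaks are called
#: overlapping, and below which a KO peak invalidates a WT peak.
D_OVERLAP = 300

#: Distance beyond which a site is called distal (putative enhancer).
D_DISTAL = 10_000


class FormatError(ValueError):
    """A file did not conform to its declared dialect."""


ChromSizes = dict  # chrom name -> length in bp


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Peak:
    """A called binding-site interval with a single-base summit.

    ``qvalue`` is the peak-calling confidence on the linear scale, in
    ``(0, 1]``, or ``None`` when the caller did not report one.
    ``summit_imputed`` marks summits that were reconstructed as the interval
    midpoint because the source file carried no summit offset.
    """

    chrom: str
    start: int
    end: int
    summit: int
    score: float = 0.0
    qvalue: float | None = None
    name: str = ""
    summit_imputed: bool = False

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"peak start must be >= 0, got {self.start}")
        if not self.start < self.end:
            raise ValueError(f"peak requires start < end, got [{self.start}, {self.end})")
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.score < 0:
            raise ValueError("peak score must be nonnegative")
        if self.qvalue is not None and not (0 < self.qvalue <= 1):
            raise ValueError(f"qvalue must be in (0, 1], got {self.qvalue}")


@dataclass
class PeakSet:
    """An ordered collection of peaks for one TF / genotype / day.

    Peaks are kept sorted by ``(chrom, start, summit)``; input order never
    matters downstream.
    """

    label: str
    peaks: list = field(default_factory=list)

    def __post_init__(self):
        self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.summit, p.name))

    def __len__(self):
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def validate_chroms(self, chrom_sizes: ChromSizes) -> None:
        """Reject peaks on undeclared chromosomes or beyond declared bounds."""
        for p in self.peaks:
            if p.chrom not in chrom_sizes:
                raise ValueError(f"peak {p.name or p.summit} on undeclared chromosome {p.chrom}")
            if p.end > chrom_sizes[p.chrom]:
                raise ValueError(
                    f"peak {p.name or p.summit} extends past end of {p.chrom} "
                    f"({p.end} > {chrom_sizes[p.chrom]})"
                )

    def summits_by_chrom(self) -> dict:
        """chrom -> ascending numpy array of summit coordinates."""
        out = {}
        for p in self.peaks:
            out.setdefault(p.chrom, []).append(p.summit)
        return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in out.items()}


@dataclass(frozen=True)
class Region:
    """A genomic region (e.g. an accessible-chromatin interval)."""

    chrom: str
    start: int
    end: int
    region_id: str

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"region {self.region_id}: start < end required")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start


class GeneAnnotation:
    """Gene records with one TSS per gene, defining promoter windows.

    Parameters
    ----------
    table:
        DataFrame with columns ``gene_id, chrom, strand, tss`` (optional
        ``name``).  ``gene_id`` must be unique and ``tss >= 0``.
    chrom_sizes:
        Optional declared chromosome-size table; when given, every gene
        chromosome must appear in it.
    """

    def __init__(self, table: pd.DataFrame, chrom_sizes: ChromSizes | None = None):
        required = ["gene_id", "chrom", "strand", "tss"]
        missing = [c for c in required if c not in table.columns]
        if missing:
            raise FormatError(f"annotation missing columns: {missing}")
        tbl = table.copy()
        if "name" not in tbl.columns:
            tbl["name"] = tbl["gene_id"]
        tbl["tss"] = tbl["tss"].astype(np.int64)
        if tbl["gene_id"].duplicated().any():
            dups = tbl.loc[tbl["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene_id in annotation: {dups}")
        if (tbl["tss"] < 0).any():
            raise ValueError("annotation contains negative TSS coordinates")
        bad = ~tbl["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError(f"invalid strand values: {tbl.loc[bad, 'strand'].unique().tolist()}")
        if chrom_sizes is not None:
            unknown = set(tbl["chrom"]) - set(chrom_sizes)
            if unknown:
                raise ValueError(f"annotation chromosomes not in size table: {sorted(unknown)}")
        self.table = tbl.sort_values(["chrom", "tss", "gene_id"]).reset_index(drop=True)
        self.chrom_sizes = dict(chrom_sizes) if chrom_sizes is not None else None
        # per-chromosome sorted TSS arrays for fast nearest / window queries
        self._by_chrom = {}
        for chrom, sub in self.table.groupby("chrom", sort=True):
            self._by_chrom[chrom] = (
                sub["tss"].to_numpy(),
                sub["gene_id"].to_numpy(dtype=object),
            )

    def __len__(self):
        return len(self.table)

    @property
    def gene_ids(self) -> list:
        return self.table["gene_id"].tolist()

    def tss_of(self, gene_id: str) -> int:
        row = self.table.loc[self.table["gene_id"] == gene_id]
        if row.empty:
            raise KeyError(gene_id)
        return int(row["tss"].iloc[0])

    def chrom_arrays(self, chrom: str):
        """Return (tss array, gene_id array) for ``chrom``, or None."""
        return self._by_chrom.get(chrom)

    def genes_in_window(self, chrom: str, lo: int, hi: int) -> list:
        """gene_ids with lo <= tss <= hi on ``chrom``, sorted by (tss, gene_id)."""
        arrays = self._by_chrom.get(chrom)
        if arrays is None:
            return []
        tss, gids = arrays
        i = int(np.searchsorted(tss, lo, side="left"))
        j = int(np.searchsorted(tss, hi, side="right"))
        return list(gids[i:j])


_SAMPLE_RE = re.compile(
    r"^(?P<cond>[A-Za-z0-9_-]+?)(?:\.d(?P<day>\d+))?(?:\.r(?P<rep>\d+))?$"
)


def parse_sample_id(sample_id: str):
    """Split ``COND[.dDAY][.rREP]`` into (condition, day or None, replicate)."""
    m = _SAMPLE_RE.match(sample_id)
    if not m:
        raise FormatError(f"cannot parse sample id {sample_id!r}")
    day = m.group("day")
    rep = m.group("rep")
    return m.group("cond"), (int(day) if day is not None else None), (int(rep) if rep else 1)


def _sample_frame(sample_ids) -> pd.DataFrame:
    rows = []
    for s in sample_ids:
        cond, day, rep = parse_sample_id(s)
        rows.append({"sample_id": s, "condition": cond, "day": day, "replicate": rep})
    df = pd.DataFrame(rows)
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids")
    return df.set_index("sample_id", drop=False)


class ExpressionMatrix:
    """Gene x sample table of nonnegative FPKM-like abundances.

    Sample ids encode their metadata as ``condition[.dDAY][.rREP]`` (e.g.
    ``WT.d2.r1``); the parsed fields are exposed in :attr:`samples`.
    """

    def __init__(self, values: pd.DataFrame):
        if values.index.duplicated().any():
            raise ValueError("duplicate gene_id in expression matrix")
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite values")
        if (arr < 0).any():
            raise ValueError("expression matrix contains negative values")
        self.values = values.astype(float)
        self.values.index.name = "gene_id"
        self.samples = _sample_frame(values.columns)

    @property
    def genes(self) -> list:
        return list(self.values.index)

    def select_samples(self, condition: str, day: int | None = None) -> list:
        mask = self.samples["condition"] == condition
        if day is not None:
            mask &= self.samples["day"] == day
        return list(self.samples.loc[mask, "sample_id"])

    def condition_means(self, condition: str, day: int | None = None) -> pd.Series:
        cols = self.select_samples(condition, day)
        if not cols:
            raise ValueError(f"no samples for condition {condition!r} (day={day})")
        return self.values[cols].mean(axis=1)


class RegionCountMatrix:
    """Accessibility region x sample counts with per-sample library sizes."""

    def __init__(self, regions: list, counts: pd.DataFrame, library_sizes: pd.Series):
        ids = [r.region_id for r in regions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate region_id")
        if list(counts.index) != ids:
            missing = set(counts.index) ^ set(ids)
            raise ValueError(f"counts rows do not match region BED: {sorted(missing)[:5]}")
        arr = counts.to_numpy(dtype=float)
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise ValueError("counts must be finite and nonnegative")
        lib = library_sizes.reindex(counts.columns)
        if lib.isna().any():
            raise ValueError("library size missing for some samples")
        if (lib <= 0).any():
            raise ValueError("library sizes must be > 0")
        colsum = counts.sum(axis=0)
        if (lib + 1e-9 < colsum).any():
            raise ValueError("library_sizes smaller than column sums of counted reads")
        self.regions = list(regions)
        self.counts = counts.astype(float)
        self.counts.index.name = "region_id"
        self.library_sizes = lib.astype(float)
        self.samples = _sample_frame(counts.columns)

    def region_by_id(self, region_id: str) -> Region:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(region_id)

    def select_samples(self, condition: str, day: int | None = None) -> list:
        mask = self.samples["condition"] == condition
        if day is not None:
            mask &= self.samples["day"] == day
        return list(self.samples.loc[mask, "sample_id"])

    def cpm(self) -> pd.DataFrame:
        """Counts per million declared library reads, per sample."""
        return self.counts.div(self.library_sizes, axis=1) * 1e6


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------
# All writers emit LF-terminated, tab-separated text with a deterministic
# column order so that byte-identical round-trips are testable.

def read_chrom_sizes(path) -> ChromSizes:
    sizes = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{ln}: chrom sizes requires 2 columns")
        sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: ChromSizes, path) -> None:
    lines = [f"{c}\t{sizes[c]}" for c in sorted(sizes)]
    Path(path).write_text("\n".join(lines) + "\n")


def _fmt_qvalue(q: float | None) -> str:
    # narrowPeak column 9 carries -log10(q); -1 means "not reported"
    if q is None:
        return "-1"
    return f"{-math.log10(q):.10g}"


def read_narrowpeak(path, label: str, chrom_sizes: ChromSizes | None = None) -> PeakSet:
    """Read an ENCODE narrowPeak (BED6+4) file into a sorted :class:`PeakSet`.

    Column 10 is the summit offset from ``start``; an offset of ``-1``
    (unknown summit) falls back to the interval midpoint and the peak is
    flagged ``summit_imputed``.  Column 9 is ``-log10(qvalue)`` per the
    ENCODE dialect and is converted to a linear q-value.
    """
    peaks = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 10:
            raise FormatError(f"{path}:{ln}: narrowPeak requires 10 columns, got {len(parts)}")
        try:
            chrom = parts[0]
            start, end = int(parts[1]), int(parts[2])
            name = parts[3]
            signal = float(parts[6])
            neglog_q = float(parts[8])
            offset = int(parts[9])
        except ValueError as exc:
            raise FormatError(f"{path}:{ln}: malformed narrowPeak row ({exc})") from None
        qvalue = None if neglog_q < 0 else 10.0 ** (-neglog_q)
        if qvalue is not None:
            qvalue = min(qvalue, 1.0)
        if offset == -1:
            summit, imputed = (start + end) // 2, True
        else:
            summit, imputed = start + offset, False
            if not (start <= summit < end):
                raise FormatError(f"{path}:{ln}: summit {summit} outside [{start}, {end})")
        peaks.append(
            Peak(chrom, start, end, summit, score=signal, qvalue=qvalue,
                 name=name, summit_imputed=imputed)
        )
    ps = PeakSet(label, peaks)
    if chrom_sizes is not None:
        ps.validate_chroms(chrom_sizes)
    return ps


def write_narrowpeak(ps: PeakSet, path) -> None:
    lines = []
    for p in ps:
        offset = -1 if p.summit_imputed else p.summit - p.start
        lines.append(
            "\t".join([
                p.chrom, str(p.start), str(p.end), p.name or ".", "0", ".",
                f"{p.score:g}", "-1", _fmt_qvalue(p.qvalue), str(offset),
            ])
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_annotation(path, chrom_sizes: ChromSizes | None = None) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    return GeneAnnotation(df, chrom_sizes=chrom_sizes)


def write_annotation(ann: GeneAnnotation, path) -> None:
    cols = ["gene_id", "chrom", "strand", "tss", "name"]
    ann.table[cols].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_expression(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path) -> None:
    df = expr.values.copy()
    df.to_csv(path, sep="\t", index=True, lineterminator="\n", float_format="%.6g")


def read_regions_bed(path) -> list:
    regions = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise FormatError(f"{path}:{ln}: region BED requires 4 columns (chrom start end id)")
        regions.append(Region(parts[0], int(parts[1]), int(parts[2]), parts[3]))
    ids = [r.region_id for r in regions]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate region ids")
    return regions


def write_regions_bed(regions: list, path) -> None:
    lines = [f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}" for r in regions]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


_LIBSIZE_PREFIX = "#library_sizes\t"


def read_region_counts(bed_path, counts_path) -> RegionCountMatrix:
    """Read a region BED plus a headered region x sample count TSV.

    The counts file may begin with a ``#library_sizes`` comment line whose
    tab-separated values align with the sample columns; when absent, library
    sizes default to the column sums.
    """
    regions = read_regions_bed(bed_path)
    text = Path(counts_path).read_text().splitlines()
    lib_line = None
    body = []
    for line in text:
        if line.startswith(_LIBSIZE_PREFIX):
            lib_line = line[len(_LIBSIZE_PREFIX):].split("\t")
        elif line.strip():
            body.append(line)
    df = pd.read_csv(io.StringIO("\n".join(body)), sep="\t", index_col="region_id")
    known = {r.region_id for r in regions}
    unknown = [i for i in df.index if i not in known]
    if unknown:
        raise FormatError(f"{counts_path}: region ids missing from BED: {unknown[:5]}")
    order = [r.region_id for r in regions]
    missing = [i for i in order if i not in df.index]
    if missing:
        raise FormatError(f"{counts_path}: BED regions missing from counts: {missing[:5]}")
    df = df.loc[order]
    if lib_line is not None:
        lib = pd.Series([float(v) for v in lib_line], index=df.columns)
    else:
        lib = df.sum(axis=0)
    return RegionCountMatrix(regions, df, lib)


def write_region_counts(rcm: RegionCountMatrix, bed_path, counts_path) -> None:
    write_regions_bed(rcm.regions, bed_path)
    lib = "\t".join(f"{v:g}" for v in rcm.library_sizes)
    header = _LIBSIZE_PREFIX + lib + "\n"
    body = rcm.counts.to_csv(sep="\t", index=True, lineterminator="\n", float_format="%g")
    Path(counts_path).write_text(header + body)


def read_reads_bed(path) -> np.ndarray:
    """Read read intervals (BED3) into a structured-friendly dict.

    Returns {chrom: (starts array, ends array)} with both arrays sorted by
    start.
    """
    by_chrom = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{ln}: read BED requires 3 columns")
        by_chrom.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
    out = {}
    for chrom, ivals in by_chrom.items():
        arr = np.asarray(sorted(ivals), dtype=np.int64)
        out[chrom] = (arr[:, 0], arr[:, 1])
    return out


def write_reads_bed(reads_by_chrom: dict, path) -> None:
    lines = []
    for chrom in sorted(reads_by_chrom):
        starts, ends = reads_by_chrom[chrom]
        for s, e in zip(starts, ends):
            lines.append(f"{chrom}\t{int(s)}\t{int(e)}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Interval primitives
# ---------------------------------------------------------------------------

def summit_distance(a: Peak, b: Peak) -> float:
    """|a.summit - b.summit| when on the same chromosome, else infinity."""
    if a.chrom != b.chrom:
        return INF
    return abs(a.summit - b.summit)


def distance_to_nearest_tss(p: Peak, ann: GeneAnnotation):
    """Nearest-TSS gene for a peak summit.

    Returns ``(gene_id, signed_distance)`` where the signed distance is
    ``summit - tss`` in genomic orientation; ties in absolute distance break
    to the lexicographically smallest gene_id.  A summit on a chromosome
    with no annotated genes returns ``(None, inf)`` (flagged unassigned).
    """
    arrays = ann.chrom_arrays(p.chrom)
    if arrays is None:
        return None, INF
    tss, gids = arrays
    i = int(np.searchsorted(tss, p.summit))
    best = INF
    for j in (i - 1, i):
        if 0 <= j < len(tss):
            best = min(best, abs(int(tss[j]) - p.summit))
    # all genes achieving the minimum |distance| (either side), pick smallest id
    candidates = []
    for target in (p.summit - best, p.summit + best):
        lo = int(np.searchsorted(tss, target, side="left"))
        hi = int(np.searchsorted(tss, target, side="right"))
        candidates.extend(gids[lo:hi])
    gene = min(candidates)
    gene_tss = int(tss[list(gids).index(gene)])
    return gene, p.summit - gene_tss
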