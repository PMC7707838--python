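"""Readers and writers for marker lists, pooled allele counts, regions and manifests.

Conventions
-----------
* Coordinates are 1-based inclusive throughout (VCF convention). BED input is
  converted on read.
* The reference allele is the BY allele (sacCer3 is BY-derived); every allele
  frequency in the package refers to the BY/reference allele.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerList",
    "PoolMeta",
    "PooledCounts",
    "Region",
    "PopulationVariantMatrix",
    "read_counts",
    "write_counts_tsv",
    "write_counts_vcf",
    "read_bed",
    "read_manifest",
    "write_manifest",
    "novel_variant_screen",
]

TSV_COLUMNS = ["chrom", "pos", "ref_count", "alt_count"]


@dataclass(frozen=True)
class Region:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    def contains(self, chrom: str, pos: int | np.ndarray):
        if isinstance(pos, np.ndarray):
            return (chrom == self.chrom) & (pos >= self.start) & (pos <= self.end)
        return chrom == self.chrom and self.start <= pos <= self.end


class MarkerList:
    """Ordered list of biallelic markers: (chrom, pos, ref, alt).

    Positions must be unique per chromosome and sorted within chromosome.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"chrom", "pos"}
        if not required.issubset(frame.columns):
            raise ValueError(f"marker list needs columns {sorted(required)}")
        frame = frame.copy()
        if "ref" not in frame.columns:
            frame["ref"] = "A"
        if "alt" not in frame.columns:
            frame["alt"] = "T"
        if frame.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate (chrom, pos) in marker list")
        for chrom, sub in frame.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise ValueError(f"markers on {chrom} are not sorted by position")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def chrom(self) -> np.ndarray:
        return self.frame["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.frame["pos"].to_numpy()

    def key(self) -> pd.Index:
        return pd.MultiIndex.from_frame(self.frame[["chrom", "pos"]])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MarkerList":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class PoolMeta:
    """Metadata for one sorted pool."""

    gene: str = "unknown"
    channel: str = "GFP"  # GFP = protein, mCherry = mRNA
    gate: str = "high"  # high | low | unsorted
    replicate: str = "1"
    batch: str = "1"


@dataclass
class PooledCounts:
    """Per-marker reference (BY) / alternate (RM) read counts for one pool."""

    markers: MarkerList
    ref: np.ndarray
    alt: np.ndarray
    meta: PoolMeta = field(default_factory=PoolMeta)

    def __post_init__(self) -> None:
        self.ref = np.asarray(self.ref, dtype=np.int64)
        self.alt = np.asarray(self.alt, dtype=np.int64)
        if self.ref.shape != self.alt.shape or len(self.ref) != len(self.markers):
            raise ValueError("count arrays must align with the marker list")
        if (self.ref < 0).any() or (self.alt < 0).any():
            raise ValueError("negative read counts")

    @property
    def depth(self) -> np.ndarray:
        return self.ref + self.alt

    def median_depth(self) -> float:
        return float(np.median(self.depth))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.markers.chrom,
                "pos": self.markers.pos,
                "ref_count": self.ref,
                "alt_count": self.alt,
            }
        )


def _check_min_depth(counts: PooledCounts, min_median_depth: float | None) -> None:
    if min_median_depth is not None and counts.median_depth() < min_median_depth:
        raise ValueError(
            f"pool median depth {counts.median_depth():.1f} is below the minimum "
            f"of {min_median_depth}; allele frequencies would be noise-dominated"
        )


def _align_to_markers(
    frame: pd.DataFrame, markers: MarkerList
) -> tuple[np.ndarray, np.ndarray, int]:
    """Align a (chrom,pos,ref_count,alt_count) frame to a marker list.

    Markers absent from the file get zero depth; file records absent from the
    list are dropped with a warning. Returns (ref, alt, n_dropped).
    """
    key = pd.MultiIndex.from_frame(frame[["chrom", "pos"]])
    target = markers.key()
    in_list = key.isin(target)
    n_dropped = int((~in_list).sum())
    if n_dropped:
        warnings.warn(
            f"{n_dropped} record(s) not in the marker list were dropped",
            stacklevel=3,
        )
    frame = frame.loc[in_list]
    aligned = (
        frame.set_index(["chrom", "pos"])
        .reindex(target)
        .fillna({"ref_count": 0, "alt_count": 0})
    )
    return (
        aligned["ref_count"].to_numpy(dtype=np.int64),
        aligned["alt_count"].to_numpy(dtype=np.int64),
        n_dropped,
    )


def _read_counts_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in TSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    bad = frame[TSV_COLUMNS[1:]].isna().any(axis=1)
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise ValueError(f"{path}: malformed record at line {line}")
    return frame


def _read_counts_vcf(path: str | Path, markers: MarkerList) -> pd.DataFrame:
    from cyvcf2 import VCF

    records: list[tuple[str, int, int, int]] = []
    allele_mismatch = 0
    lookup = {
        (c, p): (r, a)
        for c, p, r, a in markers.frame[["chrom", "pos", "ref", "alt"]].itertuples(
            index=False
        )
    }
    for v in VCF(str(path)):
        chrom, pos = v.CHROM, v.POS
        expected = lookup.get((chrom, pos))
        if expected is not None and (v.REF, v.ALT[0] if v.ALT else None) != expected:
            allele_mismatch += 1
            continue
        ad = v.format("AD")
        if ad is None:
            raise ValueError(f"{path}: record {chrom}:{pos} has no AD field")
        ref_n, alt_n = int(ad[0][0]), int(ad[0][1])
        records.append((chrom, pos, max(ref_n, 0), max(alt_n, 0)))
    if allele_mismatch:
        warnings.warn(
            f"{allele_mismatch} record(s) with alleles not matching the marker "
            "list were dropped",
            stacklevel=3,
        )
    return pd.DataFrame(records, columns=TSV_COLUMNS)


def read_counts(
    path: str | Path,
    markers: MarkerList,
    fmt: str | None = None,
    meta: PoolMeta | None = None,
    min_median_depth: float | None = 2,
) -> PooledCounts:
    """Read a pooled count table (TSV or VCF with AD) aligned to `markers`.

    Markers missing from the file get zero depth; positions not in the marker
    list are dropped with a warning. Pools whose median depth falls below
    `min_median_depth` are rejected (pass None to disable).
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in {".vcf", ".gz", ".bcf"} else "tsv"
    if fmt == "tsv":
        frame = _read_counts_tsv(path)
    elif fmt == "vcf":
        frame = _read_counts_vcf(path, markers)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    ref, alt, _ = _align_to_markers(frame, markers)
    counts = PooledCounts(markers, ref, alt, meta or PoolMeta())
    _check_min_depth(counts, min_median_depth)
    return counts


def write_counts_tsv(counts: PooledCounts, path: str | Path) -> None:
    counts.to_frame().to_csv(path, sep="\t", index=False)


def write_counts_vcf(counts: PooledCounts, path: str | Path, sample: str = "pool") -> None:
    """Write one pool as a minimal VCF 4.2 with a single sample carrying AD."""
    m = counts.markers.frame
    chroms = m["chrom"].unique()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=dualqtl\n")
        for c in chroms:
            length = int(m.loc[m["chrom"] == c, "pos"].max()) + 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths (ref,alt)">\n'
        )
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for (chrom, pos, ref, alt), r, a in zip(
            m[["chrom", "pos", "ref", "alt"]].itertuples(index=False),
            counts.ref,
            counts.alt,
        ):
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tAD\t{r},{a}\n")


def read_bed(path: str | Path) -> list[Region]:
    """Read BED intervals (0-based half-open) as 1-based inclusive Regions."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            regions.append(Region(chrom, int(start) + 1, int(end)))
    return regions


MANIFEST_COLUMNS = ["file", "gene", "channel", "gate", "replicate", "batch"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"manifest {path}: missing column(s) {missing}")
    return frame


def write_manifest(rows: pd.DataFrame | Iterable[Mapping], path: str | Path) -> None:
    frame = pd.DataFrame(rows)
    frame.to_csv(path, sep="\t", index=False, columns=MANIFEST_COLUMNS)


@dataclass
class PopulationVariantMatrix:
    """Candidate variant sites × populations (allele frequency / coverage).

    `sites` carries one row per candidate site with at least columns
    (chrom, pos, quality); `af` and `coverage` are sites × populations
    matrices sharing `sites`' row order.
    """

    sites: pd.DataFrame
    af: pd.DataFrame
    coverage: pd.DataFrame

    def __post_init__(self) -> None:
        n = len(self.sites)
        if len(self.af) != n or len(self.coverage) != n:
            raise ValueError("af/coverage must have one row per site")
        values = self.af.to_numpy(dtype=float)
        finite = values[np.isfinite(values)]
        if finite.size and ((finite < 0).any() or (finite > 1).any()):
            raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def populations(self) -> list[str]:
        return list(self.af.columns)


def novel_variant_screen(
    matrix: PopulationVariantMatrix,
    known: MarkerList,
    min_quality: float = 30.0,
    max_error_populations: int = 2,
    design_groups: Mapping[str, Sequence[str]] | None = None,
    presence_min_af: float = 0.1,
    presence_min_coverage: float = 1.0,
) -> pd.DataFrame:
    """Screen for new variants that are not known cross polymorphisms.

    Mirrors the filter cascade used to find the causal YAK1 mutation: drop
    sites in the known marker list, drop sites with quality below
    `min_quality`, and drop sites seen in at most `max_error_populations`
    populations (putative sequencing errors). A site counts as present in a
    population when its allele frequency is at least `presence_min_af` at
    coverage of at least `presence_min_coverage`.

    Returns the surviving sites annotated with `n_populations` and, for each
    design group, the fraction of that group's populations carrying the site.
    """
    if len(matrix.sites) == 0:
        return pd.DataFrame(
            columns=list(matrix.sites.columns) + ["n_populations"]
        )
    sites = matrix.sites.reset_index(drop=True)
    key = pd.MultiIndex.from_frame(sites[["chrom", "pos"]])
    keep = ~key.isin(known.key())
    keep &= sites["quality"].to_numpy(dtype=float) >= min_quality

    af = matrix.af.to_numpy(dtype=float)
    cov = matrix.coverage.to_numpy(dtype=float)
    present = (np.nan_to_num(af) >= presence_min_af) & (cov >= presence_min_coverage)
    n_pop = present.sum(axis=1)
    keep &= n_pop > max_error_populations

    out = sites.loc[keep].copy()
    out["n_populations"] = n_pop[keep]
    if design_groups:
        pops = matrix.populations
        for group, members in design_groups.items():
            idx = [pops.index(p) for p in members]
            out[f"fraction_{group}"] = present[np.ix_(keep, idx)].mean(axis=1)
    return out.reset_index(drop=True)
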