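"""Genomic interval data model, BED/gene-table I/O, and interval arithmetic.

All coordinates are 0-based half-open (`[start, end)`), the native BED
convention; any 1-based inputs must be converted at parse time.  This module
is the common currency of the pipeline: every other stage consumes and
produces :class:`RegionSet` objects validated against a :class:`GenomeLayout`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomeLayout",
    "GenomicInterval",
    "RegionSet",
    "GeneModel",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "write_gene_table",
    "overlap_fraction",
    "venn_partition",
    "union_merge",
    "distance_to_nearest_tss",
]


class BedParseError(ValueError):
    """Malformed BED/table line; message carries the 1-based line number."""


class ValidationError(ValueError):
    """Interval inconsistent with its genome layout or with an invariant."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and their lengths in bp."""

    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        if len(self.chrom_sizes) == 0:
            raise ValidationError("genome layout needs at least one chromosome")
        for name, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive size {size}")

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chrom_sizes)

    def chrom_index(self, chrom: str) -> int:
        return self.chrom_names.index(chrom)

    def size(self, chrom: str) -> int:
        try:
            return self.chrom_sizes[chrom]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    @classmethod
    def from_tsv(cls, path) -> "GenomeLayout":
        sizes: dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 2:
                    raise BedParseError(f"line {lineno}: expected 'chrom\\tsize'")
                sizes[fields[0]] = int(fields[1])
        return cls(sizes)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for name, size in self.chrom_sizes.items():
                fh.write(f"{name}\t{size}\n")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not (isinstance(self.start, (int, np.integer)) and isinstance(self.end, (int, np.integer))):
            raise ValidationError(f"coordinates must be integral: {self.start}, {self.end}")
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


class RegionSet:
    """Ordered collection of :class:`GenomicInterval` with a provenance label.

    Order is stable under round-trip I/O; validation against a genome layout
    is performed once at construction when a layout is supplied.
    """

    def __init__(self, intervals, label: str = "", genome: GenomeLayout | None = None):
        self.intervals: list[GenomicInterval] = list(intervals)
        self.label = label
        self.genome = genome
        if genome is not None:
            for iv in self.intervals:
                if iv.end > genome.size(iv.chrom):
                    raise ValidationError(
                        f"interval {iv.key()} exceeds {iv.chrom} size {genome.size(iv.chrom)}"
                    )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def keys(self) -> list[str]:
        return [iv.key() for iv in self.intervals]

    def sorted(self) -> "RegionSet":
        if self.genome is not None:
            order = {c: i for i, c in enumerate(self.genome.chrom_names)}
            key = lambda iv: (order[iv.chrom], iv.start, iv.end)
        else:
            key = lambda iv: (iv.chrom, iv.start, iv.end)
        return RegionSet(sorted(self.intervals, key=key), self.label, self.genome)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out


@dataclass(frozen=True)
class GeneModel:
    """Gene with a strand-dependent TSS: body start on '+', body end - 1 on '-'."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValidationError(f"gene {self.gene_id}: invalid body interval")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, name=self.gene_id, strand=self.strand)


# ---------------------------------------------------------------------------
# I/O


def read_bed(path, genome: GenomeLayout | None = None, label: str | None = None) -> RegionSet:
    """Parse BED3/BED6 into a RegionSet, preserving record order.

    Raises :class:`BedParseError` naming the offending line, or
    :class:`ValidationError` for out-of-bounds coordinates.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: expected >=3 tab-separated fields")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(f"{path}: line {lineno}: non-integer coordinates") from None
            name = fields[3] if len(fields) >= 4 else None
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, name=name, strand=strand))
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from None
    return RegionSet(intervals, label=label or str(path), genome=genome)


def write_bed(regions: RegionSet, path) -> None:
    """Write canonical BED3, or BED6 when any interval carries a name/strand."""
    six = any(iv.name is not None or iv.strand != "." for iv in regions)
    with open(path, "w") as fh:
        for iv in regions:
            if six:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_gene_table(path, genome: GenomeLayout | None = None) -> list[GeneModel]:
    """Gene table TSV: gene_id, chrom, start, end, strand (0-based half-open)."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise BedParseError(f"{path}: line {lineno}: expected 5 fields")
            gid = fields[0]
            if gid in seen:
                raise ValidationError(f"{path}: line {lineno}: duplicate gene_id {gid!r}")
            seen.add(gid)
            gene = GeneModel(gid, fields[1], int(fields[2]), int(fields[3]), fields[4])
            if genome is not None and gene.end > genome.size(gene.chrom):
                raise ValidationError(f"{path}: line {lineno}: gene {gid} out of bounds")
            genes.append(gene)
    return genes


def write_gene_table(genes, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\n")


# ---------------------------------------------------------------------------
# Interval arithmetic


def _sorted_arrays(regions: RegionSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for chrom, ivs in regions.by_chrom().items():
        ivs = sorted(ivs, key=lambda iv: (iv.start, iv.end))
        out[chrom] = (
            np.array([iv.start for iv in ivs], dtype=np.int64),
            np.array([iv.end for iv in ivs], dtype=np.int64),
        )
    return out


def _max_overlap_with_any(iv: GenomicInterval, arrs) -> int:
    """Largest single-interval overlap (bp) of `iv` with a sorted subject set."""
    if iv.chrom not in arrs:
        return 0
    starts, ends = arrs[iv.chrom]
    # candidates: subject intervals with start < iv.end and end > iv.start
    hi = int(np.searchsorted(starts, iv.end, side="left"))
    if hi == 0:
        return 0
    ov = np.minimum(ends[:hi], iv.end) - np.maximum(starts[:hi], iv.start)
    best = int(ov.max()) if hi else 0
    return max(best, 0)


def overlap_fraction(query: RegionSet, subject: RegionSet, min_bp: int = 1) -> float:
    """Fraction of query intervals overlapping >= min_bp with >= 1 subject interval.

    An empty query yields 0 by definition.
    """
    if min_bp < 1:
        raise ValidationError(f"min_bp must be >= 1, got {min_bp}")
    if len(query) == 0:
        return 0.0
    arrs = _sorted_arrays(subject)
    hits = sum(1 for iv in query if _max_overlap_with_any(iv, arrs) >= min_bp)
    return hits / len(query)


def venn_partition(sets: list[RegionSet]) -> dict[str, dict[tuple[bool, ...], int]]:
    """Exclusive membership-pattern counts for 2-4 region sets.

    Each interval of each set is assigned one boolean pattern: for every set
    in the input (including its own, always True), whether it overlaps that
    set by >= 1 bp.  Counts are reported per reference set, keyed by that
    set's label (or its index when labels collide), and sum to the set size.
    """
    if not (2 <= len(sets) <= 4):
        raise ValidationError(f"venn_partition supports 2-4 sets, got {len(sets)}")
    arrs = [_sorted_arrays(s) for s in sets]
    labels = []
    for i, s in enumerate(sets):
        lab = s.label or f"set{i}"
        labels.append(lab if lab not in labels else f"{lab}#{i}")
    result: dict[str, dict[tuple[bool, ...], int]] = {}
    for i, s in enumerate(sets):
        counts: dict[tuple[bool, ...], int] = {}
        for iv in s:
            pattern = tuple(
                True if j == i else _max_overlap_with_any(iv, arrs[j]) >= 1
                for j in range(len(sets))
            )
            counts[pattern] = counts.get(pattern, 0) + 1
        result[labels[i]] = counts
    return result


def union_merge(sets: list[RegionSet]) -> RegionSet:
    """Merge all intervals across sets; overlapping or book-ended intervals fuse.

    Output is sorted (genome chromosome order when available, else
    lexicographic) and pairwise disjoint.
    """
    genome = next((s.genome for s in sets if s.genome is not None), None)
    all_ivs = [iv for s in sets for iv in s]
    if not all_ivs:
        return RegionSet([], label="union", genome=genome)
    if genome is not None:
        order = {c: i for i, c in enumerate(genome.chrom_names)}
        all_ivs.sort(key=lambda iv: (order[iv.chrom], iv.start, iv.end))
    else:
        all_ivs.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = all_ivs[0].chrom, all_ivs[0].start, all_ivs[0].end
    for iv in all_ivs[1:]:
        if iv.chrom == cur_chrom and iv.start <= cur_end:  # book-ended merges too
            cur_end = max(cur_end, iv.end)
        else:
            merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return RegionSet(merged, label="union", genome=genome)


def distance_to_nearest_tss(region: GenomicInterval, genes) -> tuple[float, str | None]:
    """Distance (bp) from the region midpoint to the nearest TSS, and its gene.

    Ties break to the smaller TSS coordinate, then lexicographic gene_id.
    With no gene on the region's chromosome, returns (inf, None).
    """
    mid = region.midpoint
    best: tuple[float, int, str] | None = None
    for g in genes:
        if g.chrom != region.chrom:
            continue
        cand = (abs(mid - g.tss), g.tss, g.gene_id)
        if best is None or cand < best:
            best = cand
    if best is None:
        return (math.inf, None)
    return (best[0], best[2])
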