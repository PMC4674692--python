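"""Coverage tracks, region quantification, normalization and meta-profiles.

A :class:`SignalTrack` is a fixed-bin, per-chromosome non-negative coverage
vector for one condition (H3K27ac or DNase cuts).  Quantification pro-rates
partial bins linearly, so it is exactly additive over any partition of a
region.  Cross-condition comparability is by per-million library scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeLayout, GenomicInterval, RegionSet, ValidationError

__all__ = [
    "SignalTrack",
    "RegionActivityMatrix",
    "quantify",
    "build_activity_matrix",
    "normalize_library",
    "log_ratio",
    "meta_profile",
]


@dataclass
class SignalTrack:
    """Fixed-bin coverage for one condition; bins tile each chromosome."""

    condition: str
    bin_size: int
    data: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValidationError("bin_size must be positive")
        for chrom, vals in self.data.items():
            vals = np.asarray(vals, dtype=float)
            if not np.all(np.isfinite(vals)) or np.any(vals < 0):
                raise ValidationError(f"{self.condition}/{chrom}: values must be finite and >= 0")
            self.data[chrom] = vals

    def total(self) -> float:
        """Genome-wide sum of bin values (the library size proxy)."""
        return float(sum(v.sum() for v in self.data.values()))

    def extent(self, chrom: str) -> int:
        return len(self.data[chrom]) * self.bin_size

    @classmethod
    def zeros(cls, condition: str, genome: GenomeLayout, bin_size: int) -> "SignalTrack":
        data = {
            c: np.zeros(-(-s // bin_size), dtype=float) for c, s in genome.chrom_sizes.items()
        }
        return cls(condition, bin_size, data)

    @classmethod
    def from_bedgraph(cls, path, genome: GenomeLayout, bin_size: int, condition: str) -> "SignalTrack":
        """Read a fixed-bin 4-column bedGraph; absent bins are zero."""
        track = cls.zeros(condition, genome, bin_size)
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                f = line.split("\t")
                if len(f) < 4:
                    raise ValidationError(f"{path}: line {lineno}: expected 4 bedGraph columns")
                chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
                if start % bin_size != 0 or (end - start) > bin_size:
                    raise ValidationError(
                        f"{path}: line {lineno}: record not aligned to {bin_size}-bp bins"
                    )
                track.data[chrom][start // bin_size] = value
        return track

    def to_bedgraph(self, path) -> None:
        """Write all bins (zeros included) for deterministic byte-level output."""
        with open(path, "w") as fh:
            for chrom, vals in self.data.items():
                b = self.bin_size
                for i, v in enumerate(vals):
                    fh.write(f"{chrom}\t{i * b}\t{(i + 1) * b}\t{v:g}\n")


def quantify(track: SignalTrack, regions: RegionSet) -> np.ndarray:
    """Per-region signal: sum of bin values weighted by the fraction of each
    bin the region covers (partial bins pro-rated linearly)."""
    b = track.bin_size
    out = np.empty(len(regions), dtype=float)
    for i, iv in enumerate(regions):
        if iv.chrom not in track.data or iv.end > track.extent(iv.chrom):
            raise ValidationError(f"region {iv.key()} beyond track extent")
        vals = track.data[iv.chrom]
        first, last = iv.start // b, (iv.end - 1) // b
        if first == last:
            out[i] = vals[first] * (iv.end - iv.start) / b
            continue
        total = vals[first] * ((first + 1) * b - iv.start) / b
        total += vals[last] * (iv.end - last * b) / b
        if last - first > 1:
            total += vals[first + 1 : last].sum()
        out[i] = total
    return out


@dataclass
class RegionActivityMatrix:
    """Regions x conditions signal; raw and (optionally) per-million normalized."""

    region_ids: list[str]
    conditions: list[str]
    raw: np.ndarray
    normalized: np.ndarray | None = None
    norm_factors: dict[str, float] = field(default_factory=dict)
    normalization: str = "none"

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.shape != (len(self.region_ids), len(self.conditions)):
            raise ValidationError("raw matrix shape does not match regions x conditions")
        if np.any(self.raw < 0):
            raise ValidationError("raw signal must be >= 0")

    def col(self, condition: str, normalized: bool = True) -> np.ndarray:
        j = self.conditions.index(condition)
        mat = self.normalized if (normalized and self.normalized is not None) else self.raw
        return mat[:, j]

    def subset(self, region_ids: list[str]) -> "RegionActivityMatrix":
        index = {rid: i for i, rid in enumerate(self.region_ids)}
        rows = [index[r] for r in region_ids]
        return RegionActivityMatrix(
            list(region_ids),
            list(self.conditions),
            self.raw[rows],
            None if self.normalized is None else self.normalized[rows],
            dict(self.norm_factors),
            self.normalization,
        )

    def to_frame(self, normalized: bool = True) -> pd.DataFrame:
        mat = self.normalized if (normalized and self.normalized is not None) else self.raw
        return pd.DataFrame(mat, index=self.region_ids, columns=self.conditions)

    def to_tsv(self, path, normalized: bool = True) -> None:
        df = self.to_frame(normalized)
        df.index.name = "region"
        df.to_csv(path, sep="\t", float_format="%.6g")


def build_activity_matrix(tracks: list[SignalTrack], regions: RegionSet) -> RegionActivityMatrix:
    raw = np.column_stack([quantify(t, regions) for t in tracks])
    return RegionActivityMatrix(regions.keys(), [t.condition for t in tracks], raw)


def normalize_library(
    matrix: RegionActivityMatrix, genome_totals: dict[str, float]
) -> RegionActivityMatrix:
    """Per-million scaling: normalized = raw * 1e6 / genome-wide track total."""
    factors = {}
    cols = []
    for j, cond in enumerate(matrix.conditions):
        total = genome_totals[cond]
        if total <= 0:
            raise ValidationError(f"condition {cond}: zero library total")
        factors[cond] = 1e6 / total
        cols.append(matrix.raw[:, j] * factors[cond])
    out = RegionActivityMatrix(
        matrix.region_ids, matrix.conditions, matrix.raw, np.column_stack(cols), factors, "library"
    )
    return out


def log_ratio(
    matrix: RegionActivityMatrix, condition: str, reference: str, pseudocount: float = 1.0
) -> np.ndarray:
    """Per-region log2((x + c)/(r + c)) on the normalized scale."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    x = matrix.col(condition)
    r = matrix.col(reference)
    return np.log2((x + pseudocount) / (r + pseudocount))


def meta_profile(track: SignalTrack, regions: RegionSet, flank: int, n_points: int) -> np.ndarray:
    """Average signal profile over length-scaled +/-flank windows.

    Each region's `[start - flank, end + flank)` window is sampled at
    `n_points` equally spaced positions (bin value at the position's midpoint)
    and the profiles are averaged.  Linear in the track by construction.
    """
    if n_points < 3:
        raise ValidationError("n_points must be >= 3")
    if len(regions) == 0:
        raise ValidationError("meta_profile needs a non-empty region set")
    b = track.bin_size
    acc = np.zeros(n_points, dtype=float)
    for iv in regions:
        w_start = iv.start - flank
        w_len = len(iv) + 2 * flank
        vals = track.data[iv.chrom]
        pos = w_start + (np.arange(n_points) + 0.5) * (w_len / n_points)
        bins = np.clip((pos // b).astype(int), 0, len(vals) - 1)
        acc += vals[bins]
    return acc / len(regions)
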