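"""DNase footprint occupancy scoring, PWM scanning, and motif enrichment.

A footprint is a short window of locally depleted DNase cuts inside
accessible chromatin; its occupancy score is the flank/center cut-density
ratio with +1 pseudocounts, so an unoccupied (uniform) window scores 1 and
deeper central depletion scores higher.  The top-scoring footprints per
condition are scanned with known position-weight matrices (log2-odds
against a uniform background) and motif frequencies between two conditions
are compared with Pearson's chi-squared test on the 2x2 table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2_contingency

from .genome import GenomicInterval, RegionSet, ValidationError
from .signal import SignalTrack, quantify

__all__ = [
    "Footprint",
    "PWM",
    "MotifEnrichmentResult",
    "sliding_candidates",
    "score_footprints",
    "top_footprints",
    "pwm_scan",
    "motif_enrichment_chisq",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass
class Footprint:
    interval: GenomicInterval  # the center window
    center: int  # center width, bp
    flank: int  # flank width per side, bp
    score: float  # (mean flank cuts + 1) / (mean center cuts + 1)
    condition: str


def sliding_candidates(
    accessible: RegionSet, center: int = 20, flank: int = 50, stride: int | None = None
) -> RegionSet:
    """Candidate footprint windows: a sliding window of width `center`
    (stride defaults to the center width) over accessible regions, keeping
    only windows whose flanks fit inside the accessible region."""
    stride = stride or center
    out = []
    for iv in accessible:
        start = iv.start + flank
        while start + center + flank <= iv.end:
            out.append(GenomicInterval(iv.chrom, start, start + center))
            start += stride
    return RegionSet(out, label="footprint_candidates", genome=accessible.genome)


def score_footprints(
    cut_track: SignalTrack, candidates: RegionSet, center: int = 20, flank: int = 50
) -> list[Footprint]:
    """Occupancy score per candidate: flanks are `flank` bp on each side just
    outside the central `center` bp of the candidate."""
    if center <= 0 or flank <= 0:
        raise ValidationError("center and flank must be positive")
    out = []
    for iv in candidates:
        if len(iv) < center:
            raise ValidationError(f"candidate {iv.key()} narrower than center={center}")
        mid = iv.midpoint
        c_start = mid - center // 2
        c_iv = GenomicInterval(iv.chrom, c_start, c_start + center)
        l_iv = GenomicInterval(iv.chrom, c_start - flank, c_start)
        r_iv = GenomicInterval(iv.chrom, c_start + center, c_start + center + flank)
        windows = RegionSet([c_iv, l_iv, r_iv])
        sums = quantify(cut_track, windows)
        center_density = sums[0] / center
        flank_density = (sums[1] + sums[2]) / (2 * flank)
        score = (flank_density + 1.0) / (center_density + 1.0)
        out.append(Footprint(iv, center, flank, float(score), cut_track.condition))
    return out


def top_footprints(footprints: list[Footprint], n: int = 5000) -> list[Footprint]:
    """The n highest-scoring footprints (all, if fewer), ties broken by
    genomic order; deterministic."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    ordered = sorted(
        footprints,
        key=lambda f: (-f.score, f.interval.chrom, f.interval.start, f.interval.end),
    )
    return ordered[:n]


@dataclass
class PWM:
    """Base-probability matrix, rows A,C,G,T x L columns (each summing to 1)."""

    name: str
    probs: np.ndarray  # shape (4, L)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape[0] != 4 or self.probs.shape[1] < 4:
            raise ValidationError("PWM must be 4 x L with L >= 4")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValidationError("PWM columns must each sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[1]

    @classmethod
    def from_consensus(cls, consensus: str, pseudo: float, name: str = "motif") -> "PWM":
        """Columns carrying 1 - 3*pseudo on the consensus base, pseudo elsewhere."""
        if not (0 < pseudo < 1 / 3):
            raise ValidationError("pseudo must be in (0, 1/3)")
        consensus = consensus.upper()
        if len(consensus) < 4 or any(b not in _BASE_INDEX for b in consensus):
            raise ValidationError("consensus must be >= 4 bases over ACGT")
        probs = np.full((4, len(consensus)), pseudo)
        for j, b in enumerate(consensus):
            probs[_BASE_INDEX[b], j] = 1 - 3 * pseudo
        return cls(name, probs)

    @classmethod
    def read(cls, path) -> "PWM":
        name = "motif"
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    name = line[1:].strip() or name
                    continue
                rows.append([float(x) for x in line.split("\t")])
        if len(rows) != 4:
            raise ValidationError(f"{path}: expected 4 probability rows (A,C,G,T)")
        return cls(name, np.array(rows))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#{self.name}\n")
            for row in self.probs:
                fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")

    def log_odds(self, background: float = 0.25) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.probs / background)


def _scan_strand(seq: str, lod: np.ndarray, threshold: float):
    """Yield (offset, score) for windows scoring >= threshold; ambiguous
    bases contribute -inf."""
    L = lod.shape[1]
    idx = np.array([_BASE_INDEX.get(b, -1) for b in seq.upper()], dtype=int)
    for off in range(len(seq) - L + 1):
        window = idx[off : off + L]
        if np.any(window < 0):
            continue
        score = float(lod[window, np.arange(L)].sum())
        if score >= threshold:
            yield off, score


def pwm_scan(
    sequences: dict[str, str] | "object",
    regions: RegionSet,
    pwm: PWM,
    threshold: float = 6.0,
) -> list[tuple[str, int, str, float]]:
    """Scan both strands of each region for PWM matches >= threshold bits.

    `sequences` maps chromosome to sequence (a dict or a pyfaidx.Fasta).
    Matches are (chrom, genomic start of the motif window on the forward
    strand, strand, log2-odds bits); overlapping matches are all reported.
    """
    lod = pwm.log_odds()
    L = len(pwm)
    matches = []
    for iv in regions:
        seq = str(sequences[iv.chrom][iv.start : iv.end])
        for off, score in _scan_strand(seq, lod, threshold):
            matches.append((iv.chrom, iv.start + off, "+", score))
        rc = seq.translate(_COMPLEMENT)[::-1]
        for off, score in _scan_strand(rc, lod, threshold):
            # map the reverse-strand window back to forward coordinates
            fwd_start = iv.end - off - L
            matches.append((iv.chrom, fwd_start, "-", score))
    matches.sort(key=lambda m: (m[0], m[1], m[2]))
    return matches


def write_matches_bed(matches, path, motif_len: int, name: str = "motif") -> None:
    """Matches as BED6; score column is bits x 100, rounded."""
    with open(path, "w") as fh:
        for chrom, start, strand, score in matches:
            fh.write(f"{chrom}\t{start}\t{start + motif_len}\t{name}\t{round(score * 100)}\t{strand}\n")


@dataclass
class MotifEnrichmentResult:
    table: np.ndarray  # 2x2: rows = condition A/B, cols = present/absent
    chi2: float
    p_value: float
    percent_a: float
    percent_b: float


def motif_enrichment_chisq(
    counts_a: tuple[int, int], counts_b: tuple[int, int]
) -> MotifEnrichmentResult:
    """Pearson chi-squared (no continuity correction, 1 df) on the 2x2
    present/absent x condition table, with per-condition motif percentages."""
    table = np.array([counts_a, counts_b], dtype=float)
    if np.any(table < 0):
        raise ValidationError("counts must be >= 0")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValidationError("zero marginal: expected counts undefined")
    chi2, p, _, _ = chi2_contingency(table, correction=False)
    pa = 100.0 * counts_a[0] / (counts_a[0] + counts_a[1])
    pb = 100.0 * counts_b[0] / (counts_b[0] + counts_b[1])
    return MotifEnrichmentResult(table, float(chi2), float(p), pa, pb)
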