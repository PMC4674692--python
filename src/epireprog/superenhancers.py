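"""Super-enhancer calling: stitch, rank, elbow cutoff, catalogue, valleys.

Constituent enhancer peaks within a stitching distance of one another are
fused into stitched enhancers (optionally dropping TSS-proximal peaks
first), ranked by aggregate signal, and the rank curve's elbow — the point
of maximal vertical gap below the diagonal of the doubly-scaled ascending
curve, equivalent to the slope-1 tangent for convex curves — separates
super-enhancers from typical enhancers.  Per-condition SE calls merge into
a cross-condition catalogue that is clustered by co-variation, and each
SE's internal peak-valley-peak structure is decomposed for motif scanning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GeneModel, GenomicInterval, RegionSet, ValidationError, union_merge
from .signal import RegionActivityMatrix, SignalTrack, build_activity_matrix, normalize_library, quantify

__all__ = [
    "StitchedEnhancer",
    "SuperEnhancerCatalogue",
    "Valley",
    "stitch",
    "rank_and_cut",
    "build_catalogue",
    "cluster_catalogue",
    "peak_valley_decompose",
]


@dataclass
class StitchedEnhancer:
    interval: GenomicInterval
    constituents: list[GenomicInterval]
    signal: float = 0.0
    rank: int | None = None  # ascending-signal rank, 0-based
    is_se: bool = False


def stitch(
    peaks: RegionSet,
    stitch_bp: int = 12500,
    tss_exclude: list[GeneModel] | None = None,
    tss_window: int = 2500,
) -> list[StitchedEnhancer]:
    """Transitively merge peaks whose gap (next.start - prev.end) <= stitch_bp.

    When gene models are supplied, peaks fully contained within +/-tss_window
    of any TSS are removed before stitching.  The stitched span runs from the
    first constituent's start to the last constituent's end.
    """
    if stitch_bp < 0:
        raise ValidationError("stitch_bp must be >= 0")
    kept = list(peaks)
    if tss_exclude:
        tss_by_chrom: dict[str, np.ndarray] = {}
        for g in tss_exclude:
            tss_by_chrom.setdefault(g.chrom, []).append(g.tss)
        tss_by_chrom = {c: np.array(sorted(v)) for c, v in tss_by_chrom.items()}

        def near_tss(iv: GenomicInterval) -> bool:
            tss = tss_by_chrom.get(iv.chrom)
            if tss is None:
                return False
            # fully contained in [tss - w, tss + w]
            lo = np.searchsorted(tss, iv.start)  # tss >= start candidates
            cands = tss[max(0, lo - 1) : lo + 1]
            for t in np.concatenate([cands, tss[lo : lo + 1]]):
                if iv.start >= t - tss_window and iv.end <= t + tss_window:
                    return True
            return False

        kept = [iv for iv in kept if not near_tss(iv)]
    kept.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[StitchedEnhancer] = []
    group: list[GenomicInterval] = []
    group_end = -1
    for iv in kept:
        if group and iv.chrom == group[-1].chrom and iv.start - group_end <= stitch_bp:
            group.append(iv)
            group_end = max(group_end, iv.end)
        else:
            if group:
                out.append(_finish_group(group))
            group = [iv]
            group_end = iv.end
    if group:
        out.append(_finish_group(group))
    return out


def _finish_group(group: list[GenomicInterval]) -> StitchedEnhancer:
    start = min(g.start for g in group)
    end = max(g.end for g in group)
    return StitchedEnhancer(GenomicInterval(group[0].chrom, start, end), list(group))


def rank_and_cut(
    stitched: list[StitchedEnhancer], track: SignalTrack
) -> tuple[list[StitchedEnhancer], int]:
    """Rank stitched enhancers by aggregate signal and cut at the elbow.

    Signals are sorted ascending; rank and signal are each min-max scaled to
    [0, 1]; the elbow is the index maximizing (scaled_rank - scaled_signal),
    ties to the largest index (fewer SEs).  Entries strictly above the elbow
    index are super-enhancers; a curve never below the diagonal yields none.
    Returns the ascending-ranked list and the elbow index.
    """
    if len(stitched) < 3:
        raise ValidationError("rank_and_cut needs >= 3 stitched enhancers")
    spans = RegionSet([s.interval for s in stitched])
    signals = quantify(track, spans)
    order = np.argsort(signals, kind="stable")
    ranked = [stitched[i] for i in order]
    sig = signals[order]
    n = len(ranked)
    scaled_rank = np.arange(n) / (n - 1)
    rng = sig[-1] - sig[0]
    scaled_sig = (sig - sig[0]) / rng if rng > 0 else np.zeros(n)
    gap = scaled_rank - scaled_sig
    best = float(gap.max())
    if best <= 0:
        elbow = n - 1  # nothing above: zero SEs
    else:
        elbow = int(np.flatnonzero(gap == best)[-1])
    for i, s in enumerate(ranked):
        s.signal = float(sig[i])
        s.rank = i
        s.is_se = best > 0 and i > elbow
    return ranked, elbow


@dataclass
class SuperEnhancerCatalogue:
    regions: RegionSet  # merged SE intervals, disjoint
    matrix: RegionActivityMatrix  # per-condition normalized aggregate signal
    membership: np.ndarray  # regions x conditions bool: is_SE in that condition
    cluster_labels: np.ndarray | None = None


def build_catalogue(
    se_calls: dict[str, RegionSet], tracks: list[SignalTrack]
) -> SuperEnhancerCatalogue:
    """Union-merge per-condition SE intervals and quantify each condition's
    normalized aggregate signal over the merged catalogue."""
    nonempty = [s for s in se_calls.values() if len(s) > 0]
    if not nonempty:
        raise ValidationError("all conditions are SE-free; no catalogue to build")
    merged = union_merge(list(se_calls.values()))
    matrix = build_activity_matrix(tracks, merged)
    matrix = normalize_library(matrix, {t.condition: t.total() for t in tracks})
    from .genome import overlap_fraction  # local import avoids cycle at module load

    membership = np.zeros((len(merged), len(tracks)), dtype=bool)
    for j, t in enumerate(tracks):
        calls = se_calls.get(t.condition)
        if calls is None or len(calls) == 0:
            continue
        for i, iv in enumerate(merged):
            membership[i, j] = overlap_fraction(RegionSet([iv]), calls) > 0
    return SuperEnhancerCatalogue(merged, matrix, membership)


def cluster_catalogue(catalogue: SuperEnhancerCatalogue, k: int = 10, seed: int = 0):
    """Co-variation clustering of the SE catalogue (same contract as the
    enhancer-region clustering)."""
    from .clusters import cluster_covariation

    assignments = cluster_covariation(catalogue.matrix, k=k, seed=seed)
    catalogue.cluster_labels = np.array([a.cluster for a in assignments])
    return assignments


@dataclass
class Valley:
    parent_id: str
    interval: GenomicInterval
    left_summit: tuple[int, float] = field(default=(0, 0.0))  # (genomic pos, height)
    right_summit: tuple[int, float] = field(default=(0, 0.0))


def _find_summits(vals: np.ndarray) -> list[int]:
    """Indices of local maxima; a plateau (run of equal values above both
    flanks) counts once, at its centre bin.  Array ends flank with -inf."""
    n = len(vals)
    summits = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and vals[j + 1] == vals[i]:
            j += 1
        left = vals[i - 1] if i > 0 else -np.inf
        right = vals[j + 1] if j + 1 < n else -np.inf
        if vals[i] > left and vals[i] > right:
            summits.append((i + j) // 2)
        i = j + 1
    return summits


def peak_valley_decompose(
    se: StitchedEnhancer,
    track: SignalTrack,
    min_summit_frac: float = 0.25,
    v_frac: float = 0.5,
) -> list[Valley]:
    """Valleys between adjacent summits of an SE's binned profile.

    Summits are local maxima >= min_summit_frac x the SE maximum; for each
    adjacent summit pair, if the interior minimum falls below v_frac x the
    lower summit, the valley is the maximal run of interior bins below that
    threshold containing the minimum.  An SE with < 2 summits has none.
    """
    b = track.bin_size
    iv = se.interval
    first, last = iv.start // b, (iv.end - 1) // b
    vals = track.data[iv.chrom][first : last + 1]
    if len(vals) == 0 or vals.max() <= 0:
        return []
    summits = [s for s in _find_summits(vals) if vals[s] >= min_summit_frac * vals.max()]
    valleys: list[Valley] = []
    parent = se.interval.key()
    for a, c in zip(summits, summits[1:]):
        interior = vals[a + 1 : c]
        if len(interior) == 0:
            continue
        thr = v_frac * min(vals[a], vals[c])
        lowest = int(np.argmin(interior)) + a + 1
        if vals[lowest] >= thr:
            continue
        lo = hi = lowest
        while lo - 1 > a and vals[lo - 1] < thr:
            lo -= 1
        while hi + 1 < c and vals[hi + 1] < thr:
            hi += 1
        g_start = iv.start // b * b + lo * b
        valleys.append(
            Valley(
                parent,
                GenomicInterval(iv.chrom, g_start, g_start + (hi - lo + 1) * b),
                (first * b + a * b, float(vals[a])),
                (first * b + c * b, float(vals[c])),
            )
        )
    return valleys
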