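"""TAD-level acetylation ratios and gene-local vs domain-global decomposition.

Topologically associating domains are treated as fixed, disjoint intervals.
Each TAD's aggregate normalized H3K27ac is compared between a condition and
the reference as a pseudocounted linear ratio; TADs are ranked by descending
ratio with percentiles (0 = highest).  A gene's local regulatory change
(log2 ratio over its associated regions) is then set against its host TAD's
global change and classified: genes riding a domain-wide shift are
concordant passengers, genes moving while their TAD does not are punctuated,
and genes moving against their TAD are punctuated-opposed — the pattern of
rate-limiting cholesterol genes gaining acetylation inside TADs that lose it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genome import GeneModel, GenomicInterval, RegionSet, ValidationError
from .signal import SignalTrack, quantify

__all__ = ["TADRecord", "GeneDecomposition", "tad_aggregate", "rank_tads", "decompose_gene"]


@dataclass
class TADRecord:
    interval: GenomicInterval
    aggregates: dict[str, float]  # per-condition normalized aggregate signal
    ratio: float  # (condition + c) / (reference + c), linear
    rank: int | None = None  # 1 = highest ratio
    percentile: float | None = None  # 100 * (rank - 1) / N
    top5: bool | None = None


def tad_aggregate(
    tracks: list[SignalTrack],
    tads: RegionSet,
    condition: str,
    reference: str,
    min_signal_per_kb: float = 1.0,
    pseudocount: float = 1.0,
) -> list[TADRecord]:
    """Per-TAD library-normalized aggregate signal and cross-condition ratio.

    TADs must be disjoint.  A TAD is kept only if its aggregate reaches
    min_signal_per_kb (normalized units per kb) in at least one condition —
    the "showing acetylation in at least one line" filter.
    """
    sorted_tads = tads.sorted()
    prev = None
    for iv in sorted_tads:
        if prev is not None and iv.chrom == prev.chrom and iv.start < prev.end:
            raise ValidationError(f"overlapping TADs: {prev.key()} and {iv.key()}")
        prev = iv
    totals = {t.condition: t.total() for t in tracks}
    per_cond = {}
    for t in tracks:
        if totals[t.condition] <= 0:
            raise ValidationError(f"condition {t.condition}: zero library total")
        per_cond[t.condition] = quantify(t, sorted_tads) * 1e6 / totals[t.condition]
    records = []
    for i, iv in enumerate(sorted_tads):
        aggs = {c: float(v[i]) for c, v in per_cond.items()}
        per_kb_max = max(a / (len(iv) / 1000.0) for a in aggs.values())
        if per_kb_max < min_signal_per_kb:
            continue
        ratio = (aggs[condition] + pseudocount) / (aggs[reference] + pseudocount)
        records.append(TADRecord(iv, aggs, ratio))
    return records


def rank_tads(records: list[TADRecord]) -> list[TADRecord]:
    """Sort by descending ratio (ties stable by coordinate); rank 1 = highest;
    percentile = 100 * (rank - 1) / N; top-5% flag iff percentile < 5."""
    if not records:
        raise ValidationError("rank_tads needs >= 1 record")
    ordered = sorted(
        records, key=lambda r: (-r.ratio, r.interval.chrom, r.interval.start, r.interval.end)
    )
    n = len(ordered)
    for i, r in enumerate(ordered):
        r.rank = i + 1
        r.percentile = 100.0 * i / n
        r.top5 = r.percentile < 5.0
    return ordered


CLASSES = ("neutral", "concordant_passenger", "punctuated_amplified", "punctuated_opposed")


@dataclass
class GeneDecomposition:
    gene_id: str
    local_log2: float  # gene-associated regions
    global_log2: float  # host TAD
    klass: str
    warning: str | None = None


def _log2_ratio_over_regions(
    regions: RegionSet,
    track_x: SignalTrack,
    track_r: SignalTrack,
    totals: dict[str, float],
    pseudocount: float,
) -> float:
    x = quantify(track_x, regions).sum() * 1e6 / totals[track_x.condition]
    r = quantify(track_r, regions).sum() * 1e6 / totals[track_r.condition]
    return math.log2((x + pseudocount) / (r + pseudocount))


def decompose_gene(
    gene: GeneModel,
    local_regions: RegionSet,
    tad_records: list[TADRecord],
    tracks: list[SignalTrack],
    condition: str,
    reference: str,
    tau: float = math.log2(1.2),
    pseudocount: float = 1.0,
) -> GeneDecomposition:
    """Classify a gene by its local vs TAD-global log2 acetylation change.

    |local| <= tau -> neutral; |local| > tau with |global| <= tau ->
    punctuated_amplified; both above tau -> concordant_passenger when the
    signs agree, punctuated_opposed when they oppose.  A gene whose TSS is
    not inside exactly one kept TAD is neutral with a warning.
    """
    if len(local_regions) == 0:
        raise ValidationError(f"gene {gene.gene_id}: no associated regions")
    track_x = next(t for t in tracks if t.condition == condition)
    track_r = next(t for t in tracks if t.condition == reference)
    totals = {t.condition: t.total() for t in tracks}
    local = _log2_ratio_over_regions(local_regions, track_x, track_r, totals, pseudocount)

    hosts = [
        r for r in tad_records
        if r.interval.chrom == gene.chrom and r.interval.start <= gene.tss < r.interval.end
    ]
    if len(hosts) != 1:
        return GeneDecomposition(
            gene.gene_id, local, float("nan"), "neutral",
            warning=f"TSS inside {len(hosts)} TADs; expected exactly 1",
        )
    glob = math.log2(hosts[0].ratio)

    if abs(local) <= tau:
        klass = "neutral"
    elif abs(glob) <= tau:
        klass = "punctuated_amplified"
    elif (local > 0) == (glob > 0):
        klass = "concordant_passenger"
    else:
        klass = "punctuated_opposed"
    return GeneDecomposition(gene.gene_id, local, glob, klass)
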