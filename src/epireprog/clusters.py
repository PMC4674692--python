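"""Differential acetylation, co-variation clustering, and expression coupling.

The core discovery procedure: call per-condition differential H3K27ac
against the parental reference with an exact conditional binomial test,
pool every region that moves in at least one derived line, cluster the
pooled regions by the shape of their cross-condition profile (k-means on
per-region standardized log signal), deconvolute clusters into TSS-proximal
and TSS-distal elements, attach nearest genes to proximal elements,
summarize each cluster's expression as the median linear FPKM, and extract
top-decile up-regulation signatures per condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .genome import GeneModel, ValidationError, distance_to_nearest_tss
from .signal import RegionActivityMatrix

__all__ = [
    "DifferentialCall",
    "ClusterAssignment",
    "SignatureSet",
    "call_differential",
    "pool_dynamic",
    "cluster_covariation",
    "silhouette_scan",
    "split_proximal_distal",
    "assign_genes",
    "cluster_expression_summary",
    "extract_signature",
    "score_signature",
]

FLAT_CLUSTER = 0  # reserved label for zero-variance profiles excluded from k-means


@dataclass
class DifferentialCall:
    region_id: str
    condition: str
    direction: str  # "up" | "down" | "none"
    fold_change: float  # linear, normalized scale
    p_value: float
    q_value: float


def call_differential(
    matrix: RegionActivityMatrix,
    condition: str,
    reference: str,
    alpha: float = 0.05,
    min_fc: float = 2.0,
    pseudocount: float = 1.0,
) -> list[DifferentialCall]:
    """Exact conditional binomial test of condition vs reference counts.

    Given the per-region count total n = x + r, x is Binomial(n, p0) under
    the null, with p0 the condition's share of the combined library.  The
    two-sided exact p-value is Benjamini-Hochberg corrected across regions;
    a region is called (direction != "none") only when q <= alpha AND the
    normalized fold change passes min_fc in either direction.
    """
    if not (0 < alpha < 1):
        raise ValidationError(f"alpha must be in (0,1), got {alpha}")
    if min_fc < 1:
        raise ValidationError(f"min_fc must be >= 1, got {min_fc}")
    jx = matrix.conditions.index(condition)
    jr = matrix.conditions.index(reference)
    x_raw = matrix.raw[:, jx]
    r_raw = matrix.raw[:, jr]
    lib_x = 1.0 / matrix.norm_factors[condition] if matrix.norm_factors else x_raw.sum()
    lib_r = 1.0 / matrix.norm_factors[reference] if matrix.norm_factors else r_raw.sum()
    p0 = lib_x / (lib_x + lib_r)

    xn = matrix.col(condition)
    rn = matrix.col(reference)
    fc = (xn + pseudocount) / (rn + pseudocount)

    pvals = np.ones(len(x_raw))
    for i in range(len(x_raw)):
        n = int(round(x_raw[i] + r_raw[i]))
        if n > 0:
            pvals[i] = binomtest(int(round(x_raw[i])), n, p0).pvalue
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")

    calls = []
    for i, rid in enumerate(matrix.region_ids):
        f = fc[i]
        passes = qvals[i] <= alpha and max(f, 1.0 / f) >= min_fc
        direction = "none"
        if passes:
            direction = "up" if f > 1 else "down"
        calls.append(DifferentialCall(rid, condition, direction, float(f), float(pvals[i]), float(qvals[i])))
    return calls


def pool_dynamic(
    calls_by_condition: dict[str, list[DifferentialCall]], matrix: RegionActivityMatrix
) -> tuple[list[str], RegionActivityMatrix]:
    """Regions with direction != none in >= 1 non-reference condition, deduplicated,
    in matrix row order; returns ids and the matching activity sub-matrix."""
    dynamic: set[str] = set()
    for calls in calls_by_condition.values():
        for c in calls:
            if c.direction != "none":
                dynamic.add(c.region_id)
    ids = [rid for rid in matrix.region_ids if rid in dynamic]
    return ids, matrix.subset(ids)


@dataclass
class ClusterAssignment:
    region_id: str
    cluster: int  # 1..k by descending size; 0 = reserved flat cluster
    profile: np.ndarray  # standardized per-condition z-values
    proximal: bool | None = None
    gene_id: str | None = None
    tss_distance: float | None = None


def _standardize_profiles(matrix: RegionActivityMatrix, pseudocount: float) -> tuple[np.ndarray, np.ndarray]:
    logp = np.log2(
        (matrix.normalized if matrix.normalized is not None else matrix.raw) + pseudocount
    )
    mean = logp.mean(axis=1, keepdims=True)
    sd = logp.std(axis=1, ddof=0, keepdims=True)
    flat = (sd[:, 0] == 0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (logp - mean) / sd_safe
    return z, flat


def cluster_covariation(
    matrix: RegionActivityMatrix, k: int = 13, seed: int = 0, n_restarts: int = 10,
    pseudocount: float = 1.0,
) -> list[ClusterAssignment]:
    """k-means on per-region standardized log2 profiles across conditions.

    Labels are renumbered 1..k by descending cluster size; constant
    (zero-variance) profiles go to the reserved flat cluster 0 and are
    excluded from k-means.  Deterministic given the seed.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    z, flat = _standardize_profiles(matrix, pseudocount)
    variable = np.where(~flat)[0]
    if len(variable) < k:
        raise ValidationError(f"fewer variable regions ({len(variable)}) than k={k}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw_labels = km.fit_predict(z[variable])
    # renumber by descending size; ties by original label for determinism
    sizes = np.bincount(raw_labels, minlength=k)
    order = sorted(range(k), key=lambda lab: (-sizes[lab], lab))
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = np.full(len(matrix.region_ids), FLAT_CLUSTER, dtype=int)
    labels[variable] = [remap[l] for l in raw_labels]
    return [
        ClusterAssignment(rid, int(labels[i]), z[i])
        for i, rid in enumerate(matrix.region_ids)
    ]


def silhouette_scan(
    matrix: RegionActivityMatrix, k_values, seed: int = 0, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Silhouette score per candidate k — a report to aid choosing k, not an
    automatic selector."""
    z, flat = _standardize_profiles(matrix, pseudocount)
    zv = z[~flat]
    rows = []
    for k in k_values:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(zv)
        rows.append({"k": k, "silhouette": silhouette_score(zv, labels)})
    return pd.DataFrame(rows)


def split_proximal_distal(
    assignments: list[ClusterAssignment],
    regions_by_id: dict[str, "object"],
    genes: list[GeneModel],
    threshold: int = 2500,
) -> list[ClusterAssignment]:
    """Flag each region proximal iff its midpoint-to-nearest-TSS distance is
    <= threshold (inclusive); regions on gene-free chromosomes are distal."""
    for a in assignments:
        dist, gid = distance_to_nearest_tss(regions_by_id[a.region_id], genes)
        a.tss_distance = dist
        a.proximal = dist <= threshold
        a.gene_id = gid if a.proximal else None
    return assignments


def assign_genes(
    assignments: list[ClusterAssignment],
    regions_by_id: dict[str, "object"],
    genes: list[GeneModel],
) -> list[ClusterAssignment]:
    """Attach the nearest-TSS gene to each proximal region (tie rule: smaller
    TSS coordinate, then gene_id); distal regions carry no gene."""
    for a in assignments:
        if a.proximal is None:
            raise ValidationError("run split_proximal_distal before assign_genes")
        if a.proximal:
            _, a.gene_id = distance_to_nearest_tss(regions_by_id[a.region_id], genes)
        else:
            a.gene_id = None
    return assignments


def cluster_proportions(assignments: list[ClusterAssignment]) -> pd.DataFrame:
    """Per-cluster proximal/distal counts and fractions."""
    rows: dict[int, dict[str, int]] = {}
    for a in assignments:
        d = rows.setdefault(a.cluster, {"proximal": 0, "distal": 0})
        d["proximal" if a.proximal else "distal"] += 1
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out["fraction_proximal"] = out["proximal"] / (out["proximal"] + out["distal"])
    out.index.name = "cluster"
    return out


def cluster_expression_summary(
    assignments: list[ClusterAssignment], expression: pd.DataFrame
) -> pd.DataFrame:
    """Median linear FPKM per cluster per condition, over the distinct genes
    assigned within each cluster; clusters with no assigned genes are absent."""
    genes_per_cluster: dict[int, set[str]] = {}
    for a in assignments:
        if a.gene_id is not None and a.gene_id in expression.index:
            genes_per_cluster.setdefault(a.cluster, set()).add(a.gene_id)
    rows = {}
    for cluster, genes in sorted(genes_per_cluster.items()):
        rows[cluster] = expression.loc[sorted(genes)].median(axis=0)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "cluster"
    return out


@dataclass
class SignatureSet:
    condition: str
    genes: list[str]  # ordered by descending selection statistic
    statistic: dict[str, float]  # gene -> log2 fold change


def extract_signature(
    expression: pd.DataFrame,
    condition: str,
    reference: str,
    fraction: float = 0.10,
    pseudocount: float = 0.1,
) -> SignatureSet:
    """Top-`fraction` up-regulated genes of `condition` vs `reference`.

    Eligible genes have linear fold change > 1 (with an FPKM pseudocount);
    ranking is by descending log2 fold change, ties broken by gene_id, and
    the list size is ceil(fraction x eligible).
    """
    if not (0 < fraction <= 1):
        raise ValidationError(f"fraction must be in (0,1], got {fraction}")
    fc = (expression[condition] + pseudocount) / (expression[reference] + pseudocount)
    up = fc[fc > 1]
    n = math.ceil(fraction * len(up))
    log2fc = np.log2(up)
    ranked = sorted(up.index, key=lambda g: (-log2fc[g], g))[:n]
    return SignatureSet(condition, ranked, {g: float(log2fc[g]) for g in ranked})


def score_signature(
    signature: SignatureSet, expression: pd.DataFrame, pseudocount: float = 0.1
) -> pd.DataFrame:
    """Mean per-gene z-score (z over samples of log2 FPKM) per sample, with a
    high/low split at the median score (ties go low)."""
    if expression.shape[1] < 2:
        raise ValidationError("score_signature needs >= 2 samples")
    missing = [g for g in signature.genes if g not in expression.index]
    if missing:
        raise ValidationError(f"signature genes absent from table: {missing}")
    logv = np.log2(expression.loc[signature.genes] + pseudocount)
    mean = logv.mean(axis=1)
    sd = logv.std(axis=1, ddof=0).replace(0, 1.0)
    z = logv.sub(mean, axis=0).div(sd, axis=0)
    score = z.mean(axis=0)
    split = np.where(score > score.median(), "high", "low")
    return pd.DataFrame({"score": score, "group": split})
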