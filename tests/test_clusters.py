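import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom
from sklearn.metrics import adjusted_rand_score

from epireprog.clusters import (
    FLAT_CLUSTER,
    assign_genes,
    call_differential,
    cluster_covariation,
    cluster_expression_summary,
    extract_signature,
    pool_dynamic,
    score_signature,
    split_proximal_distal,
)
from epireprog.genome import GeneModel, GenomicInterval, ValidationError
from epireprog.signal import RegionActivityMatrix, normalize_library
from conftest import make_count_matrix


def make_profile_matrix(profiles, conditions=None):
    """Activity matrix whose normalized values are 2**profile, so clustering
    with a tiny pseudocount sees (a monotone image of) the planted profile."""
    profiles = np.asarray(profiles, dtype=float)
    conds = conditions or [f"c{j}" for j in range(profiles.shape[1])]
    ids = [f"chr1:{i * 1000}-{i * 1000 + 500}" for i in range(len(profiles))]
    vals = np.exp2(profiles)
    m = RegionActivityMatrix(ids, conds, vals)
    m.normalized = vals
    m.normalization = "library"
    return m


class TestCallDifferential:
    def test_matches_exact_binomial_doubling_oracle(self):
        m = make_count_matrix([400.0, 100.0], [100.0, 100.0])
        calls = call_differential(m, "cond", "ref")
        # equal libraries: two-sided exact p = 2 * P(Bin(500, .5) >= 400)
        oracle = min(1.0, 2 * binom.sf(399, 500, 0.5))
        assert calls[0].p_value == pytest.approx(oracle, rel=1e-9)
        assert calls[0].direction == "up"
        assert calls[0].fold_change == pytest.approx(401 / 101, rel=1e-12)
        assert calls[1].direction == "none"  # 100 vs 100: symmetric

    def test_unequal_libraries_shift_the_null(self):
        # condition library twice the reference: 200 vs 100 is expected, not a call
        m = make_count_matrix([200.0], [100.0], lib_x=2e6, lib_r=1e6)
        calls = call_differential(m, "cond", "ref")
        assert calls[0].direction == "none"
        assert calls[0].p_value > 0.5

    def test_null_calibration_poisson(self):
        rng = np.random.default_rng(42)
        n = 3000
        m = make_count_matrix(rng.poisson(100, n).astype(float), rng.poisson(100, n).astype(float))
        calls = call_differential(m, "cond", "ref", alpha=0.05, min_fc=2.0)
        frac = sum(c.direction != "none" for c in calls) / n
        assert frac <= 0.06

    def test_power_at_fourfold(self):
        rng = np.random.default_rng(43)
        n = 2000
        m = make_count_matrix(rng.poisson(400, n).astype(float), rng.poisson(100, n).astype(float))
        calls = call_differential(m, "cond", "ref")
        power = sum(c.direction == "up" for c in calls) / n
        assert power >= 0.9

    def test_alpha_validation(self):
        m = make_count_matrix([1.0], [1.0])
        with pytest.raises(ValidationError):
            call_differential(m, "cond", "ref", alpha=1.5)


class TestPoolDynamic:
    def _calls(self, matrix, conds):
        return {c: call_differential(matrix, c, "ref") for c in conds}

    def test_included_iff_dynamic_somewhere(self):
        raw = np.array([[400.0, 100.0, 100.0], [100.0, 100.0, 100.0]])
        m = RegionActivityMatrix(["chr1:0-500", "chr1:1000-1500"], ["a", "b", "ref"], raw)
        m = normalize_library(m, {"a": 1e6, "b": 1e6, "ref": 1e6})
        ids, sub = pool_dynamic(self._calls(m, ["a", "b"]), m)
        assert ids == ["chr1:0-500"]
        assert sub.raw.shape == (1, 3)

    def test_planted_recovery_and_monotonicity(self):
        rng = np.random.default_rng(7)
        n_dyn, n_static = 60, 940
        x = np.concatenate([rng.poisson(400, n_dyn), rng.poisson(100, n_static)]).astype(float)
        r = rng.poisson(100, n_dyn + n_static).astype(float)
        m = make_count_matrix(x, r)
        calls = {"cond": call_differential(m, "cond", "ref", alpha=0.05)}
        ids, _ = pool_dynamic(calls, m)
        assert abs(len(ids) - n_dyn) <= 8  # high-SNR planted recovery
        stricter = {"cond": call_differential(m, "cond", "ref", alpha=0.005)}
        ids2, _ = pool_dynamic(stricter, m)
        assert set(ids2) <= set(ids)  # lowering alpha never adds regions


class TestClusterCovariation:
    def test_identical_profiles_same_label_and_determinism(self):
        profiles = np.array([[1, 5, 1], [1, 5, 1], [5, 1, 5], [5, 1, 5.0]])
        m = make_profile_matrix(profiles)
        a1 = cluster_covariation(m, k=2, seed=0)
        a2 = cluster_covariation(m, k=2, seed=0)
        assert [x.cluster for x in a1] == [x.cluster for x in a2]
        assert a1[0].cluster == a1[1].cluster != a1[2].cluster == a1[3].cluster

    def test_flat_profiles_reserved_cluster(self):
        profiles = np.array([[2, 2, 2], [1, 9, 1], [9, 1, 9.0], [1, 5, 9.0]])
        a = cluster_covariation(make_profile_matrix(profiles), k=2, seed=0)
        assert a[0].cluster == FLAT_CLUSTER
        assert all(x.cluster != FLAT_CLUSTER for x in a[1:])
        z = a[1].profile
        assert z.mean() == pytest.approx(0, abs=1e-9)
        assert z.std() == pytest.approx(1, abs=1e-9)

    @pytest.mark.parametrize("sd,k,min_ari", [(0.05, 3, 1.0), (0.3, 13, 0.9)])
    def test_planted_pattern_recovery(self, sd, k, min_ari):
        rng = np.random.default_rng(1234)
        n_per = 200
        base_patterns = rng.normal(0, 1, size=(k, 6)) * 2
        truth, rows = [], []
        for i, p in enumerate(base_patterns):
            truth += [i] * n_per
            rows.append(p + rng.normal(0, sd, size=(n_per, 6)))
        m = make_profile_matrix(np.vstack(rows))
        labels = [a.cluster for a in cluster_covariation(m, k=k, seed=0, pseudocount=1e-9)]
        assert adjusted_rand_score(truth, labels) >= min_ari

    def test_too_few_regions_error(self):
        m = make_profile_matrix(np.array([[1, 2, 3], [3, 2, 1.0]]))
        with pytest.raises(ValidationError):
            cluster_covariation(m, k=5)

    def test_labels_ordered_by_descending_size(self):
        rng = np.random.default_rng(5)
        big = np.tile([0.0, 4.0, 0.0], (30, 1)) + rng.normal(0, 0.05, (30, 3))
        small = np.tile([4.0, 0.0, 4.0], (5, 1)) + rng.normal(0, 0.05, (5, 3))
        a = cluster_covariation(make_profile_matrix(np.vstack([big, small])), k=2, seed=0, pseudocount=1e-9)
        labels = np.array([x.cluster for x in a])
        assert (labels[:30] == 1).all() and (labels[30:] == 2).all()


GENES = [
    GeneModel("g1", "chr1", 10_000, 12_000, "+"),
    GeneModel("g2", "chr1", 40_000, 42_000, "+"),
]


def _assignments_for(region_pairs, k=2):
    ids = [f"chr1:{s}-{e}" for s, e in region_pairs]
    prof = np.column_stack([np.arange(len(ids)), np.zeros(len(ids)), np.ones(len(ids))]) + 1.0
    m = make_profile_matrix(prof)
    m.region_ids = ids
    a = cluster_covariation(m, k=k, seed=0)
    regions = {f"chr1:{s}-{e}": GenomicInterval("chr1", s, e) for s, e in region_pairs}
    return a, regions


class TestProximalDistalAndGenes:
    def test_threshold_inclusive_boundary(self):
        # midpoints at 8500 (1500 bp), 12500 (exactly 2500 bp), 20000 (distal)
        pairs = [(8000, 9000), (12_000, 13_000), (19_500, 20_500)]
        a, regions = _assignments_for(pairs)
        a = split_proximal_distal(a, regions, GENES, threshold=2500)
        assert [x.proximal for x in a] == [True, True, False]

    def test_no_gene_chromosome_is_distal(self):
        a, regions = _assignments_for([(0, 1000), (2000, 3000), (4000, 5000)])
        for key, iv in list(regions.items()):
            regions[key] = GenomicInterval("chr9", iv.start, iv.end)
        a = split_proximal_distal(a, regions, GENES)
        assert all(x.proximal is False for x in a)

    def test_nearest_gene_wins(self):
        pairs = [(9_000, 10_000), (38_000, 39_000), (200_000, 201_000)]
        a, regions = _assignments_for(pairs)
        a = split_proximal_distal(a, regions, GENES)
        a = assign_genes(a, regions, GENES)
        assert a[0].gene_id == "g1"
        assert a[1].gene_id == "g2"
        assert a[2].gene_id is None  # distal: no gene

    def test_expression_summary_median_linear_fpkm(self):
        pairs = [(9_000, 10_000), (9_500, 10_500), (38_000, 39_000)]
        a, regions = _assignments_for(pairs)
        for x in a:
            x.cluster = 1
        a = split_proximal_distal(a, regions, GENES)
        a = assign_genes(a, regions, GENES)
        expr = pd.DataFrame({"s1": [1.0, 9.0], "s2": [2.0, 4.0]}, index=["g1", "g2"])
        med = cluster_expression_summary(a, expr)
        # distinct genes {g1, g2}: median of {1,9} and {2,4}
        assert med.loc[1, "s1"] == pytest.approx(5.0)
        assert med.loc[1, "s2"] == pytest.approx(3.0)


class TestSignatures:
    def _expr(self, n_up=100, n_down=50):
        rng = np.random.default_rng(0)
        genes = [f"g{i:04d}" for i in range(n_up + n_down)]
        ref = np.full(n_up + n_down, 10.0)
        cond = np.concatenate([np.linspace(20, 120, n_up), np.full(n_down, 5.0)])
        return pd.DataFrame({"cond": cond, "ref": ref}, index=genes)

    def test_top_decile_size(self):
        sig = extract_signature(self._expr(), "cond", "ref", fraction=0.10)
        assert len(sig.genes) == 10  # ceil(0.1 * 100 upregulated)
        assert len(set(sig.genes)) == 10

    def test_no_upregulated_genes_empty(self):
        expr = pd.DataFrame({"cond": [1.0, 2.0], "ref": [5.0, 6.0]}, index=["a", "b"])
        assert extract_signature(expr, "cond", "ref").genes == []

    def test_planted_strong_up_recovered(self):
        rng = np.random.default_rng(9)
        n = 1000
        ref = np.full(n, 10.0)
        cond = ref * np.exp(rng.normal(0, 0.05, n))
        cond[:20] = 200.0  # strongly up
        expr = pd.DataFrame({"cond": cond, "ref": ref},
                            index=[f"g{i:04d}" for i in range(n)])
        sig = extract_signature(expr, "cond", "ref", fraction=0.10)
        assert set(f"g{i:04d}" for i in range(20)) <= set(sig.genes)

    def test_row_order_invariance(self):
        expr = self._expr()
        shuffled = expr.sample(frac=1, random_state=1)
        assert extract_signature(expr, "cond", "ref").genes == \
            extract_signature(shuffled, "cond", "ref").genes

    def test_fraction_validation(self):
        with pytest.raises(ValidationError):
            extract_signature(self._expr(), "cond", "ref", fraction=0.0)

    def test_score_monotone_and_split(self):
        genes = [f"g{i}" for i in range(5)]
        rng = np.random.default_rng(2)
        base = rng.random((5, 4)) * 10
        expr = pd.DataFrame(base, index=genes, columns=["s1", "s2", "s3", "s4"])
        expr["s4"] = expr[["s1", "s2", "s3"]].max(axis=1) * 2  # uniformly higher
        from epireprog.clusters import SignatureSet

        sig = SignatureSet("cond", genes, {g: 1.0 for g in genes})
        scores = score_signature(sig, expr)
        assert scores.loc["s4", "score"] == scores["score"].max()
        assert scores.loc["s4", "group"] == "high"
        assert (scores["group"] == "low").sum() >= 2  # median split, ties low

    def test_missing_genes_listed(self):
        from epireprog.clusters import SignatureSet

        expr = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["known"])
        sig = SignatureSet("cond", ["known", "ghost"], {})
        with pytest.raises(ValidationError, match="ghost"):
            score_signature(sig, expr)
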