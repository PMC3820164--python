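import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from sigdriver import SubtypeAssignment
from sigdriver.io import ExpressionMatrix, GeneSet, ValidationError
from sigdriver.signature import detect_signature
from sigdriver.simulate import generate_subtype_testbed
from sigdriver.subtyping import (
    Dendrogram,
    build_dendrogram,
    cut_to_core_clusters,
    iterate_subtyping,
    merge_bad_clusters,
)


def three_cloud_matrix(seed=0, n_per=20, n_genes=50, shift=5.0):
    """3 well-separated Gaussian sample clouds, all-tumor."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n_genes, 3 * n_per))
    third = n_genes // 3
    x[:third, :n_per] += shift
    x[third : 2 * third, n_per : 2 * n_per] += shift
    x[2 * third :, 2 * n_per :] += shift
    genes = [f"g{i:02d}" for i in range(n_genes)]
    samples = [f"s{j:02d}" for j in range(3 * n_per)]
    truth = {samples[j]: j // n_per + 1 for j in range(3 * n_per)}
    return ExpressionMatrix(genes, samples, x, ["tumor"] * 3 * n_per), truth


def ari(labels, truth):
    samples = sorted(truth)
    return adjusted_rand_score(
        [truth[s] for s in samples], [labels.labels[s] for s in samples]
    )


class TestBuildDendrogramAndCut:
    def test_three_planted_clouds_recovered_exactly(self):
        expr, truth = three_cloud_matrix(seed=1)
        dendro = build_dendrogram(expr, GeneSet(set(expr.gene_ids)), embed_dims=3)
        labels = cut_to_core_clusters(dendro, 3)
        assert labels.K == 3
        assert ari(labels, truth) == 1.0

    def test_duplicate_samples_merge_at_zero_height(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(30, 5))
        x[:, 4] = x[:, 0]  # duplicate column
        expr = ExpressionMatrix(
            [f"g{i}" for i in range(30)], list("abcde"), x, ["tumor"] * 5
        )
        dendro = build_dendrogram(expr, GeneSet(set(expr.gene_ids)), embed_dims=2)
        assert dendro.merge_heights().min() == pytest.approx(0.0, abs=1e-12)

    def test_partition_invariant_to_sample_order(self):
        expr, truth = three_cloud_matrix(seed=2)
        rng = np.random.default_rng(0)
        perm = rng.permutation(expr.n_samples)
        shuffled = ExpressionMatrix(
            expr.gene_ids,
            [expr.sample_ids[j] for j in perm],
            expr.values[:, perm],
            ["tumor"] * expr.n_samples,
        )
        genes = GeneSet(set(expr.gene_ids))
        a = cut_to_core_clusters(build_dendrogram(expr, genes, 3), 3)
        b = cut_to_core_clusters(build_dendrogram(shuffled, genes, 3), 3)
        assert a.partition() == b.partition()

    def test_needs_three_tumors(self):
        x = np.ones((5, 2))
        expr = ExpressionMatrix([f"g{i}" for i in range(5)], ["a", "b"], x, ["tumor"] * 2)
        with pytest.raises(ValidationError, match="3 tumor"):
            build_dendrogram(expr, GeneSet(set(expr.gene_ids)), 2)

    def test_disjoint_gene_subset_rejected(self, small_matrix):
        with pytest.raises(ValidationError, match="disjoint"):
            build_dendrogram(small_matrix, GeneSet({"nope1", "nope2"}), 2)

    def test_k1_single_cluster(self):
        expr, _ = three_cloud_matrix(seed=3)
        dendro = build_dendrogram(expr, GeneSet(set(expr.gene_ids)), 3)
        labels = cut_to_core_clusters(dendro, 1)
        assert labels.K == 1
        assert len(labels.labels) == expr.n_samples

    def test_outlier_absorbed_into_nearest_cluster(self):
        # 2 planted clusters plus 1 extreme sample: K=3 -> outlier absorbed
        rng = np.random.default_rng(9)
        n = 8
        x = rng.normal(size=(40, 2 * n + 1), scale=0.5)
        x[:20, :n] += 6.0
        x[20:, n : 2 * n] += 6.0
        x[:, -1] += rng.normal(size=40) * 3  # lone atypical sample
        samples = [f"s{j}" for j in range(2 * n + 1)]
        expr = ExpressionMatrix(
            [f"g{i}" for i in range(40)], samples, x, ["tumor"] * (2 * n + 1)
        )
        dendro = build_dendrogram(expr, GeneSet(set(expr.gene_ids)), 3)
        labels = cut_to_core_clusters(dendro, 3)
        assert labels.K == 2
        assert min(labels.sizes().values()) >= 2

    def test_no_singletons_even_when_k_equals_sample_count(self):
        expr, _ = three_cloud_matrix(seed=5, n_per=5)
        dendro = build_dendrogram(expr, GeneSet(set(expr.gene_ids)), 5)
        labels = cut_to_core_clusters(dendro, expr.n_samples)
        assert min(labels.sizes().values()) >= 2  # brute-force: no singleton remains

    def test_k_out_of_range_rejected(self):
        expr, _ = three_cloud_matrix(seed=6, n_per=4)
        dendro = build_dendrogram(expr, GeneSet(set(expr.gene_ids)), 3)
        with pytest.raises(ValidationError, match="out of range"):
            cut_to_core_clusters(dendro, expr.n_samples + 1)


def _fake_sig(sizes_by_cluster, phi_size, fct=1.0, alpha=0.05):
    """Minimal SignatureResult stand-in with prescribed signature sizes."""
    import pandas as pd

    from sigdriver.signature import SignatureResult

    gene_pool = [f"G{i}" for i in range(phi_size)]
    signatures = {}
    start = 0
    for k, size in sizes_by_cluster.items():
        signatures[k] = GeneSet(set(gene_pool[start : start + size]))
        start += size
    phi = set().union(*(s.gene_ids for s in signatures.values()))
    return SignatureResult(signatures, phi, pd.DataFrame(), fct=fct, alpha=alpha)


class TestMergeBadClusters:
    def _dendro(self, coords, samples):
        from scipy.cluster.hierarchy import linkage

        return Dendrogram(samples, linkage(coords, method="single"), coords)

    def test_small_signature_cluster_dissolved(self):
        # |S_k| = (100, 80, 1), |phi| = 181, threshold = 181/12 = 15.08
        samples = [f"s{j}" for j in range(9)]
        coords = np.array(
            [[0, 0], [0, 0.1], [0, -0.1], [5, 0], [5, 0.1], [5, -0.1], [2.4, 3], [2.6, 3], [2.5, 3.1]]
        )
        labels = SubtypeAssignment(
            {s: 1 if j < 3 else (2 if j < 6 else 3) for j, s in enumerate(samples)}, K=3
        )
        sig = _fake_sig({1: 100, 2: 80, 3: 1}, 181)
        merged = merge_bad_clusters(labels, sig, self._dendro(coords, samples))
        assert merged.K == 2
        # the dissolved samples went somewhere among the two good clusters
        assert set(merged.labels.values()) == {1, 2}

    def test_all_good_clusters_untouched(self):
        samples = [f"s{j}" for j in range(6)]
        coords = np.array([[0, 0], [0, 1], [5, 0], [5, 1], [9, 0], [9, 1]], dtype=float)
        labels = SubtypeAssignment(
            {s: j // 2 + 1 for j, s in enumerate(samples)}, K=3
        )
        sig = _fake_sig({1: 40, 2: 40, 3: 40}, 120)  # threshold 10, all good
        merged = merge_bad_clusters(labels, sig, self._dendro(coords, samples))
        assert merged.labels == labels.labels

    def test_single_cluster_owns_phi_and_is_good(self):
        samples = ["a", "b", "c"]
        coords = np.zeros((3, 2))
        labels = SubtypeAssignment({s: 1 for s in samples}, K=1)
        sig = _fake_sig({1: 30}, 30)  # threshold |phi|/4 = 7.5
        merged = merge_bad_clusters(labels, sig, self._dendro(coords, samples))
        assert merged.K == 1

    def test_bad_cluster_samples_reassigned_individually(self):
        # each bad-cluster sample goes to its own nearest good centroid,
        # so one bad cluster may scatter over several good clusters
        samples = [f"s{j}" for j in range(8)]
        coords = np.array(
            [[0, 0], [0, 1], [0, 0.5],      # cluster 1
             [9, 0], [9, 1], [9, 0.5],      # cluster 2
             [1, 0.5], [8, 0.5]],           # bad cluster, straddling both
            dtype=float,
        )
        labels = SubtypeAssignment(
            {s: (1 if j < 3 else 2 if j < 6 else 3) for j, s in enumerate(samples)}, K=3
        )
        sig = _fake_sig({1: 60, 2: 50, 3: 1}, 111)  # threshold 111/12 = 9.25
        merged = merge_bad_clusters(labels, sig, self._dendro(coords, samples))
        assert merged.K == 2
        assert merged.labels["s6"] == merged.labels["s0"]
        assert merged.labels["s7"] == merged.labels["s3"]

    def test_sibling_fragments_reunite_with_redetection(self):
        # one real subtype over-split into two halves: both look bad, but
        # dissolving one into the other restores a good cluster
        expr, truth = generate_subtype_testbed(
            n_subtypes=3, tumors_per_subtype=10, n_normals=5, n_genes=400,
            sig_block_size=20, seed=21,
        )
        tumors = expr.tumor_sample_ids
        split = {}
        for s in tumors:
            k = truth.labels.labels[s]
            if k == 3:
                half = int(s[1:]) % 2  # split subtype 3 arbitrarily in two
                split[s] = 3 + half
            else:
                split[s] = k
        labels = SubtypeAssignment(split, K=4)
        dendro = build_dendrogram(expr, GeneSet(set(expr.gene_ids)), 4)
        sig = detect_signature(expr, labels)
        assert len(sig.signatures[3]) == 0 and len(sig.signatures[4]) == 0
        merged = merge_bad_clusters(
            labels, sig, dendro,
            redetect=lambda lb: detect_signature(expr, lb),
        )
        assert merged.K == 3
        assert ari(merged, truth.labels.labels) == 1.0


class TestIterateSubtyping:
    def test_planted_three_subtypes_recovered(self):
        expr, truth = generate_subtype_testbed(seed=7)
        res = iterate_subtyping(expr, K_init=20)
        assert res.converged
        assert res.labels.K == 3
        assert res.iterations_run <= 10
        assert ari(res.labels, truth.labels.labels) == 1.0

    def test_result_independent_of_k_init(self):
        expr, truth = generate_subtype_testbed(seed=11)
        partitions = set()
        for k_init in (2, 6, 13, 20):
            res = iterate_subtyping(expr, K_init=k_init)
            assert res.converged
            partitions.add(res.labels.partition())
        assert len(partitions) == 1

    def test_trace_invariant_k_ordering(self):
        expr, _ = generate_subtype_testbed(seed=13)
        res = iterate_subtyping(expr, K_init=15)
        for rec in res.trace:
            assert rec.K_double_prime <= rec.K_prime <= rec.K_requested

    def test_deterministic(self):
        expr, _ = generate_subtype_testbed(seed=17)
        a = iterate_subtyping(expr, K_init=10)
        b = iterate_subtyping(expr, K_init=10)
        assert a.labels.labels == b.labels.labels
        assert [r.K_double_prime for r in a.trace] == [r.K_double_prime for r in b.trace]

    def test_unreachable_fct_raises(self):
        expr, _ = generate_subtype_testbed(seed=19)
        with pytest.raises(ValidationError, match="fct"):
            iterate_subtyping(expr, K_init=5, fct=1e6)

    def test_single_planted_subtype_collapses_to_one(self):
        expr, _ = generate_subtype_testbed(
            n_subtypes=1, tumors_per_subtype=20, n_normals=8, n_genes=500,
            sig_block_size=30, seed=23,
        )
        res = iterate_subtyping(expr, K_init=5)
        assert res.labels.K == 1

    def test_null_data_does_not_fabricate_subtypes(self):
        # pure noise, no normals: either the loop dies for lack of signal or
        # it settles on a single cluster; it must not report K > 1 converged
        fabricated = 0
        for seed in range(10):
            rng = np.random.default_rng(3000 + seed)
            x = rng.normal(size=(400, 30))
            samples = [f"s{j}" for j in range(25)] + [f"n{j}" for j in range(5)]
            expr = ExpressionMatrix(
                [f"g{i}" for i in range(400)], samples, x,
                ["tumor"] * 25 + ["normal"] * 5,
            )
            try:
                res = iterate_subtyping(expr, K_init=8, fct=1.0)
            except ValidationError:
                continue
            if res.converged and res.labels.K > 1:
                fabricated += 1
        assert fabricated == 0
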