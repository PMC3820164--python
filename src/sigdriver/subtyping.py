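"""Iterative signature-regularized subtype discovery.

The loop alternates clustering with signature detection.  Starting from the
top-variance genes and a deliberately large cluster number K:

1. spectrally embed the tumor samples on the current gene set and build an
   average-linkage dendrogram in the embedding;
2. cut into K clusters and absorb singletons into their nearest core
   cluster (K′ core clusters remain);
3. detect each cluster's signature on the *full* matrix and form the union
   Φ;
4. dissolve "bad" clusters — those holding fewer than ``|Φ|/(4K′)``
   signature genes — reassigning their samples to the nearest good cluster
   (K″ clusters remain);
5. re-cluster on Φ with K = K″ + ΔK, until the partition stabilizes.

The regularization defines a subtype as the smallest sample group backed by
a substantial signature: clusters that cannot support one are not subtypes
and are merged away, while ΔK keeps the search from collapsing to too few
clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.linalg import eigh

from .io import ExpressionMatrix, GeneSet, SubtypeAssignment, ValidationError
from .signature import SignatureResult, detect_signature
from .io import top_variance_genes

logger = logging.getLogger(__name__)


@dataclass
class Dendrogram:
    """Average-linkage merge tree over tumor samples in spectral coordinates.

    ``linkage_matrix`` is a scipy hierarchical-clustering encoding;
    ``embedding`` holds the spectral coordinates (samples × dims) the tree
    was built in, reused for nearest-centroid reassignments.
    """

    sample_ids: list[str]
    linkage_matrix: np.ndarray
    embedding: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.sample_ids)

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


@dataclass
class IterationRecord:
    """One iteration of the subtyping loop."""

    iteration: int
    K_requested: int
    K_prime: int
    K_double_prime: int
    cluster_sizes: dict[int, int]
    signature_sizes: dict[int, int]
    phi_size: int
    n_cluster_genes: int
    labels: SubtypeAssignment


@dataclass
class SubtypingResult:
    labels: SubtypeAssignment
    signature: SignatureResult
    trace: list[IterationRecord] = field(default_factory=list)
    converged: bool = False
    iterations_run: int = 0


def _spectral_embedding(values: np.ndarray, embed_dims: int) -> np.ndarray:
    """Embed samples (columns) via the normalized graph Laplacian.

    Similarity between samples is shifted Pearson correlation (1+r)/2 over
    the supplied gene rows.  The top ``embed_dims`` nontrivial eigenvectors
    of D^{-1/2} W D^{-1/2} are scaled by their eigenvalues — so
    cluster-indicator directions dominate noise directions when embed_dims
    exceeds the true structure — and rows are then normalized to the unit
    sphere.  Eigenvector signs are fixed by making each vector's
    largest-magnitude entry positive, so the embedding is deterministic.
    """
    n = values.shape[1]
    sd = values.std(axis=0)
    centered = values - values.mean(axis=0)
    denom = np.outer(sd, sd) * values.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (centered.T @ centered) / denom
    r = np.where(np.isfinite(r), r, 0.0)
    np.fill_diagonal(r, 1.0)
    w = (1.0 + np.clip(r, -1.0, 1.0)) / 2.0
    d = w.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(np.maximum(d, 1e-12))
    m = d_inv_sqrt[:, None] * w * d_inv_sqrt[None, :]
    m = (m + m.T) / 2.0
    embed_dims = max(1, min(embed_dims, n - 1))
    # eigh ascending: last column is the trivial eigenvector, skip it
    vals, vecs = eigh(m, subset_by_index=(n - embed_dims - 1, n - 1))
    coords = vecs[:, :-1][:, ::-1]  # nontrivial vectors, largest eigenvalue first
    coords = coords * np.maximum(vals[:-1][::-1], 0.0)[None, :]
    for j in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    norms = np.linalg.norm(coords, axis=1, keepdims=True)
    return coords / np.where(norms > 0, norms, 1.0)


def build_dendrogram(
    expr: ExpressionMatrix,
    gene_subset: GeneSet,
    embed_dims: int,
    linkage_method: str = "single",
) -> Dendrogram:
    """Spectral embedding of tumor samples + agglomerative dendrogram.

    ``linkage_method`` is any scipy hierarchical linkage.  The default is
    single linkage: when the tree is cut into more clusters than the data
    supports, single linkage peels off isolated samples — which the
    singleton-absorption step then reclaims — whereas average/complete/ward
    bisect real clusters into sibling fragments whose mutual similarity
    suppresses both siblings' signatures.
    """
    genes = [g for g in gene_subset.sorted() if g in expr._gene_index]
    if not genes:
        raise ValidationError("gene subset is disjoint from the matrix genes")
    if len(genes) < 2:
        raise ValidationError("need at least 2 genes to cluster on")
    tumors = expr.tumor_sample_ids
    if len(tumors) < 3:
        raise ValidationError("need at least 3 tumor samples to cluster")
    sub = expr.values[np.ix_(expr.gene_rows(genes), expr.sample_cols(tumors))]
    coords = _spectral_embedding(sub, embed_dims)
    z = linkage(coords, method=linkage_method, metric="euclidean")
    return Dendrogram(tumors, z, coords)


def _relabel(groups: dict[str, int], sample_order: list[str]) -> SubtypeAssignment:
    """Relabel clusters 1..K by order of first appearance in sample_order."""
    mapping: dict[int, int] = {}
    out: dict[str, int] = {}
    for s in sample_order:
        g = groups[s]
        if g not in mapping:
            mapping[g] = len(mapping) + 1
        out[s] = mapping[g]
    return SubtypeAssignment(out, K=len(mapping))


def _centroids(
    dendro_ids: list[str], embedding: np.ndarray, labels: SubtypeAssignment
) -> dict[int, np.ndarray]:
    idx = {s: i for i, s in enumerate(dendro_ids)}
    return {
        k: embedding[[idx[s] for s in labels.members(k)], :].mean(axis=0)
        for k in range(1, labels.K + 1)
    }


def cut_to_core_clusters(dendro: Dendrogram, K: int) -> SubtypeAssignment:
    """Cut the dendrogram into K groups and absorb singletons.

    Every singleton group's sample is reassigned to the cluster whose
    centroid (mean embedding coordinate) is nearest; when every group is a
    singleton, the closest pair is merged first.  The result has K′ ≤ K
    clusters, all of size ≥ 2, relabeled 1..K′.
    """
    if not (1 <= K <= dendro.n_leaves):
        raise ValidationError(f"K={K} out of range 1..{dendro.n_leaves}")
    flat = fcluster(dendro.linkage_matrix, t=K, criterion="maxclust")
    groups = {s: int(g) for s, g in zip(dendro.sample_ids, flat)}
    labels = _relabel(groups, dendro.sample_ids)
    idx = {s: i for i, s in enumerate(dendro.sample_ids)}
    while True:
        sizes = labels.sizes()
        singles = [k for k, n in sizes.items() if n == 1]
        if not singles or labels.K == 1:
            break
        cores = [k for k, n in sizes.items() if n >= 2]
        cents = _centroids(dendro.sample_ids, dendro.embedding, labels)
        new = dict(labels.labels)
        if cores:
            for k in singles:
                (s,) = labels.members(k)
                x = dendro.embedding[idx[s]]
                best = min(cores, key=lambda c: (float(np.linalg.norm(x - cents[c])), c))
                new[s] = best
        else:
            # all clusters are singletons: merge the closest pair, then re-loop
            pairs = [
                (float(np.linalg.norm(cents[a] - cents[b])), a, b)
                for a in singles
                for b in singles
                if a < b
            ]
            _, a, b = min(pairs)
            for s in labels.members(b):
                new[s] = a
        labels = _relabel(new, dendro.sample_ids)
    return labels


def _merge_nearest_pair(
    labels: SubtypeAssignment, dendro: Dendrogram
) -> SubtypeAssignment:
    """Merge the two clusters with nearest centroids (ties by labels)."""
    cents = _centroids(dendro.sample_ids, dendro.embedding, labels)
    pairs = [
        (float(np.linalg.norm(cents[a] - cents[b])), a, b)
        for a in range(1, labels.K + 1)
        for b in range(a + 1, labels.K + 1)
    ]
    _, a, b = min(pairs)
    new = {s: (a if v == b else v) for s, v in labels.labels.items()}
    return _relabel(new, dendro.sample_ids)


def merge_bad_clusters(
    labels: SubtypeAssignment,
    sig: SignatureResult,
    dendro: Dendrogram,
    bad_cluster_factor: float = 0.25,
    redetect=None,
) -> SubtypeAssignment:
    """Dissolve clusters whose signature is below ``factor · |Φ| / K′``.

    With the default factor 1/4 the threshold is ``|Φ|/(4K′)``.  Without
    ``redetect``, a single pass reassigns every bad cluster's samples,
    each individually, to the good cluster with the nearest centroid in
    the embedding.

    With ``redetect`` (a callable ``labels -> SignatureResult``), bad
    clusters are dissolved one at a time — worst first, each sample moved
    to the nearest *remaining* cluster — and signatures are recomputed
    after each dissolution.  This matters when an over-cut has split one
    real subtype into sibling fragments: the siblings suppress each
    other's specificity, so both look bad, yet dissolving one into the
    other restores a good cluster.  Reuniting siblings must therefore be
    possible before good clusters absorb their samples.

    The result is relabeled 1..K″.
    """
    if redetect is None:
        return _merge_bad_single_pass(labels, sig, dendro, bad_cluster_factor)
    while True:
        k_now = labels.K
        phi_size = len(sig.phi)
        threshold = bad_cluster_factor * phi_size / k_now
        sizes = sig.sizes()
        bad = [k for k in range(1, k_now + 1) if sizes.get(k, 0) < threshold]
        if not bad:
            return labels
        if len(bad) == k_now:
            raise ValidationError(
                f"all {k_now} clusters are bad (|phi|={phi_size}, "
                f"threshold={threshold:.2f}); the signal is degenerate — "
                "consider lowering fct"
            )
        cluster_sizes = labels.sizes()
        worst = min(bad, key=lambda k: (sizes.get(k, 0), cluster_sizes[k], k))
        targets = [k for k in range(1, k_now + 1) if k != worst]
        idx = {s: i for i, s in enumerate(dendro.sample_ids)}
        cents = _centroids(dendro.sample_ids, dendro.embedding, labels)
        new = dict(labels.labels)
        for s in labels.members(worst):
            x = dendro.embedding[idx[s]]
            new[s] = min(targets, key=lambda c: (float(np.linalg.norm(x - cents[c])), c))
        labels = _relabel(new, dendro.sample_ids)
        sig = redetect(labels)


def _merge_bad_single_pass(
    labels: SubtypeAssignment,
    sig: SignatureResult,
    dendro: Dendrogram,
    bad_cluster_factor: float,
) -> SubtypeAssignment:
    k_prime = labels.K
    phi_size = len(sig.phi)
    threshold = bad_cluster_factor * phi_size / k_prime
    sizes = sig.sizes()
    good = [k for k in range(1, k_prime + 1) if sizes.get(k, 0) >= threshold]
    bad = [k for k in range(1, k_prime + 1) if k not in good]
    if not good:
        raise ValidationError(
            f"all {k_prime} clusters are bad (|phi|={phi_size}, threshold={threshold:.1f}); "
            "the signal is degenerate — consider lowering fct"
        )
    if not bad:
        return labels
    idx = {s: i for i, s in enumerate(dendro.sample_ids)}
    cents = _centroids(dendro.sample_ids, dendro.embedding, labels)
    new = dict(labels.labels)
    for k in bad:
        for s in labels.members(k):
            x = dendro.embedding[idx[s]]
            new[s] = min(good, key=lambda c: (float(np.linalg.norm(x - cents[c])), c))
    return _relabel(new, dendro.sample_ids)


def iterate_subtyping(
    expr: ExpressionMatrix,
    K_init: int = 20,
    fct: float = 1.0,
    delta_K: int = 1,
    alpha: float = 0.05,
    max_iter: int = 10,
    initial_gene_fraction: float = 0.10,
    bad_cluster_factor: float = 0.25,
    embed_dims: int | None = None,
    linkage_method: str = "single",
) -> SubtypingResult:
    """Run the full iterative subtyping loop.

    Clustering runs on the current gene set (initially the top
    ``initial_gene_fraction`` of genes by tumor variance, afterwards the
    signature union Φ); signatures are always detected on the full matrix.
    Convergence requires the partition and K″ to repeat in consecutive
    iterations; the loop stops at ``max_iter`` regardless.
    """
    if K_init < 2:
        raise ValidationError("K_init must be >= 2")
    if delta_K < 1:
        raise ValidationError("delta_K must be >= 1")
    if max_iter < 1:
        raise ValidationError("max_iter must be >= 1")
    n_tumors = len(expr.tumor_sample_ids)
    gene_set = top_variance_genes(expr, initial_gene_fraction)
    K = min(K_init, n_tumors)
    trace: list[IterationRecord] = []
    prev_partition = None
    prev_kpp = None
    converged = False
    final_labels: SubtypeAssignment | None = None
    for it in range(1, max_iter + 1):
        dims = embed_dims if embed_dims is not None else K
        dendro = build_dendrogram(expr, gene_set, dims, linkage_method=linkage_method)
        labels = cut_to_core_clusters(dendro, K)
        k_prime = labels.K
        sig = detect_signature(expr, labels, fct=fct, alpha=alpha)
        # When no cluster carries any signature the partition is pure
        # over-fragmentation (every subtype split into sibling fragments
        # that cancel each other's specificity).  Reduce resolution
        # gradually: merge the two nearest clusters and look again.
        while not sig.phi and labels.K > 1:
            labels = _merge_nearest_pair(labels, dendro)
            sig = detect_signature(expr, labels, fct=fct, alpha=alpha)
        if not sig.phi:
            raise ValidationError(
                f"empty signature union at iteration {it}; "
                f"lower fct (currently {fct})"
            )
        merged = merge_bad_clusters(
            labels,
            sig,
            dendro,
            bad_cluster_factor,
            redetect=lambda lb: detect_signature(expr, lb, fct=fct, alpha=alpha),
        )
        if merged is not labels:
            sig = detect_signature(expr, merged, fct=fct, alpha=alpha)
            while not sig.phi and merged.K > 1:
                merged = _merge_nearest_pair(merged, dendro)
                sig = detect_signature(expr, merged, fct=fct, alpha=alpha)
            if not sig.phi:
                raise ValidationError(
                    f"empty signature union at iteration {it}; "
                    f"lower fct (currently {fct})"
                )
        k_pp = merged.K
        trace.append(
            IterationRecord(
                iteration=it,
                K_requested=K,
                K_prime=k_prime,
                K_double_prime=k_pp,
                cluster_sizes=merged.sizes(),
                signature_sizes=sig.sizes(),
                phi_size=len(sig.phi),
                n_cluster_genes=len(gene_set),
                labels=merged,
            )
        )
        logger.info(
            "iteration %d: K=%d -> K'=%d -> K''=%d, |phi|=%d", it, K, k_prime, k_pp, len(sig.phi)
        )
        final_labels = merged
        part = merged.partition()
        if prev_partition is not None and part == prev_partition and k_pp == prev_kpp:
            converged = True
            break
        prev_partition, prev_kpp = part, k_pp
        gene_set = GeneSet(set(sig.phi))
        K = min(k_pp + delta_K, n_tumors)
    assert final_labels is not None
    final_sig = detect_signature(expr, final_labels, fct=fct, alpha=alpha)
    return SubtypingResult(
        labels=final_labels,
        signature=final_sig,
        trace=trace,
        converged=converged,
        iterations_run=len(trace),
    )
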