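"""Cross-dataset validation of subtype assignments.

Two cohorts measured on different platforms are first restricted to their
common genes, and each common gene is affinely rescaled within each cohort
so that it attains a target mean of (m₁+m₂)/2 and a target standard
deviation of sqrt(s₁²/n₁ + s₂²/n₂) — the standard error-like pooling of the
two per-cohort moments.  Subtype labels trained on one cohort are then
transferred to the other by k-nearest-neighbor vote (default k = 3,
Euclidean distance over the training cohort's signature genes), and the
transfer is scored against the test cohort's self-trained labels as a
confusion matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .io import ExpressionMatrix, GeneSet, SubtypeAssignment, ValidationError
from .signature import SignatureResult

logger = logging.getLogger(__name__)


@dataclass
class PairNormalization:
    """Per-common-gene two-moment normalization record."""

    table: pd.DataFrame  # gene, m1, s1, n1, m2, s2, n2, target_mean, target_sd

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()


@dataclass
class ConfusionMatrix:
    """Square count matrix: rows self-trained labels, columns predictions."""

    counts: np.ndarray
    labels: list[int]

    @property
    def accuracy(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


def normalize_pair(
    expr1: ExpressionMatrix, expr2: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix, PairNormalization]:
    """Restrict both cohorts to common genes and equalize per-gene moments.

    Each gene in each cohort is transformed to mean ``(m1+m2)/2`` and SD
    ``sqrt(s1²/n1 + s2²/n2)`` (sample SD, ddof=1).  A gene with zero SD in
    a cohort is shifted to the target mean with its scale left at zero.
    """
    common = [g for g in expr1.gene_ids if g in set(expr2.gene_ids)]
    if not common:
        raise ValidationError("no common genes between the two datasets")
    v1 = expr1.values[expr1.gene_rows(common), :]
    v2 = expr2.values[expr2.gene_rows(common), :]
    n1, n2 = expr1.n_samples, expr2.n_samples
    m1, m2 = v1.mean(axis=1), v2.mean(axis=1)
    s1 = v1.std(axis=1, ddof=1)
    s2 = v2.std(axis=1, ddof=1)
    target_mean = (m1 + m2) / 2.0
    target_sd = np.sqrt(s1**2 / n1 + s2**2 / n2)
    zero1, zero2 = s1 == 0, s2 == 0
    if zero1.any() or zero2.any():
        logger.warning(
            "%d gene(s) constant in one dataset; shifted without rescaling",
            int((zero1 | zero2).sum()),
        )

    def transform(v, m, s, zero):
        scale = np.where(zero, 0.0, target_sd / np.where(zero, 1.0, s))
        return (v - m[:, None]) * scale[:, None] + target_mean[:, None]

    out1 = ExpressionMatrix(
        common, list(expr1.sample_ids), transform(v1, m1, s1, zero1), list(expr1.sample_class)
    )
    out2 = ExpressionMatrix(
        common, list(expr2.sample_ids), transform(v2, m2, s2, zero2), list(expr2.sample_class)
    )
    norm = PairNormalization(
        pd.DataFrame(
            {
                "gene": common,
                "m1": m1,
                "s1": s1,
                "n1": n1,
                "m2": m2,
                "s2": s2,
                "n2": n2,
                "target_mean": target_mean,
                "target_sd": target_sd,
            }
        )
    )
    return out1, out2, norm


def knn_transfer(
    train: ExpressionMatrix,
    train_labels: SubtypeAssignment,
    test: ExpressionMatrix,
    feature_genes: GeneSet | list[str],
    k: int = 3,
) -> SubtypeAssignment:
    """Predict test-cohort subtype labels by k-NN over feature genes.

    Euclidean distance in feature space to the labeled training tumors;
    majority vote among the k nearest, ties broken by the label of the
    single nearest neighbor.  Predictions are made for the test cohort's
    tumor samples.
    """
    genes = feature_genes.sorted() if isinstance(feature_genes, GeneSet) else list(feature_genes)
    if not genes:
        raise ValidationError("empty feature gene set")
    train_samples = [s for s in train.tumor_sample_ids if s in train_labels.labels]
    if k > len(train_samples):
        raise ValidationError(f"k={k} exceeds {len(train_samples)} training samples")
    xt = train.values[np.ix_(train.gene_rows(genes), train.sample_cols(train_samples))].T
    test_samples = test.tumor_sample_ids
    xs = test.values[np.ix_(test.gene_rows(genes), test.sample_cols(test_samples))].T
    y = train_labels.as_array(train_samples)
    nn = NearestNeighbors(n_neighbors=k).fit(xt)
    _, idx = nn.kneighbors(xs)
    pred = {}
    for s, neighbors in zip(test_samples, idx):
        votes = y[neighbors]
        counts = np.bincount(votes)
        winners = np.flatnonzero(counts == counts.max())
        pred[s] = int(winners[0]) if len(winners) == 1 else int(votes[0])
    k_max = max(pred.values())
    # predictions need not use every training label; keep the training K if covered
    used = set(pred.values())
    if used == set(range(1, k_max + 1)):
        return SubtypeAssignment(pred, K=k_max)
    remap = {old: i + 1 for i, old in enumerate(sorted(used))}
    logger.warning("not all training labels predicted; compacting to 1..%d", len(used))
    return SubtypeAssignment({s: remap[v] for s, v in pred.items()}, K=len(used))


def confusion_and_accuracy(
    self_labels: SubtypeAssignment, predicted: SubtypeAssignment
) -> ConfusionMatrix:
    """Confusion matrix of predictions against self-trained labels.

    Label alphabets must have been matched by the caller (see
    :func:`match_subtypes_by_signature`); accuracy is trace/total.
    """
    if set(self_labels.labels) != set(predicted.labels):
        raise ValidationError("self-trained and predicted label sets cover different samples")
    kk = max(self_labels.K, predicted.K)
    counts = np.zeros((kk, kk), dtype=int)
    for s, true in self_labels.labels.items():
        counts[true - 1, predicted.labels[s] - 1] += 1
    return ConfusionMatrix(counts, labels=list(range(1, kk + 1)))


def match_subtypes_by_signature(
    train_sig: SignatureResult, test_sig: SignatureResult
) -> dict[int, int]:
    """Greedy matching of training → testing subtype identities.

    Integer subtype labels are arbitrary per cohort; identities are aligned
    by repeatedly pairing the (train, test) subtypes with the largest
    signature-gene overlap.  Unmatched subtypes keep distinct fresh labels.
    Returns a mapping train label → test label.
    """
    pairs = [
        (len(train_sig.signatures[a].gene_ids & test_sig.signatures[b].gene_ids), a, b)
        for a in train_sig.signatures
        for b in test_sig.signatures
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    mapping: dict[int, int] = {}
    used_b: set[int] = set()
    for _, a, b in pairs:
        if a in mapping or b in used_b:
            continue
        mapping[a] = b
        used_b.add(b)
    nxt = max(list(used_b) + [0]) + 1
    for a in train_sig.signatures:
        if a not in mapping:
            mapping[a] = nxt
            nxt += 1
    return mapping


def relabel(labels: SubtypeAssignment, mapping: dict[int, int]) -> SubtypeAssignment:
    """Apply a label mapping, compacting to a contiguous 1..K range."""
    raw = {s: mapping[v] for s, v in labels.labels.items()}
    used = sorted(set(raw.values()))
    compact = {old: i + 1 for i, old in enumerate(used)}
    if compact != {v: v for v in used}:
        raw = {s: compact[v] for s, v in raw.items()}
    return SubtypeAssignment(raw, K=len(used))
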