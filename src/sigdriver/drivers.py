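"""Subtype-specific ranking of candidate CNA driver genes.

A copy-number-affected gene that participates in a subtype's pathology
should leave a correlation footprint on the subtype's signature genes.
With J signature genes and L pre-selected candidates, the between-set
covariance C_ab (J × L, computed over the subtype's own samples and
row-centered) summarizes those dependencies.  Rather than solving the
canonical-correlation problem exactly, the candidates are scored by a PCA
projection: thin SVD ``C_ab = U Σ Vᵀ`` and driver potentials

    ŵ_b = C_abᵀ u₁ = σ₁ v₁,

i.e. each candidate's loading along the leading covariance direction.  The
identity ``u₁ᵀ C_ab C_abᵀ u₁ = σ₁²`` ties the projection to the maximal
between-set covariance captured by any single direction.  Significance
comes from a permutation null: random gene sets of the same size as the
signature are drawn from the non-candidate pool, the projection recomputed,
and all null potentials pooled into one empirical distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet, SubtypeAssignment, ValidationError
from .signature import SignatureResult

logger = logging.getLogger(__name__)


@dataclass
class SVDProjection:
    """First-singular-vector projection of a between-set covariance."""

    C_ab: np.ndarray
    u1: np.ndarray
    sigma1: float
    v1: np.ndarray
    w_hat_b: np.ndarray

    def __post_init__(self) -> None:
        if self.sigma1 > 0:
            assert abs(np.linalg.norm(self.u1) - 1) < 1e-8
            assert abs(np.linalg.norm(self.v1) - 1) < 1e-8
            resid = np.max(np.abs(self.w_hat_b - self.sigma1 * self.v1))
            assert resid < 1e-8, f"w_hat_b != sigma1*v1 (max |diff| {resid:.2e})"
            quad = float(self.u1 @ self.C_ab @ self.C_ab.T @ self.u1)
            assert abs(quad - self.sigma1**2) <= 1e-8 * max(1.0, self.sigma1**2)


@dataclass
class DriverRanking:
    """Permutation-ranked candidate drivers for one subtype."""

    table: pd.DataFrame  # columns: gene, driver_potential, p_value, rank
    projection: SVDProjection
    n_permutations: int
    seed: int
    signature_size: int

    def significant(self, p_threshold: float = 0.01) -> pd.DataFrame:
        return self.table[self.table["p_value"] < p_threshold].reset_index(drop=True)


def between_set_covariance(
    expr: ExpressionMatrix,
    subtype_samples: list[str],
    signature: GeneSet | list[str],
    candidates: GeneSet | list[str],
) -> np.ndarray:
    """Row-centered covariance between signature and candidate genes.

    Sample covariance (ddof=1) of each signature gene (rows) against each
    candidate gene (columns), over the given subtype's samples only, then
    each row centered to zero mean.  Constant genes contribute zero
    covariance.
    """
    sig_genes = signature.sorted() if isinstance(signature, GeneSet) else list(signature)
    cand_genes = candidates.sorted() if isinstance(candidates, GeneSet) else list(candidates)
    overlap = set(sig_genes) & set(cand_genes)
    if overlap:
        raise ValidationError(f"signature and candidates overlap: {sorted(overlap)[:5]}")
    if not sig_genes or not cand_genes:
        raise ValidationError("signature and candidate sets must be non-empty")
    if len(subtype_samples) < 3:
        raise ValidationError("need at least 3 subtype samples for a covariance")
    cols = expr.sample_cols(subtype_samples)
    a = expr.values[np.ix_(expr.gene_rows(sig_genes), cols)]
    b = expr.values[np.ix_(expr.gene_rows(cand_genes), cols)]
    n = len(subtype_samples)
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    if np.any(ac.std(axis=1) == 0) or np.any(bc.std(axis=1) == 0):
        logger.info("constant gene(s) in covariance input; their covariances are 0")
    c = (ac @ bc.T) / (n - 1)
    return c - c.mean(axis=1, keepdims=True)


def driver_potentials(C_ab: np.ndarray) -> SVDProjection:
    """Project C_ab onto its first left singular vector.

    Sign convention: u₁ (and v₁ with it) is flipped so its
    largest-magnitude entry is positive, making results deterministic
    across linear-algebra backends.  An all-zero matrix yields σ₁ = 0 and
    zero potentials.
    """
    c = np.asarray(C_ab, dtype=float)
    if c.ndim != 2 or c.size == 0:
        raise ValidationError("C_ab must be a non-empty 2-D matrix")
    if not np.all(np.isfinite(c)):
        raise ValidationError("C_ab must be finite")
    if not c.any():
        logger.warning("all-zero between-set covariance; potentials are 0")
        j, l = c.shape
        u1 = np.zeros(j)
        u1[0] = 1.0
        v1 = np.zeros(l)
        return SVDProjection(c, u1, 0.0, v1, np.zeros(l))
    u, s, vt = np.linalg.svd(c, full_matrices=False)
    u1, sigma1, v1 = u[:, 0], float(s[0]), vt[0, :]
    i = int(np.argmax(np.abs(u1)))
    if u1[i] < 0:
        u1, v1 = -u1, -v1
    return SVDProjection(c, u1, sigma1, v1, c.T @ u1)


def candidate_vs_null_potentials(
    expr: ExpressionMatrix,
    subtype_samples: list[str],
    signature: GeneSet | list[str],
    candidates: GeneSet | list[str],
    null_genes: GeneSet | list[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Score candidates and null genes in one shared projection.

    Because C_ab is row-centered, every projection's potentials sum to
    zero, so candidates can only be compared against a reference gene set
    if both are columns of the *same* covariance matrix.  This scores the
    candidates jointly with a null set (e.g. the non-signature,
    non-candidate background genes of a synthetic testbed) and returns
    ``(candidate potentials, null potentials)``.
    """
    cand = candidates.sorted() if isinstance(candidates, GeneSet) else list(candidates)
    null = null_genes.sorted() if isinstance(null_genes, GeneSet) else list(null_genes)
    overlap = set(cand) & set(null)
    if overlap:
        raise ValidationError(f"candidates and null genes overlap: {sorted(overlap)[:5]}")
    proj = driver_potentials(
        between_set_covariance(expr, subtype_samples, signature, cand + null)
    )
    return proj.w_hat_b[: len(cand)], proj.w_hat_b[len(cand) :]


def permutation_pvalues(
    expr: ExpressionMatrix,
    subtype_samples: list[str],
    signature: GeneSet | list[str],
    candidates: GeneSet | list[str],
    n_permutations: int = 1000,
    seed: int = 0,
) -> DriverRanking:
    """Permutation p-values for candidate driver potentials.

    Null signature sets of size |signature| are drawn uniformly without
    replacement from all genes excluding the candidates; each draw's
    potentials are pooled into one empirical null.  The two-sided p-value
    for candidate l is ``(1 + #{|null| >= |ŵ_bl|}) / (1 + #null)``
    (add-one, so p is never zero).  Ranking is ascending by p, ties broken
    by larger |ŵ_bl|, then gene id.
    """
    if n_permutations < 100:
        raise ValidationError("n_permutations must be >= 100")
    sig_genes = signature.sorted() if isinstance(signature, GeneSet) else list(signature)
    cand_genes = candidates.sorted() if isinstance(candidates, GeneSet) else list(candidates)
    cand_set = set(cand_genes)
    pool = [g for g in expr.gene_ids if g not in cand_set]
    if len(pool) < len(sig_genes):
        raise ValidationError(
            f"gene pool ({len(pool)}) smaller than signature size ({len(sig_genes)})"
        )
    proj = driver_potentials(
        between_set_covariance(expr, subtype_samples, sig_genes, cand_genes)
    )
    rng = np.random.default_rng(seed)
    pool_arr = np.array(pool)
    null_values = np.empty(n_permutations * len(cand_genes))
    for p in range(n_permutations):
        draw = rng.choice(pool_arr, size=len(sig_genes), replace=False)
        null_proj = driver_potentials(
            between_set_covariance(expr, subtype_samples, list(draw), cand_genes)
        )
        null_values[p * len(cand_genes) : (p + 1) * len(cand_genes)] = null_proj.w_hat_b
    abs_null = np.sort(np.abs(null_values))
    w = proj.w_hat_b
    n_null = abs_null.size
    exceed = n_null - np.searchsorted(abs_null, np.abs(w), side="left")
    pvals = (1.0 + exceed) / (1.0 + n_null)
    table = pd.DataFrame(
        {"gene": cand_genes, "driver_potential": w, "p_value": pvals}
    )
    order = table.sort_values(
        ["p_value", "driver_potential", "gene"],
        ascending=[True, True, True],
        key=lambda s: -s.abs() if s.name == "driver_potential" else s,
    ).index
    rank = np.empty(len(table), dtype=int)
    rank[order] = np.arange(1, len(table) + 1)
    table["rank"] = rank
    return DriverRanking(
        table=table,
        projection=proj,
        n_permutations=n_permutations,
        seed=seed,
        signature_size=len(sig_genes),
    )


def run_driver_analysis(
    expr: ExpressionMatrix,
    labels: SubtypeAssignment,
    sig: SignatureResult,
    candidates_per_subtype: dict[int, GeneSet],
    n_permutations: int = 1000,
    seed: int = 0,
    p_threshold: float = 0.01,
) -> dict[int, DriverRanking]:
    """Rank each subtype's candidate list against that subtype's signature.

    Candidate lists come from an external recurrence analysis (e.g. GISTIC
    on the subtype's copy-number profiles); subtypes with an empty
    signature are skipped with a warning.  Each subtype's analysis is
    independent and uses its own derived seed.
    """
    results: dict[int, DriverRanking] = {}
    for k, cand in sorted(candidates_per_subtype.items()):
        sk = sig.signatures.get(k)
        if sk is None or len(sk) == 0:
            logger.warning("subtype %d has an empty signature; skipped", k)
            continue
        sig_genes = [g for g in sk.sorted() if g not in cand.gene_ids]
        if not sig_genes:
            logger.warning("subtype %d signature fully overlaps candidates; skipped", k)
            continue
        ranking = permutation_pvalues(
            expr,
            labels.members(k),
            sig_genes,
            cand,
            n_permutations=n_permutations,
            seed=seed + k,
        )
        n_sig = int((ranking.table["p_value"] < p_threshold).sum())
        logger.info(
            "subtype %d: %d/%d candidates at p < %g", k, n_sig, len(ranking.table), p_threshold
        )
        results[k] = ranking
    return results
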