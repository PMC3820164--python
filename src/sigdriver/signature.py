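"""Subtype-specific gene signature detection.

A signature gene for subtype *k* must pass two filters:

1. **Statistical**: differentially expressed in subtype *k* versus all other
   samples (other tumor subtypes pooled with normals), by an empirical-Bayes
   moderated two-sample t-test with Benjamini–Hochberg correction.
2. **Specificity**: its mean in subtype *k* must strictly exceed (or fall
   below) every other group mean — other tumor subtypes and the normal group
   each counted as separate groups — and the subtype-specific fold change

       FC_k = Δ_k − Δ′_k,
       Δ_k  = min(|μ_k − min_{ℓ≠k} μ_ℓ|, |μ_k − max_{ℓ≠k} μ_ℓ|),
       Δ′_k = max_{ℓ≠k} μ_ℓ − min_{ℓ≠k} μ_ℓ,

   must exceed the fold-change threshold (FCT).  Δ_k measures how far the
   subtype departs from the nearest extreme of the other groups, Δ′_k how
   spread out the other groups themselves are; FC_k > 0 demands that the
   subtype's departure dominate the background spread.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSet, SubtypeAssignment, ValidationError

logger = logging.getLogger(__name__)

NORMAL_GROUP = 0  # group key for the pooled normal samples


@dataclass
class GeneSubtypeStats:
    """Per-(gene, subtype) statistics backing a signature call."""

    gene_id: str
    subtype: int
    mu_k: float
    delta_k: float
    delta_prime_k: float
    fc_k: float
    t_stat: float
    p_raw: float
    p_adj: float
    direction: str  # up | down | none


@dataclass
class SignatureResult:
    """Signatures for all subtypes of one labeling.

    Attributes
    ----------
    signatures
        Per subtype ``k``: a :class:`GeneSet` with per-gene direction.
    phi
        Union of all subtype signatures (the gene set used for the next
        clustering round during iterative subtyping).
    stats
        Long-format table, one row per (gene, subtype), with all
        :class:`GeneSubtypeStats` fields plus ``in_signature``.
    fct, alpha
        The parameters the signatures were called with.
    """

    signatures: dict[int, GeneSet]
    phi: set[str]
    stats: pd.DataFrame
    fct: float
    alpha: float

    def sizes(self) -> dict[int, int]:
        return {k: len(s) for k, s in self.signatures.items()}

    def __post_init__(self) -> None:
        union = set().union(*(s.gene_ids for s in self.signatures.values())) if self.signatures else set()
        if union != self.phi:
            raise ValidationError("phi must equal the union of the subtype signatures")
        for d in ("up", "down"):
            owner: dict[str, int] = {}
            for k, s in self.signatures.items():
                for g, gd in s.direction.items():
                    if gd != d:
                        continue
                    if g in owner:
                        logger.warning(
                            "gene %s is %s-signature in subtypes %d and %d", g, d, owner[g], k
                        )
                    owner[g] = k


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x for y by Newton iteration (monotone, convex)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x  # good starting point for the relevant range
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) / y < 1e-10):
            break
    return y


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F prior to per-gene sample variances.

    Models ``s2 ~ s0^2 * F(df, d0)`` and estimates the prior variance
    ``s0^2`` and prior degrees of freedom ``d0`` from the mean and variance
    of ``log(s2)``.  Returns ``(d0, s0_sq)``; ``d0 = inf`` when the observed
    spread of log-variances does not exceed what sampling alone explains.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise ValidationError("all genes have zero variance; cannot fit variance prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    n = e.size
    e_var = float(((e - e_mean) ** 2).sum() / (n - 1.0)) if n > 1 else 0.0
    e_var -= special.polygamma(1, df / 2.0)
    if e_var > 0:
        d0 = 2.0 * float(_trigamma_inverse(np.array([e_var]))[0])
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # spread of log-variances is fully explained by sampling: all true
        # variances equal, best estimate is the plain average
        d0 = np.inf
        s0_sq = float(s2[ok].mean())
    return d0, s0_sq


def moderated_de_test(
    expr: ExpressionMatrix,
    labels: SubtypeAssignment,
    k: int,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated two-group t-test: subtype *k* versus all other samples.

    The comparison group is every sample not labeled *k* — other tumor
    subtypes regardless of label, plus normals.  Per-gene pooled variances
    are shrunk toward a prior fitted across genes by moments
    (empirical-Bayes, limma-style); two-sided p-values use the t
    distribution with ``d0 + d`` degrees of freedom.

    Parameters
    ----------
    prior_df
        Override for the prior degrees of freedom ``d0``.  ``None`` (default)
        fits it from the data; ``0`` disables shrinkage, recovering the
        ordinary pooled-variance two-sample t-test.

    Returns
    -------
    DataFrame indexed by gene with columns ``t_stat`` and ``p_raw``.
    """
    in_k = np.array([labels.labels.get(s) == k for s in expr.sample_ids])
    rest = ~in_k
    n1, n2 = int(in_k.sum()), int(rest.sum())
    if n1 < 2 or n2 < 2:
        raise ValidationError(
            f"subtype {k} vs rest needs >=2 samples per group (got {n1} vs {n2})"
        )
    x1, x2 = expr.values[:, in_k], expr.values[:, rest]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    ss1 = ((x1 - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((x2 - m2[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    s2 = (ss1 + ss2) / df
    if np.all(s2 == 0):
        raise ValidationError("zero pooled variance for every gene")
    if prior_df is None:
        d0, s0_sq = fit_f_dist(s2, df)
    elif prior_df == 0:
        d0, s0_sq = 0.0, 0.0
    else:
        d0 = float(prior_df)
        _, s0_sq = fit_f_dist(s2, df)
    df_pooled = df * expr.n_genes  # cap: no more information than all genes pooled
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = df_pooled
    elif d0 == 0:
        s2_post = s2
        df_total = df
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = min(d0 + df, df_pooled)
    diff = m1 - m2
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(diff == 0, 0.0, diff / se)
    t = np.where(np.isnan(t), 0.0, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isinf(t), 0.0, p)
    return pd.DataFrame({"t_stat": t, "p_raw": p}, index=expr.gene_ids)


def bh_adjust(p_raw) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def subtype_specific_fc(
    mu_by_group: dict[int, float] | list[float], k: int
) -> tuple[float, float, float, str]:
    """Subtype-specific deviation statistics for group means.

    ``mu_by_group`` maps group key → mean (or is a list whose positions
    1..K are tumor subtypes when given as a dict-like); ``k`` is the group
    of interest.  Returns ``(delta_k, delta_prime_k, fc_k, direction)``.
    """
    if isinstance(mu_by_group, dict):
        mus = mu_by_group
    else:
        mus = {i + 1: float(v) for i, v in enumerate(mu_by_group)}
    if k not in mus:
        raise ValidationError(f"group {k} not among the group means")
    if len(mus) < 2:
        raise ValidationError("need at least 2 groups")
    mu_k = float(mus[k])
    others = np.array([v for g, v in mus.items() if g != k], dtype=float)
    if not np.all(np.isfinite(others)) or not np.isfinite(mu_k):
        raise ValidationError("group means must be finite")
    lo, hi = others.min(), others.max()
    delta_k = min(abs(mu_k - lo), abs(mu_k - hi))
    delta_prime_k = abs(hi - lo)
    fc_k = delta_k - delta_prime_k
    if mu_k > hi:
        direction = "up"
    elif mu_k < lo:
        direction = "down"
    else:
        direction = "none"
    return float(delta_k), float(delta_prime_k), float(fc_k), direction


def _group_means(
    expr: ExpressionMatrix, labels: SubtypeAssignment
) -> tuple[dict[int, np.ndarray], list[int]]:
    """Per-group mean expression vectors: subtypes 1..K plus normals (key 0)."""
    means: dict[int, np.ndarray] = {}
    for k in range(1, labels.K + 1):
        cols = expr.sample_cols(labels.members(k))
        means[k] = expr.values[:, cols].mean(axis=1)
    normal_cols = [j for j, c in enumerate(expr.sample_class) if c == "normal"]
    if normal_cols:
        means[NORMAL_GROUP] = expr.values[:, normal_cols].mean(axis=1)
    return means, sorted(means)


def detect_signature(
    expr: ExpressionMatrix,
    labels: SubtypeAssignment,
    fct: float = 1.0,
    alpha: float = 0.05,
    prior_df: float | None = None,
) -> SignatureResult:
    """Call subtype signatures on the full expression matrix.

    For each subtype *k*, ``S_k`` collects the genes with BH-adjusted
    p-value below ``alpha`` in the *k*-vs-rest moderated test, a strict
    up/down direction over all other group means (other subtypes and the
    normal group), and subtype-specific fold change ``FC_k`` strictly above
    ``fct``.
    """
    if fct < 0:
        raise ValidationError("fct must be >= 0")
    if not (0 < alpha < 1):
        raise ValidationError("alpha must be in (0, 1)")
    missing = set(labels.labels) - set(expr.sample_ids)
    if missing:
        raise ValidationError(f"labeled samples absent from matrix: {sorted(missing)}")
    means, group_keys = _group_means(expr, labels)
    if len(group_keys) < 2:
        raise ValidationError(
            "specificity needs at least 2 groups (add normals or more subtypes)"
        )
    mu_mat = np.column_stack([means[g] for g in group_keys])  # genes × groups
    rows: list[pd.DataFrame] = []
    signatures: dict[int, GeneSet] = {}
    for k in range(1, labels.K + 1):
        de = moderated_de_test(expr, labels, k, prior_df=prior_df)
        p_adj = bh_adjust(de["p_raw"].to_numpy())
        k_col = group_keys.index(k)
        other_cols = [j for j in range(len(group_keys)) if j != k_col]
        mu_k = mu_mat[:, k_col]
        others = mu_mat[:, other_cols]
        lo, hi = others.min(axis=1), others.max(axis=1)
        delta_k = np.minimum(np.abs(mu_k - lo), np.abs(mu_k - hi))
        delta_prime = np.abs(hi - lo)
        fc = delta_k - delta_prime
        direction = np.where(mu_k > hi, "up", np.where(mu_k < lo, "down", "none"))
        in_sig = (p_adj < alpha) & (direction != "none") & (fc > fct)
        sel = np.flatnonzero(in_sig)
        signatures[k] = GeneSet(
            {expr.gene_ids[i] for i in sel},
            {expr.gene_ids[i]: str(direction[i]) for i in sel},
        )
        rows.append(
            pd.DataFrame(
                {
                    "gene": expr.gene_ids,
                    "subtype": k,
                    "mu_k": mu_k,
                    "delta_k": delta_k,
                    "delta_prime_k": delta_prime,
                    "fc_k": fc,
                    "t_stat": de["t_stat"].to_numpy(),
                    "p_raw": de["p_raw"].to_numpy(),
                    "p_adj": p_adj,
                    "direction": direction,
                    "in_signature": in_sig,
                }
            )
        )
    stats_df = pd.concat(rows, ignore_index=True)
    phi = set().union(*(s.gene_ids for s in signatures.values()))
    return SignatureResult(signatures, phi, stats_df, fct=fct, alpha=alpha)
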