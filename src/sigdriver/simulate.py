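"""Synthetic testbeds with planted ground truth.

Two generators:

* :func:`generate_driver_testbed` — the driver-ranking testbed: an i.i.d.
  standard-Gaussian expression matrix in which the first block of genes
  plays the signature, the next block the CNA candidates, and the rest are
  non-signature-non-candidate (NSNC) background.  Dependencies are planted
  by updating each signature gene j with

      x̃_j = Σ_i w_i c_ij x_i + x_j,

  where x_i is the *initialized* expression of candidate i, c_ij ~ U(0,1)
  is the regulating potential of candidate i on signature gene j, and the
  per-candidate weights w_i follow one of four regimes: U[−1,0], U[0,1],
  identically 0, or U[−1,1].  NSNC genes are left untouched and serve as
  the empirical null when evaluating driver potentials.

* :func:`generate_subtype_testbed` — planted multi-subtype structure for
  the subtyping pipeline: Gaussian background with disjoint per-subtype
  signature blocks, half up-shifted and half down-shifted only in that
  subtype's tumors, plus unshifted normal controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import NORMAL, TUMOR, ExpressionMatrix, SubtypeAssignment, ValidationError

REGIMES = {
    "neg": (-1.0, 0.0),
    "pos": (0.0, 1.0),
    "zero": None,
    "mixed": (-1.0, 1.0),
}


@dataclass
class DriverTestbedTruth:
    """Planted parameters of one driver testbed draw."""

    n_genes: int
    n_cases: int
    signature_idx: np.ndarray
    candidate_idx: np.ndarray
    nsnc_idx: np.ndarray
    w: np.ndarray  # per-candidate weight, length L
    c: np.ndarray  # candidate × signature regulating potentials, U(0,1)
    regime: str
    seed: int

    @property
    def signature_genes(self) -> list[str]:
        return [f"G{i + 1:05d}" for i in self.signature_idx]

    @property
    def candidate_genes(self) -> list[str]:
        return [f"G{i + 1:05d}" for i in self.candidate_idx]

    @property
    def nsnc_genes(self) -> list[str]:
        return [f"G{i + 1:05d}" for i in self.nsnc_idx]


@dataclass
class SubtypeTestbedTruth:
    """Planted parameters of one subtype testbed draw."""

    labels: SubtypeAssignment
    signature_blocks: dict[int, dict[str, str]]  # subtype -> gene -> up/down
    n_normals: int
    shift: float
    noise_sd: float
    seed: int


def generate_driver_testbed(
    n_genes: int = 10_000,
    n_cases: int = 100,
    n_signature: int = 100,
    n_candidates: int = 200,
    regime: str = "pos",
    seed: int = 0,
) -> tuple[ExpressionMatrix, DriverTestbedTruth]:
    """Generate the planted-dependency driver testbed.

    Defaults are the full-scale testbed (10,000 genes × 100 cases with 100
    signature and 200 candidate genes); pass e.g. ``n_genes=1000,
    n_signature=50, n_candidates=100`` for a fast scaled-down version.
    All samples are flagged tumor.
    """
    if regime not in REGIMES:
        raise ValidationError(f"unknown regime {regime!r}; choose from {sorted(REGIMES)}")
    if n_signature + n_candidates > n_genes:
        raise ValidationError("n_signature + n_candidates must not exceed n_genes")
    if n_cases < 3:
        raise ValidationError("n_cases must be >= 3")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_genes, n_cases))
    sig_idx = np.arange(n_signature)
    cand_idx = np.arange(n_signature, n_signature + n_candidates)
    nsnc_idx = np.arange(n_signature + n_candidates, n_genes)
    bounds = REGIMES[regime]
    if bounds is None:
        w = np.zeros(n_candidates)
    else:
        w = rng.uniform(bounds[0], bounds[1], size=n_candidates)
    c = rng.uniform(0.0, 1.0, size=(n_candidates, n_signature))
    # x̃_j = Σ_i w_i c_ij x_i + x_j, using the candidates' initialized values
    x[sig_idx, :] = (w[:, None] * c).T @ x[cand_idx, :] + x[sig_idx, :]
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    sample_ids = [f"S{j + 1:03d}" for j in range(n_cases)]
    expr = ExpressionMatrix(gene_ids, sample_ids, x, [TUMOR] * n_cases)
    truth = DriverTestbedTruth(
        n_genes=n_genes,
        n_cases=n_cases,
        signature_idx=sig_idx,
        candidate_idx=cand_idx,
        nsnc_idx=nsnc_idx,
        w=w,
        c=c,
        regime=regime,
        seed=seed,
    )
    return expr, truth


def generate_subtype_testbed(
    n_subtypes: int = 3,
    tumors_per_subtype: int = 20,
    n_normals: int = 10,
    n_genes: int = 2000,
    sig_block_size: int = 50,
    shift: float = 3.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SubtypeTestbedTruth]:
    """Generate planted-subtype expression data with normal controls.

    Background is N(0, noise_sd²).  Subtype k's signature block (disjoint
    across subtypes) is shifted by +shift in its first half and −shift in
    its second half, in subtype-k tumors only; normals stay unshifted.
    """
    if n_subtypes < 1:
        raise ValidationError("n_subtypes must be >= 1")
    if n_subtypes * sig_block_size > n_genes:
        raise ValidationError("signature blocks exceed the gene count")
    if shift == 0:
        raise ValidationError("shift must be nonzero")
    if tumors_per_subtype < 2:
        raise ValidationError("need at least 2 tumors per subtype")
    rng = np.random.default_rng(seed)
    n_tumors = n_subtypes * tumors_per_subtype
    n_samples = n_tumors + n_normals
    x = rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    tumor_ids = [f"T{j + 1:03d}" for j in range(n_tumors)]
    normal_ids = [f"N{j + 1:03d}" for j in range(n_normals)]
    labels = {}
    blocks: dict[int, dict[str, str]] = {}
    for k in range(1, n_subtypes + 1):
        cols = np.arange((k - 1) * tumors_per_subtype, k * tumors_per_subtype)
        for j in cols:
            labels[tumor_ids[j]] = k
        rows = np.arange((k - 1) * sig_block_size, k * sig_block_size)
        half = sig_block_size // 2
        x[np.ix_(rows[:half], cols)] += shift
        x[np.ix_(rows[half:], cols)] -= shift
        blocks[k] = {
            gene_ids[i]: ("up" if pos < half else "down") for pos, i in enumerate(rows)
        }
    expr = ExpressionMatrix(
        gene_ids,
        tumor_ids + normal_ids,
        x,
        [TUMOR] * n_tumors + [NORMAL] * n_normals,
    )
    truth = SubtypeTestbedTruth(
        labels=SubtypeAssignment(labels, K=n_subtypes),
        signature_blocks=blocks,
        n_normals=n_normals,
        shift=shift,
        noise_sd=noise_sd,
        seed=seed,
    )
    return expr, truth
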