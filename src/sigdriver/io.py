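"""Core domain types and tab-delimited I/O.

The central container is :class:`ExpressionMatrix`, a log2-scale genes ×
samples matrix with per-sample tumor/normal annotation.  The orientation is
fixed as genes in rows and samples in columns throughout the package, and
the public API is explicit about it to avoid the transposition ambiguity
common in the expression-analysis literature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TUMOR = "tumor"
NORMAL = "normal"


class ValidationError(ValueError):
    """Raised when an input violates a domain-type invariant."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed into a domain type."""


@dataclass
class ExpressionMatrix:
    """Log2-scale expression matrix, genes × samples, with class annotation.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per row.
    sample_ids
        Unique sample identifiers, one per column.
    values
        Real matrix of shape ``(len(gene_ids), len(sample_ids))`` holding
        log2 expression; all entries must be finite.
    sample_class
        Per-sample flag, ``"tumor"`` or ``"normal"``.  Normal samples are
        never clustered but participate in signature detection.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    sample_class: list[str]

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        self.sample_class = [str(c) for c in self.sample_class]
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample identifiers")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must all be finite")
        bad = set(self.sample_class) - {TUMOR, NORMAL}
        if bad:
            raise ValidationError(f"unknown sample classes: {sorted(bad)}")
        if len(self.sample_class) != len(self.sample_ids):
            raise ValidationError("sample_class length mismatch")
        if sum(c == TUMOR for c in self.sample_class) < 2:
            raise ValidationError("need at least 2 tumor samples")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._sample_index = {s: j for j, s in enumerate(self.sample_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def tumor_mask(self) -> np.ndarray:
        return np.array([c == TUMOR for c in self.sample_class])

    @property
    def tumor_sample_ids(self) -> list[str]:
        return [s for s, c in zip(self.sample_ids, self.sample_class) if c == TUMOR]

    @property
    def normal_sample_ids(self) -> list[str]:
        return [s for s, c in zip(self.sample_ids, self.sample_class) if c == NORMAL]

    def gene_rows(self, gene_ids: Iterable[str]) -> np.ndarray:
        """Row indices for the given gene ids (order preserved)."""
        try:
            return np.array([self._gene_index[g] for g in gene_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in matrix") from None

    def sample_cols(self, sample_ids: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._sample_index[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in matrix") from None

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        rows = self.gene_rows(gene_ids)
        return ExpressionMatrix(
            [self.gene_ids[i] for i in rows],
            list(self.sample_ids),
            self.values[rows, :],
            list(self.sample_class),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SubtypeAssignment:
    """Mapping of tumor sample id → subtype label in ``1..K``.

    Labels must form a contiguous range ``1..K``; normal samples never
    appear.
    """

    labels: dict[str, int]
    K: int

    def __post_init__(self) -> None:
        self.labels = {str(s): int(v) for s, v in self.labels.items()}
        if self.K < 1:
            raise ValidationError("K must be >= 1")
        seen = set(self.labels.values())
        if seen != set(range(1, self.K + 1)):
            raise ValidationError(
                f"labels must cover the contiguous range 1..{self.K}, got {sorted(seen)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels)

    def as_array(self, sample_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.labels[s] for s in sample_ids], dtype=int)

    def members(self, k: int) -> list[str]:
        return [s for s, v in self.labels.items() if v == k]

    def sizes(self) -> dict[int, int]:
        out = {k: 0 for k in range(1, self.K + 1)}
        for v in self.labels.values():
            out[v] += 1
        return out

    def partition(self) -> frozenset[frozenset[str]]:
        """Label-free view of the clustering, for convergence comparison."""
        return frozenset(frozenset(self.members(k)) for k in range(1, self.K + 1))


@dataclass
class GeneSet:
    """A set of gene ids with an optional per-gene up/down direction."""

    gene_ids: set[str]
    direction: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = {str(g) for g in self.gene_ids}
        bad = set(self.direction) - self.gene_ids
        if bad:
            raise ValidationError(f"direction given for genes outside the set: {sorted(bad)}")
        bad_dir = set(self.direction.values()) - {"up", "down"}
        if bad_dir:
            raise ValidationError(f"invalid directions: {sorted(bad_dir)}")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene: str) -> bool:
        return gene in self.gene_ids

    def sorted(self) -> list[str]:
        return sorted(self.gene_ids)


def read_expression_matrix(
    path: str | Path,
    class_file: str | Path | None = None,
    class_column: str = "class",
) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix (gene rows, sample columns).

    The first column holds gene ids and the header row holds sample ids.
    Duplicate gene rows are collapsed by their mean with a logged warning.
    An optional companion TSV (columns ``sample`` and *class_column*)
    assigns tumor/normal per sample; by default all samples are tumor.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dups = sorted({s for s in header if header.count(s) > 1})
        raise ValidationError(f"duplicate sample ids in {path.name}: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna() | df.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric cell in {path.name} at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r}: {df.iat[i, j]!r}"
        )
    if numeric.index.duplicated().any():
        dup_genes = sorted(set(numeric.index[numeric.index.duplicated()]))
        logger.warning(
            "collapsing %d duplicated gene id(s) by mean: %s%s",
            len(dup_genes), ", ".join(dup_genes[:5]), "..." if len(dup_genes) > 5 else "",
        )
        numeric = numeric.groupby(level=0, sort=False).mean()
    sample_ids = [str(s) for s in numeric.columns]
    classes = [TUMOR] * len(sample_ids)
    if class_file is not None:
        cls = read_sample_classes(class_file, class_column)
        classes = [cls.get(s, TUMOR) for s in sample_ids]
    return ExpressionMatrix(
        [str(g) for g in numeric.index], sample_ids, numeric.to_numpy(dtype=float), classes
    )


def read_sample_classes(path: str | Path, class_column: str = "class") -> dict[str, str]:
    """Read a two-column TSV mapping sample id → tumor/normal."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df.columns or class_column not in df.columns:
        raise ParseError(f"class file must have columns 'sample' and {class_column!r}")
    out = {}
    for _, row in df.iterrows():
        c = row[class_column].strip().lower()
        if c not in (TUMOR, NORMAL):
            raise ParseError(f"unknown class {row[class_column]!r} for sample {row['sample']!r}")
        out[str(row["sample"])] = c
    return out


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene")


def read_gene_list(path: str | Path) -> GeneSet:
    """Read a plain-text gene list, one id per line; ``#`` starts a comment."""
    genes: set[str] = set()
    for line in Path(path).read_text().splitlines():
        token = line.split("#", 1)[0].strip()
        if token:
            genes.add(token)
    return GeneSet(genes)


def read_labels(path: str | Path) -> SubtypeAssignment:
    """Read a TSV with columns ``sample`` and ``subtype`` (integers 1..K)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df.columns or "subtype" not in df.columns:
        raise ParseError("label file must have columns 'sample' and 'subtype'")
    labels = {str(r["sample"]): int(r["subtype"]) for _, r in df.iterrows()}
    return SubtypeAssignment(labels, K=max(labels.values()))


def write_labels(labels: SubtypeAssignment, path: str | Path) -> None:
    df = pd.DataFrame(
        {"sample": list(labels.labels), "subtype": list(labels.labels.values())}
    )
    write_table(df, path)


def write_table(records: pd.DataFrame | Sequence[Mapping], path: str | Path) -> None:
    """Write a result table as TSV with header.

    Accepts a DataFrame or a sequence of mappings; an empty table with known
    columns yields a header-only file.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def top_variance_genes(expr: ExpressionMatrix, fraction: float = 0.10) -> GeneSet:
    """Select the ``ceil(fraction * n_genes)`` genes of largest variance.

    Variance is computed over tumor samples only, since the selected genes
    feed the clustering of tumors.  Ties at the cutoff are broken
    deterministically in favor of the lexicographically smaller gene id.
    """
    if not (0 < fraction <= 1):
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    tumor = expr.values[:, expr.tumor_mask]
    variances = tumor.var(axis=1, ddof=1)
    if np.allclose(variances, variances[0]):
        logger.warning("all genes have (near-)equal variance; selection falls back to gene id order")
    n_keep = math.ceil(fraction * expr.n_genes)
    # sort by (-variance, gene id): descending variance, lexicographic tie-break
    order = sorted(range(expr.n_genes), key=lambda i: (-variances[i], expr.gene_ids[i]))
    return GeneSet({expr.gene_ids[i] for i in order[:n_keep]})
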