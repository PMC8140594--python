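"""Expression-profile loading and Pearson co-expression similarity networks.

Expression similarity is the evidence layer of the bilayer network: under the
ceRNA hypothesis, lncRNAs with correlated expression across tissues tend to
share miRNA partners, so the pairwise Pearson correlation of z-scored
expression profiles is used as an edge weight between RNAs of the same class
(the lncRNA similarity network and the miRNA similarity network).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SimilarityNetwork",
    "load_expression",
    "standardize",
    "pearson_similarity",
]


@dataclass
class ExpressionMatrix:
    """Expression values for one RNA class: rows are RNAs, columns conditions.

    Parameters
    ----------
    rna_ids
        Unique RNA identifiers, one per row.
    condition_ids
        Tissue / cell-line labels, one per column.
    values
        Real matrix of shape ``(len(rna_ids), len(condition_ids))`` with all
        entries finite. Units are whatever the source database reports;
        no cross-condition normalisation is applied.
    """

    rna_ids: list[str]
    condition_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, m = self.values.shape
        if n != len(self.rna_ids):
            raise ValueError(f"{len(self.rna_ids)} RNA ids for {n} rows")
        if m != len(self.condition_ids):
            raise ValueError(f"{len(self.condition_ids)} condition ids for {m} columns")
        if m < 2:
            raise ValueError("need at least 2 conditions (correlation undefined)")
        if len(set(self.rna_ids)) != len(self.rna_ids):
            raise ValueError("duplicate RNA ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_rna(self) -> int:
        return len(self.rna_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)


@dataclass
class SimilarityNetwork:
    """Symmetric weighted co-expression network over one RNA class.

    Weights are Pearson correlations in [-1, 1]; the diagonal is fixed at 0
    so that self-similarity never enters the link structure seen by the
    perturbation method.
    """

    node_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.node_ids)
        if self.weights.shape != (n, n):
            raise ValueError(f"weights shape {self.weights.shape} != ({n}, {n})")
        if len(set(self.node_ids)) != n:
            raise ValueError("duplicate node ids")
        if not np.array_equal(self.weights, self.weights.T):
            raise ValueError("weights must be exactly symmetric")
        if np.any(np.diagonal(self.weights) != 0.0):
            raise ValueError("diagonal must be exactly 0")
        if np.any(np.abs(self.weights) > 1.0 + 1e-12):
            raise ValueError("weights must lie in [-1, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def load_expression(
    path: str | Path,
    id_filter: Iterable[str] | None = None,
    delimiter: str | None = None,
) -> ExpressionMatrix:
    """Read a delimited expression table (header = conditions, col 0 = RNA ids).

    Rows containing any missing value are dropped (with a logged warning), and
    duplicate RNA ids are collapsed to their first occurrence. If ``id_filter``
    is given, only rows whose id is in the set are kept, in file order.

    Raises
    ------
    ValueError
        If a row has the wrong field count (the line number is reported), or
        if no usable profiles remain after filtering.
    """
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, header=0, index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # pandas names the offending line
        raise ValueError(f"malformed expression file {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ValueError(f"no condition columns in {path}")

    values = df.apply(pd.to_numeric, errors="coerce")

    n_dup = df.index.duplicated(keep="first").sum()
    if n_dup:
        logger.warning("%s: collapsed %d duplicate RNA ids (kept first)", path, n_dup)
        keep = ~df.index.duplicated(keep="first")
        values = values.loc[keep]

    incomplete = values.isna().any(axis=1)
    if incomplete.any():
        logger.warning("%s: dropped %d rows with missing values", path, int(incomplete.sum()))
        values = values.loc[~incomplete]

    if id_filter is not None:
        wanted = set(id_filter)
        values = values.loc[[i in wanted for i in values.index]]

    if values.shape[0] == 0:
        raise ValueError(f"no usable profiles in {path} after filtering")

    return ExpressionMatrix(
        rna_ids=[str(i) for i in values.index],
        condition_ids=[str(c) for c in values.columns],
        values=values.to_numpy(dtype=float),
    )


def standardize(em: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each profile across conditions (mean 0, population sd 1).

    Rows with zero variance carry no correlation information and are removed
    with a logged warning. The transform is idempotent up to floating error,
    and leaves pairwise Pearson correlations unchanged.

    Raises
    ------
    ValueError
        If every row has zero variance ("degenerate expression matrix").
    """
    sd = em.values.std(axis=1, ddof=0)
    degenerate = sd == 0.0
    if degenerate.all():
        raise ValueError("degenerate expression matrix: all rows have zero variance")
    if degenerate.any():
        logger.warning("standardize: removed %d zero-variance rows", int(degenerate.sum()))
    keep = ~degenerate
    vals = em.values[keep]
    z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=0, keepdims=True)
    return ExpressionMatrix(
        rna_ids=[r for r, k in zip(em.rna_ids, keep) if k],
        condition_ids=list(em.condition_ids),
        values=z,
    )


def pearson_similarity(em: ExpressionMatrix, clip_negative: bool = False) -> SimilarityNetwork:
    """Pairwise Pearson correlation network of expression profiles.

    The diagonal is set to 0 (no self-loops) and the matrix is mirrored from
    its upper triangle so symmetry is exact, not merely within tolerance.
    Negative correlations are kept as signed weights by default;
    ``clip_negative=True`` zeroes them for sensitivity analyses.

    Raises
    ------
    ValueError
        If fewer than 2 rows remain, or any row has zero variance (such rows
        must be removed by :func:`standardize` first).
    """
    if em.n_rna < 2:
        raise ValueError("need at least 2 profiles for a similarity network")
    if np.any(em.values.std(axis=1) == 0.0):
        raise ValueError("zero-variance row in expression matrix; standardize first")
    corr = np.corrcoef(em.values)
    np.clip(corr, -1.0, 1.0, out=corr)
    upper = np.triu(corr, k=1)
    weights = upper + upper.T  # exact symmetry, zero diagonal
    if clip_negative:
        weights[weights < 0.0] = 0.0
    return SimilarityNetwork(node_ids=list(em.rna_ids), weights=weights)
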