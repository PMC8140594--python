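"""Known-interaction loading and bilayer block-adjacency assembly.

The bilayer network stacks three layers into one symmetric block matrix

    A = [[ LS ,  LM ],
         [ LM.T, MS ]]

where LS and MS are the lncRNA and miRNA co-expression similarity networks
and LM is the binary known-interaction matrix. Nodes are ordered lncRNAs
first (indices ``0..n_lnc-1``) then miRNAs; all downstream layer masks rely
on that ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .similarity import ExpressionMatrix, SimilarityNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "BilayerNetwork",
    "load_interactions",
    "build_bilayer",
    "interaction_block",
    "align_networks",
]

# tokens that mark an optional header row in a 2-column edge list
_HEADER_TOKENS = {
    "lncrna", "mirna", "lnc", "mi", "lnc_id", "mi_id", "lncrna_id",
    "mirna_id", "source", "target", "id1", "id2",
}


@dataclass
class InteractionNetwork:
    """Binary bipartite lncRNA x miRNA interaction matrix."""

    lnc_ids: list[str]
    mi_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.lnc_ids), len(self.mi_ids)):
            raise ValueError("interaction matrix shape does not match id lists")
        if len(set(self.lnc_ids)) != len(self.lnc_ids):
            raise ValueError("duplicate lncRNA ids")
        if len(set(self.mi_ids)) != len(self.mi_ids):
            raise ValueError("duplicate miRNA ids")
        if not np.isin(self.matrix, (0.0, 1.0)).all():
            raise ValueError("interaction entries must be 0 or 1")
        if self.matrix.sum() < 1:
            raise ValueError("interaction network has no links")

    @property
    def n_links(self) -> int:
        return int(self.matrix.sum())


@dataclass
class BilayerNetwork:
    """The N x N block adjacency matrix with layer bookkeeping.

    ``A`` is exactly symmetric; its upper-right ``n_lnc x n_mi`` block is the
    (possibly re-weighted) interaction matrix and the two diagonal blocks are
    the similarity layers with zero diagonal.
    """

    A: np.ndarray
    n_lnc: int
    n_mi: int
    node_ids: list[str]
    lm_weight: float = 1.0

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        N = self.n_lnc + self.n_mi
        if self.A.shape != (N, N):
            raise ValueError(f"A has shape {self.A.shape}, expected ({N}, {N})")
        if len(self.node_ids) != N:
            raise ValueError("node_ids length does not match matrix size")
        if not np.array_equal(self.A, self.A.T):
            raise ValueError("A must be exactly symmetric")
        if np.any(np.diagonal(self.A) != 0.0):
            raise ValueError("A must have zero diagonal")
        block = self.A[: self.n_lnc, self.n_lnc :]
        if not np.isin(block, (0.0, self.lm_weight)).all():
            raise ValueError("interaction block entries must be 0 or lm_weight")

    @property
    def N(self) -> int:
        return self.n_lnc + self.n_mi

    @property
    def lnc_ids(self) -> list[str]:
        return self.node_ids[: self.n_lnc]

    @property
    def mi_ids(self) -> list[str]:
        return self.node_ids[self.n_lnc :]

    @property
    def lnc_slice(self) -> slice:
        return slice(0, self.n_lnc)

    @property
    def mi_slice(self) -> slice:
        return slice(self.n_lnc, self.N)


def load_interactions(path: str | Path, delimiter: str | None = None) -> InteractionNetwork:
    """Read a 2-column (lncRNA id, miRNA id) edge list into a binary matrix.

    Duplicate pairs are collapsed; axis orders follow first appearance in the
    file. A header row is detected when its fields match common column-name
    tokens and never recur as data.

    Raises
    ------
    ValueError
        On an empty file, a self-pair (same id in both columns), or a row
        without exactly two fields.
    """
    path = Path(path)
    sep = "," if (delimiter is None and path.suffix.lower() == ".csv") else (delimiter or "\t")
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split(sep)
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
            a, b = fields[0].strip(), fields[1].strip()
            if lineno == 1 and (a.lower() in _HEADER_TOKENS or b.lower() in _HEADER_TOKENS):
                continue
            if a == b:
                raise ValueError(f"{path}:{lineno}: self-pair {a!r}")
            pairs.append((a, b))
    if not pairs:
        raise ValueError(f"empty interaction file {path}")

    seen: set[tuple[str, str]] = set()
    lnc_ids: list[str] = []
    mi_ids: list[str] = []
    lnc_pos: dict[str, int] = {}
    mi_pos: dict[str, int] = {}
    edges: list[tuple[int, int]] = []
    for a, b in pairs:
        if (a, b) in seen:
            continue
        seen.add((a, b))
        if a not in lnc_pos:
            lnc_pos[a] = len(lnc_ids)
            lnc_ids.append(a)
        if b not in mi_pos:
            mi_pos[b] = len(mi_ids)
            mi_ids.append(b)
        edges.append((lnc_pos[a], mi_pos[b]))

    matrix = np.zeros((len(lnc_ids), len(mi_ids)))
    rows, cols = zip(*edges)
    matrix[rows, cols] = 1.0
    logger.info("%s: %d unique interactions over %d lncRNAs x %d miRNAs",
                path, len(edges), len(lnc_ids), len(mi_ids))
    return InteractionNetwork(lnc_ids=lnc_ids, mi_ids=mi_ids, matrix=matrix)


def build_bilayer(
    ls: SimilarityNetwork,
    ms: SimilarityNetwork,
    lm: InteractionNetwork,
    lm_weight: float = 1.0,
) -> BilayerNetwork:
    """Assemble the symmetric block adjacency from aligned layer networks.

    ``ls.node_ids`` must equal ``lm.lnc_ids`` and ``ms.node_ids`` must equal
    ``lm.mi_ids`` in the same order (use :func:`align_networks` first).
    ``lm_weight`` rescales the binary interaction block relative to the
    real-valued similarity blocks (default 1.0: no rescaling).
    """
    if ls.node_ids != lm.lnc_ids:
        bad = next(
            (a for a, b in zip(ls.node_ids, lm.lnc_ids) if a != b),
            ls.node_ids[len(lm.lnc_ids):][:1] or lm.lnc_ids[len(ls.node_ids):][:1],
        )
        raise ValueError(f"unaligned networks: lncRNA ids differ at {bad!r}")
    if ms.node_ids != lm.mi_ids:
        bad = next(
            (a for a, b in zip(ms.node_ids, lm.mi_ids) if a != b),
            ms.node_ids[len(lm.mi_ids):][:1] or lm.mi_ids[len(ms.node_ids):][:1],
        )
        raise ValueError(f"unaligned networks: miRNA ids differ at {bad!r}")

    block = lm.matrix * lm_weight
    A = np.block([[ls.weights, block], [block.T, ms.weights]])
    return BilayerNetwork(
        A=A,
        n_lnc=len(lm.lnc_ids),
        n_mi=len(lm.mi_ids),
        node_ids=list(lm.lnc_ids) + list(lm.mi_ids),
        lm_weight=lm_weight,
    )


def interaction_block(bn: BilayerNetwork, scores: np.ndarray) -> np.ndarray:
    """Extract the lncRNA x miRNA block of any N x N matrix aligned with ``bn``."""
    scores = np.asarray(scores)
    if scores.shape != (bn.N, bn.N):
        raise ValueError(f"scores shape {scores.shape} != ({bn.N}, {bn.N})")
    return scores[bn.lnc_slice, bn.mi_slice]


def align_networks(
    lnc_em: ExpressionMatrix,
    mi_em: ExpressionMatrix,
    lm: InteractionNetwork,
) -> tuple[ExpressionMatrix, ExpressionMatrix, InteractionNetwork]:
    """Restrict all three inputs to RNAs with both a profile and an interaction row.

    The interaction network's first-appearance order defines the node order;
    RNAs lacking an expression profile are dropped from the interaction axes
    (and vice versa), mirroring the id-matching step applied to the source
    databases.
    """
    lnc_keep = [i for i in lm.lnc_ids if i in set(lnc_em.rna_ids)]
    mi_keep = [i for i in lm.mi_ids if i in set(mi_em.rna_ids)]
    if not lnc_keep or not mi_keep:
        raise ValueError("no RNAs shared between expression profiles and interactions")

    def _subset(em: ExpressionMatrix, order: list[str]) -> ExpressionMatrix:
        pos = {r: k for k, r in enumerate(em.rna_ids)}
        idx = [pos[i] for i in order]
        return ExpressionMatrix(order, list(em.condition_ids), em.values[idx])

    li = [lm.lnc_ids.index(i) for i in lnc_keep]
    mi = [lm.mi_ids.index(i) for i in mi_keep]
    sub = lm.matrix[np.ix_(li, mi)]
    if sub.sum() < 1:
        raise ValueError("no interactions left after id matching")
    return (
        _subset(lnc_em, lnc_keep),
        _subset(mi_em, mi_keep),
        InteractionNetwork(lnc_keep, mi_keep, sub),
    )
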