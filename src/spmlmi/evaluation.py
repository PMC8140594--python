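"""k-fold cross-validation of interaction prediction with ROC/AUC.

Protocol: the known interactions are split into k equal folds. For each
fold, its positives are reset to unknown in the interaction block (the
similarity layers, which derive from expression only, are untouched), the
score matrix is recomputed on the masked bilayer, and the held-out positives
are ranked against all entries that were unknown in the original network.
Known training positives are excluded from the evaluation universe. AUC uses
the rank (Mann-Whitney) form with half credit for ties, which equals the
trapezoidal area under the threshold-swept ROC curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .network import BilayerNetwork, InteractionNetwork, interaction_block
from .spm import as_rng, predict

logger = logging.getLogger(__name__)

__all__ = [
    "CVConfig",
    "CVResult",
    "kfold_split",
    "run_cv",
    "roc_auc",
    "top_fraction_tpr",
]


@dataclass
class CVConfig:
    """Cross-validation settings; defaults follow the method's standard use."""

    k: int = 5
    t: int = 8
    fraction: float = 0.1
    n_repeats: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        if self.t < 1:
            raise ValueError(f"t must be >= 1, got {self.t}")
        if self.n_repeats < 1:
            raise ValueError(f"n_repeats must be >= 1, got {self.n_repeats}")
        if not 0.0 < self.fraction < 1.0:
            raise ValueError(f"fraction must be in (0, 1), got {self.fraction}")


@dataclass
class CVResult:
    """Per-fold AUCs (all repeats concatenated), their mean/sd, ROC points."""

    auc_per_fold: np.ndarray
    auc_mean: float
    auc_sd: float
    roc_points: list[list[tuple[float, float]]] = field(default_factory=list)


def kfold_split(
    lm: InteractionNetwork,
    k: int,
    rng: np.random.Generator | int | None = None,
) -> list[np.ndarray]:
    """Partition the positive entries into k disjoint folds of near-equal size.

    Returns k arrays of (row, col) index pairs; sizes differ by at most one
    and their union is every positive entry.
    """
    pos = np.argwhere(lm.matrix == 1.0)
    if k > len(pos):
        raise ValueError(f"k={k} exceeds number of positives ({len(pos)})")
    rng = as_rng(rng)
    perm = rng.permutation(len(pos))
    return [pos[idx] for idx in np.array_split(perm, k)]


def roc_auc(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[list[tuple[float, float]], float]:
    """ROC curve and AUC with the midpoint (U-statistic) tie convention.

    AUC is computed from rank sums, which is exactly the probability that a
    random positive outscores a random negative with ties counting 1/2 —
    identical to the trapezoidal area under the ROC swept over all distinct
    thresholds.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("labels must contain at least one positive and one negative")

    ranks = stats.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    # threshold sweep over distinct scores, descending
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    tps = np.cumsum(labels[order] == 1)
    fps = np.cumsum(labels[order] == 0)
    boundary = np.nonzero(np.diff(sorted_scores))[0]
    idx = np.concatenate((boundary, [len(scores) - 1]))
    points = [(0.0, 0.0)] + [
        (fps[i] / n_neg, tps[i] / n_pos) for i in idx
    ]
    return points, float(auc)


def top_fraction_tpr(scores: np.ndarray, labels: np.ndarray, frac: float) -> float:
    """Share of positives recovered in the top ``round(frac * n)`` candidates.

    Candidates are ranked by score descending with stable (input-order)
    tie-breaking; the recovery protocol behind the top-1/k true-positive rate.
    """
    if not 0.0 < frac <= 1.0:
        raise ValueError(f"frac must be in (0, 1], got {frac}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    if n_pos == 0 or (labels == 0).sum() == 0:
        raise ValueError("labels must contain at least one positive and one negative")
    n_top = int(round(frac * len(scores)))
    top = np.argsort(-scores, kind="stable")[:n_top]
    return float((labels[top] == 1).sum() / n_pos)


def _mask_fold(bn: BilayerNetwork, fold: np.ndarray) -> BilayerNetwork:
    """Zero the fold's positives in both interaction blocks of a copy of A."""
    A = bn.A.copy()
    rows = fold[:, 0]
    cols = fold[:, 1] + bn.n_lnc
    A[rows, cols] = 0.0
    A[cols, rows] = 0.0
    return BilayerNetwork(
        A=A, n_lnc=bn.n_lnc, n_mi=bn.n_mi, node_ids=list(bn.node_ids),
        lm_weight=bn.lm_weight,
    )


def run_cv(
    bn: BilayerNetwork,
    cfg: CVConfig,
    keep_roc: bool = False,
    _predict=predict,
) -> CVResult:
    """Repeated k-fold cross-validation of the full prediction pipeline.

    Per fold: held-out positives are zeroed in the interaction block, the
    score matrix is recomputed on the masked bilayer, and AUC is taken over
    {held-out positives} ∪ {entries unknown in the original network}.
    ``cfg.n_repeats`` fresh partitions are run; ``auc_per_fold`` concatenates
    all repeats (k * n_repeats values).

    ``_predict`` is an injection point for scoring oracles in tests.
    """
    rng = as_rng(cfg.seed)
    lm_matrix = bn.A[bn.lnc_slice, bn.mi_slice]
    lm = InteractionNetwork(bn.lnc_ids, bn.mi_ids, (lm_matrix != 0.0).astype(float))
    neg_mask = lm.matrix == 0.0

    aucs: list[float] = []
    rocs: list[list[tuple[float, float]]] = []
    for _ in range(cfg.n_repeats):
        folds = kfold_split(lm, cfg.k, rng)
        for fold in folds:
            if len(fold) == 0:
                raise ValueError("fold with zero test positives")
            masked = _mask_fold(bn, fold)
            sm = _predict(masked, t=cfg.t, fraction=cfg.fraction,
                          rng=int(rng.integers(0, 2**31)))
            block = interaction_block(bn, sm.scores)
            pos_scores = block[fold[:, 0], fold[:, 1]]
            neg_scores = block[neg_mask]
            scores = np.concatenate((pos_scores, neg_scores))
            labels = np.concatenate(
                (np.ones(len(pos_scores), dtype=int), np.zeros(len(neg_scores), dtype=int))
            )
            points, auc = roc_auc(scores, labels)
            aucs.append(auc)
            if keep_roc:
                rocs.append(points)

    arr = np.asarray(aucs)
    return CVResult(
        auc_per_fold=arr,
        auc_mean=float(arr.mean()),
        auc_sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        roc_points=rocs,
    )
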