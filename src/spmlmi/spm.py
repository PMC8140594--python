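"""The structural perturbation method (SPM) for link prediction.

Given a symmetric adjacency A, remove a random fraction of its links (the
perturbation set dA, leaving the reduced matrix A_R = A - dA), eigendecompose
A_R = sum_k lambda_k x_k x_k^T, and estimate how each eigenvalue shifts when
the removed links are restored while holding the eigenvectors fixed:

    dlambda_k = x_k^T dA x_k / (x_k^T x_k)

The perturbed reconstruction

    A~ = sum_k (lambda_k + dlambda_k) x_k x_k^T

scores every node pair; entries that are not observed links but receive high
scores are the predicted missing links. Averaging A~ over t independent
perturbation draws gives the prediction (score) matrix.

For the bilayer lncRNA-miRNA network the perturbation set is stratified per
layer: the same fraction of links is removed independently from each
similarity layer and from the interaction layer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .network import BilayerNetwork, interaction_block

logger = logging.getLogger(__name__)

__all__ = [
    "PerturbationSample",
    "ScoreMatrix",
    "sample_perturbation",
    "first_order_perturb",
    "predict",
    "rank_candidates",
]

# eigenvalues closer than DEGENERACY_RTOL * max|lambda| share a subspace
DEGENERACY_RTOL = 1e-8


def as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    """Coerce a seed or generator into a numpy Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass
class PerturbationSample:
    """One random split A = A_R + dA of a symmetric adjacency.

    ``removed_edges`` holds the unordered index pairs (i < j) whose entries
    were moved wholly from A_R into dA; supports of A_R and dA are disjoint
    off the diagonal.
    """

    A_R: np.ndarray
    dA: np.ndarray
    removed_edges: list[tuple[int, int]]
    fraction: float


@dataclass
class ScoreMatrix:
    """Averaged perturbed reconstruction; entries rank candidate links."""

    scores: np.ndarray
    t: int
    fraction: float
    seed: int | None = None


def layer_link_pairs(bn: BilayerNetwork) -> dict[str, np.ndarray]:
    """Upper-triangle index pairs of the links in each layer of the bilayer.

    Similarity-layer links are the nonzero off-diagonal entries of the LS and
    MS blocks; interaction-layer links are the nonzero entries of the LM block.
    """
    A, n = bn.A, bn.n_lnc
    iu, ju = np.triu_indices(bn.N, k=1)
    nz = A[iu, ju] != 0.0
    iu, ju = iu[nz], ju[nz]
    ls = (iu < n) & (ju < n)
    ms = (iu >= n) & (ju >= n)
    lm = (iu < n) & (ju >= n)
    return {
        "LS": np.column_stack((iu[ls], ju[ls])),
        "MS": np.column_stack((iu[ms], ju[ms])),
        "LM": np.column_stack((iu[lm], ju[lm])),
    }


def sample_from_layers(
    A: np.ndarray,
    layers: dict[str, np.ndarray],
    fraction: float,
    rng: np.random.Generator | int | None = None,
) -> PerturbationSample:
    """Remove ``round(fraction * L)`` links independently from each layer.

    Empty layers are skipped; a layer whose removal count rounds to zero
    contributes one link (with a warning) so that every perturbed layer is
    actually perturbed.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    rng = as_rng(rng)
    A = np.asarray(A, dtype=float)
    dA = np.zeros_like(A)
    removed: list[tuple[int, int]] = []
    for name, pairs in layers.items():
        L = len(pairs)
        if L == 0:
            continue
        n_rm = int(round(fraction * L))
        if n_rm == 0:
            warnings.warn(
                f"layer {name}: fraction {fraction} rounds to 0 of {L} links; removing 1",
                stacklevel=2,
            )
            n_rm = 1
        take = rng.choice(L, size=n_rm, replace=False)
        for i, j in pairs[np.sort(take)]:
            dA[i, j] = A[i, j]
            dA[j, i] = A[j, i]
            removed.append((int(i), int(j)))
    A_R = A - dA
    return PerturbationSample(A_R=A_R, dA=dA, removed_edges=removed, fraction=fraction)


def sample_perturbation(
    bn: BilayerNetwork,
    fraction: float = 0.1,
    rng: np.random.Generator | int | None = None,
    per_layer: bool = True,
) -> PerturbationSample:
    """Draw a perturbation set from a bilayer network.

    With ``per_layer=True`` (default) the fraction applies independently to
    the lncRNA similarity layer, the miRNA similarity layer, and the
    interaction layer; with ``per_layer=False`` all links are pooled before
    sampling (ablation mode).
    """
    layers = layer_link_pairs(bn)
    if not per_layer:
        layers = {"pooled": np.concatenate([p for p in layers.values() if len(p)], axis=0)}
    return sample_from_layers(bn.A, layers, fraction, rng)


def _degenerate_groups(eigvals: np.ndarray) -> list[np.ndarray]:
    """Cluster ascending eigenvalues into near-degenerate groups."""
    tol = DEGENERACY_RTOL * np.max(np.abs(eigvals)) if eigvals.size else 0.0
    groups: list[np.ndarray] = []
    start = 0
    for k in range(1, eigvals.size + 1):
        if k == eigvals.size or eigvals[k] - eigvals[k - 1] > tol:
            groups.append(np.arange(start, k))
            start = k
    return groups


def first_order_perturb(
    ps: PerturbationSample,
    degenerate_handling: str = "subspace",
) -> np.ndarray:
    """First-order perturbed reconstruction A~ of A_R + dA.

    Eigenvectors of A_R are held fixed; each eigenvalue receives the
    first-order correction ``x_k^T dA x_k``. With ``degenerate_handling=
    "subspace"`` (default), eigenvalues equal within ``DEGENERACY_RTOL`` of
    the spectral radius are treated as one eigenspace: dA is diagonalised
    inside that subspace and the resulting rotated basis and shifts are used,
    which is the basis-independent form of the correction. ``"naive"``
    applies the per-vector formula regardless of degeneracy.
    """
    A_R, dA = ps.A_R, ps.dA
    if not np.allclose(A_R, A_R.T, atol=1e-12):
        raise ValueError("A_R must be symmetric")
    if degenerate_handling not in ("subspace", "naive"):
        raise ValueError(f"unknown degenerate_handling {degenerate_handling!r}")
    try:
        eigvals, X = np.linalg.eigh(A_R)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"eigendecomposition failed for {A_R.shape[0]}-node network: {exc}"
        ) from exc

    if degenerate_handling == "naive":
        shifts = np.einsum("ki,kl,li->i", X, dA, X)
    else:
        shifts = np.empty_like(eigvals)
        for grp in _degenerate_groups(eigvals):
            Xg = X[:, grp]
            W = Xg.T @ dA @ Xg
            if len(grp) == 1:
                shifts[grp[0]] = W[0, 0]
            else:
                w, U = np.linalg.eigh((W + W.T) / 2.0)
                X[:, grp] = Xg @ U
                shifts[grp] = w

    tilde = (X * (eigvals + shifts)) @ X.T
    return (tilde + tilde.T) / 2.0


def predict(
    bn: BilayerNetwork,
    t: int = 8,
    fraction: float = 0.1,
    rng: np.random.Generator | int | None = None,
    per_layer: bool = True,
    degenerate_handling: str = "subspace",
) -> ScoreMatrix:
    """Average t independent perturbed reconstructions of the full bilayer.

    Each of the t perturbations draws its own child seed from ``rng``, so a
    fixed top-level seed reproduces the score matrix bit-for-bit. Entries
    that are already links simply score near their observed weight; only
    non-link entries are candidates for prediction.
    """
    if t < 1:
        raise ValueError(f"t must be >= 1, got {t}")
    rng = as_rng(rng)
    child_seeds = rng.integers(0, 2**31, size=t)
    acc = np.zeros_like(bn.A)
    for seed in child_seeds:
        ps = sample_perturbation(bn, fraction, np.random.default_rng(int(seed)), per_layer)
        acc += first_order_perturb(ps, degenerate_handling)
    return ScoreMatrix(scores=acc / t, t=t, fraction=fraction)


def rank_candidates(
    bn: BilayerNetwork,
    sm: ScoreMatrix,
    query: str | None = None,
) -> list[tuple[str, str, float]]:
    """Rank unobserved lncRNA-miRNA pairs by prediction score, descending.

    Candidates are the zero entries of the interaction block. Ties break by
    (lncRNA index, miRNA index) ascending for determinism. With ``query``,
    only pairs involving that node (an lncRNA or miRNA id) are returned —
    the single-RNA case-study mode.
    """
    block = interaction_block(bn, sm.scores)
    known = bn.A[bn.lnc_slice, bn.mi_slice] != 0.0
    li, mj = np.where(~known)
    if query is not None:
        if query in set(bn.lnc_ids):
            keep = li == bn.lnc_ids.index(query)
        elif query in set(bn.mi_ids):
            keep = mj == bn.mi_ids.index(query)
        else:
            raise ValueError(f"query id {query!r} not in network")
        li, mj = li[keep], mj[keep]
    scores = block[li, mj]
    order = np.lexsort((mj, li, -scores))
    lnc_ids, mi_ids = bn.lnc_ids, bn.mi_ids
    return [(lnc_ids[li[k]], mi_ids[mj[k]], float(scores[k])) for k in order]
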