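"""Structural consistency: an intrinsic measure of link predictability.

A network is structurally consistent when the spectral features of a randomly
reduced copy still encode the removed links. Per repetition: remove a random
fraction of links (the perturbation set), build the first-order perturbed
reconstruction of the reduced matrix, rank all non-link entries of the
reduced matrix by score, and measure what fraction of the top-L entries are
the L removed links. The index sigma_c lies in [0, 1]; a density-matched
random graph sits near the small random-overlap baseline, while a network
whose links follow its spectral structure scores far above it.

Dense correlation networks have no exact non-links, so a similarity-only
network is sparsified first: only the strongest q% of |weights| are kept as
links. This thresholding step is an inferred preprocessing choice, exposed as
a parameter and documented as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .network import BilayerNetwork
from .similarity import SimilarityNetwork
from .spm import as_rng, first_order_perturb, layer_link_pairs, sample_from_layers

logger = logging.getLogger(__name__)

__all__ = [
    "ConsistencyResult",
    "sparsify",
    "structural_consistency",
    "compare_layers",
]


@dataclass
class ConsistencyResult:
    """Mean and spread of sigma_c over independent perturbation repetitions."""

    sigma_mean: float
    sigma_sd: float
    n_reps: int
    fraction: float
    per_rep: np.ndarray

    def __post_init__(self) -> None:
        self.per_rep = np.asarray(self.per_rep, dtype=float)
        if len(self.per_rep) != self.n_reps:
            raise ValueError("per_rep length must equal n_reps")
        if not 0.0 <= self.sigma_mean <= 1.0:
            raise ValueError("sigma_mean must lie in [0, 1]")


def sparsify(net: SimilarityNetwork, top_q: float) -> SimilarityNetwork:
    """Keep only the strongest ``top_q`` percent of |weights| as links.

    Applied to dense correlation networks before structural-consistency
    analysis so that a non-link candidate pool exists. ``top_q`` is a
    percentage of the off-diagonal pairs (default convention: 10).
    """
    if not 0.0 < top_q <= 100.0:
        raise ValueError(f"top_q must be in (0, 100], got {top_q}")
    n = net.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    vals = np.abs(net.weights[iu, ju])
    n_keep = max(1, int(round(top_q / 100.0 * len(vals))))
    order = np.argsort(-vals, kind="stable")
    keep = order[:n_keep]
    W = np.zeros_like(net.weights)
    W[iu[keep], ju[keep]] = net.weights[iu[keep], ju[keep]]
    W = W + W.T
    return SimilarityNetwork(node_ids=list(net.node_ids), weights=W)


def _as_layers(
    net: BilayerNetwork | SimilarityNetwork,
    sparsify_top_q: float | None,
) -> tuple[np.ndarray, dict[str, np.ndarray], int | None]:
    """Normalise either network type to (A, layer pair dict, n_lnc or None)."""
    if isinstance(net, BilayerNetwork):
        return net.A, layer_link_pairs(net), net.n_lnc
    if isinstance(net, SimilarityNetwork):
        if sparsify_top_q is not None:
            net = sparsify(net, sparsify_top_q)
        A = net.weights
        iu, ju = np.triu_indices(net.n_nodes, k=1)
        nz = A[iu, ju] != 0.0
        pairs = np.column_stack((iu[nz], ju[nz]))
        return A, {"links": pairs}, None
    raise TypeError(f"unsupported network type {type(net).__name__}")


def structural_consistency(
    net: BilayerNetwork | SimilarityNetwork,
    fraction: float = 0.1,
    n_reps: int = 10,
    rng: np.random.Generator | int | None = None,
    sparsify_top_q: float | None = None,
    interaction_only: bool = False,
    degenerate_handling: str = "subspace",
) -> ConsistencyResult:
    """Estimate sigma_c = |top-L scored non-links  ∩  removed links| / L.

    Parameters
    ----------
    net
        A bilayer network (per-layer stratified removal) or a single
        similarity network (``sparsify_top_q`` required if dense).
    fraction
        Proportion of links removed per layer each repetition (default 0.10).
    n_reps
        Independent repetitions; the result reports their mean and sd.
    sparsify_top_q
        For similarity-only networks: percentage of strongest |weights| kept
        as links before analysis. Ignored for bilayer networks.
    interaction_only
        Bilayer mode restricting the candidate pool (and the overlap) to the
        interaction block — ablation of the cross-layer candidate universe.

    Raises
    ------
    ValueError
        If no links exist, or the non-link candidate pool of a repetition is
        smaller than the number of removed links (for a dense similarity
        network: pass ``sparsify_top_q``).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = as_rng(rng)
    A, layers, n_lnc = _as_layers(net, sparsify_top_q)
    if all(len(p) == 0 for p in layers.values()):
        raise ValueError("network has no links to perturb")
    N = A.shape[0]
    iu, ju = np.triu_indices(N, k=1)
    if interaction_only:
        if n_lnc is None:
            raise ValueError("interaction_only requires a bilayer network")
        scope = (iu < n_lnc) & (ju >= n_lnc)
        iu, ju = iu[scope], ju[scope]

    sigmas = np.empty(n_reps)
    for r in range(n_reps):
        ps = sample_from_layers(A, layers, fraction, rng)
        removed = set(ps.removed_edges)
        if interaction_only:
            removed = {(i, j) for (i, j) in removed if i < n_lnc <= j}
        L = len(removed)
        if L == 0:
            raise ValueError("perturbation removed no links in scope")
        cand = ps.A_R[iu, ju] == 0.0
        ci, cj = iu[cand], ju[cand]
        if len(ci) <= L:  # == L means every candidate is a removed link: sigma is trivially 1
            raise ValueError(
                f"candidate pool ({len(ci)}) not larger than removed set ({L}); "
                "sparsify dense similarity networks first"
            )
        tilde = first_order_perturb(ps, degenerate_handling)
        scores = tilde[ci, cj]
        top = np.lexsort((cj, ci, -scores))[:L]
        hits = sum((int(ci[k]), int(cj[k])) in removed for k in top)
        sigmas[r] = hits / L

    sd = float(sigmas.std(ddof=1)) if n_reps > 1 else 0.0
    return ConsistencyResult(
        sigma_mean=float(sigmas.mean()),
        sigma_sd=sd,
        n_reps=n_reps,
        fraction=fraction,
        per_rep=sigmas,
    )


def compare_layers(
    ls: SimilarityNetwork,
    ms: SimilarityNetwork,
    bn: BilayerNetwork,
    fraction: float = 0.1,
    n_reps: int = 10,
    rng: np.random.Generator | int | None = None,
    sparsify_top_q: float = 10.0,
) -> dict[str, ConsistencyResult]:
    """Sigma_c for each single layer and for the bilayer, same protocol.

    The similarity layers are sparsified to their strongest ``sparsify_top_q``
    percent of weights (they are dense); the bilayer is analysed as built.
    Each network gets its own child seed derived from ``rng`` so the three
    analyses are independent but jointly reproducible.
    """
    rng = as_rng(rng)
    seeds = rng.integers(0, 2**31, size=3)
    return {
        "LSnet": structural_consistency(
            ls, fraction, n_reps, int(seeds[0]), sparsify_top_q=sparsify_top_q
        ),
        "MSnet": structural_consistency(
            ms, fraction, n_reps, int(seeds[1]), sparsify_top_q=sparsify_top_q
        ),
        "bilayer": structural_consistency(bn, fraction, n_reps, int(seeds[2])),
    }
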