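# Methods

## Model and assumptions

`spmlmi` treats lncRNA–miRNA interaction prediction as link prediction on a
heterogeneous *bilayer* network. The block adjacency

```
A = [ LSnet   LMnet ]      (lncRNA nodes first, indices 0..n_lnc-1,
    [ LMnetᵀ  MSnet ]       then miRNA nodes)
```

combines two real-valued co-expression similarity layers with one binary
interaction layer. The modelling assumptions are:

1. **Expression similarity is informative about interactions** (the ceRNA
   premise): RNAs with correlated expression across tissues tend to share
   interaction partners.
2. **The network's spectrum encodes its link structure smoothly**: restoring
   a small set of removed links perturbs eigenvalues at first order while
   leaving eigenvectors approximately fixed. This is the regime in which the
   structural perturbation method (SPM) is a faithful estimator; it degrades
   when the removed fraction is large or the spectrum is dominated by noise.
3. **Layers are combined without rescaling.** Similarity weights lie in
   [−1, 1] and interaction entries are exactly 1; the block matrix mixes the
   two scales as-is. `build_bilayer(lm_weight=...)` exposes the relative
   scale for sensitivity analyses, but the default (1.0) applies no
   balancing, and no thresholding or rescaling of similarity weights is
   applied before spectral analysis. Both are documented assumptions rather
   than derived choices.

Negative correlations are kept as signed weights (SPM operates on any real
symmetric matrix); `pearson_similarity(clip_negative=True)` zeroes them for
ablation. The similarity diagonal is fixed at 0 so self-similarity never
counts as a link. Standardization is the per-RNA z-score across conditions
(population sd), which leaves Pearson correlations unchanged and is
idempotent; zero-variance profiles are removed with a warning because their
correlation is undefined.

## The perturbation estimator

Per draw, `round(f · L_layer)` links are removed independently from each
layer (similarity links = nonzero off-diagonal entries; interaction links =
1-entries). Removal is all-or-nothing: the full weight moves into ΔA. With
A_R = A − ΔA and A_R = Σ λ_k x_k x_kᵀ (dense symmetric eigendecomposition,
no truncation — N at desk scale is at most a few thousand):

    Δλ_k = x_kᵀ ΔA x_k / (x_kᵀ x_k),
    Ã    = Σ_k (λ_k + Δλ_k) x_k x_kᵀ.

The prediction matrix averages Ã over t independent draws, each with its own
child seed fanned out deterministically from the top-level seed.

**Degenerate eigenvalues.** The per-vector correction is basis-dependent
when eigenvalues coincide (common in sparse binary graphs: disconnected
components, symmetric motifs). Eigenvalues within `1e-8 · max|λ|` of each
other are therefore grouped, ΔA is diagonalised inside each group's
eigenspace, and the rotated basis with its exact subspace shifts is used —
standard degenerate first-order perturbation theory, and the form that makes
the result independent of the eigensolver's arbitrary basis choice.
`degenerate_handling="naive"` restores the per-vector formula for
comparison. Reconstructions are symmetrised (`(Ã + Ãᵀ)/2`) to remove
floating-point asymmetry.

## Structural consistency

σ_c removes a fraction f of links (per layer), scores all non-link entries
of A_R with Ã, and reports the fraction of the L removed links found in the
top-L candidates. Repetitions (default 10, matching the repeated-experiment
convention used throughout) give mean ± sd.

Two protocol choices deserve attention:

- **Dense similarity networks have no non-links**, so a similarity-only
  network is sparsified first: the strongest q% of |weights| are kept as
  links (default q = 10, the same order as the removal fraction). This
  thresholding is the largest inferred step in the pipeline — results for
  single similarity layers should be read as conditional on it.
- **Candidate universe for the bilayer**: all non-link entries across both
  layers, matching the per-layer perturbation set. Because the similarity
  blocks are dense, their only non-links in A_R are the removed entries
  themselves; the candidate pool is therefore dominated by the interaction
  block plus the removed similarity links. `interaction_only=True` restricts
  the pool to the interaction block for ablation.

**Layer comparison.** With the default generator (noise_sd = 0.3, i.e.
within-group correlation ≈ 0.92), each sparsified similarity layer is a
near-clique structure whose own spectrum predicts its removed links close to
optimally, and σ_c(single layer) exceeds σ_c(bilayer): integration cannot
improve on an almost-deterministic layer, while the bilayer's aggregate σ_c
is diluted by the much harder interaction-recovery task. The ordering
reverses as expression noise grows: at noise_sd = 3.0 the bilayer beats both
single layers in most seeded repetitions (the acceptance script computes
both regimes; see `bilayer_sigma_wins_of_10` vs
`bilayer_sigma_wins_of_10_noisy_expression`). The bilayer advantage is thus
a property of the noisy-similarity regime that real expression compendia
occupy, not of clean planted structure.

## Cross-validation protocol

Positives (known interactions) are partitioned into k folds (sizes differ by
at most one). Per fold, the held-out positives are zeroed in both copies of
the interaction block; the similarity blocks are *not* recomputed (they
derive from expression only). Scores come from a fresh `predict` on the
masked bilayer. The evaluation universe is {held-out positives} ∪ {entries
that are 0 in the original interaction matrix}; known training positives are
excluded so that memorising the training links earns nothing. AUC uses the
rank (Mann–Whitney) form with half credit for ties — equal to the
trapezoidal area under the threshold-swept ROC — because SPM scores can tie
exactly on symmetric toys. `top_fraction_tpr` implements the complementary
top-slice recovery rate. Defaults: k = 5, t = 8, f = 0.10, 10 repeats.

## The synthetic generator

`generate_dataset` realises a latent-block model: each RNA class is split
into `n_groups` contiguous, balanced co-expression groups; each group draws
one iid standard-normal condition profile; each RNA adds iid noise of sd
`noise_sd` (so `noise_sd` is in units of the group-signal sd). Interactions
are independent Bernoulli draws with probability `affinity[g, h]` for a
group pair, falling back to `background_p` where the affinity entry is 0.
Defaults — 120 lncRNAs × 40 miRNAs × 24 conditions, 4 groups, noise_sd 0.3,
diagonal affinity 0.6, background 0.02 — keep the lncRNA:miRNA ratio of
curated interaction catalogues (~12:1), a realistic condition count, and
eigendecompositions well under a second, which is what keeps the full test
suite and acceptance run fast at desk scale.

What the generator does *not* emulate: heavy-tailed expression magnitudes,
shared batch/tissue covariance between the two RNA classes, degree
heterogeneity beyond the block structure, and correlated missingness. Tests
passing on this generator therefore demonstrate the machinery's correctness
and the qualitative behaviour of the method under planted structure — not
calibrated performance on any real database.

## Numerical and design details

- Removal counts use `int(round(f · L))`; a layer whose count rounds to 0
  still loses one link (with a warning) so a requested perturbation never
  silently skips a layer.
- Candidate ranking ties break by (row, column) index ascending, making all
  rankings deterministic and bit-reproducible under a fixed seed.
- σ_c errors out when the candidate pool is not larger than the removed set
  (a dense unsparsified network): the index would be trivially 1.
- Exact symmetry of similarity networks and of A is enforced by mirroring
  the upper triangle, never by tolerance checks.
- Duplicate expression rows keep the first occurrence; rows with missing
  values are dropped; interaction edge lists are deduplicated with
  first-appearance ordering and self-pairs are rejected.
- All top-level seeds fan out to child generators via integer draws below
  2³¹, so any stage can be replayed in isolation.

## Known limitations

- Full dense eigendecomposition costs O(N³); beyond ~10⁴ nodes a truncated
  solver would be needed (deliberately not enabled: the estimator sums over
  the full spectrum).
- The sparsification step for similarity-only σ_c introduces a free
  parameter (q) that the bilayer analysis does not share; cross-network σ_c
  comparisons are sensitive to it.
- The method scores *pairs already connected through network structure*;
  isolated nodes (no interactions and weak similarity) receive uninformative
  scores.
- Indirect interactions (via proteins or mRNAs) are indistinguishable from
  direct binding in expression-derived similarity.
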