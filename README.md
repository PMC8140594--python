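# spmlmi

Structural-perturbation link prediction for lncRNA–miRNA interaction
networks.

## The problem

Long non-coding RNAs (lncRNAs) interact with microRNAs (miRNAs) — for
example as miRNA "sponges" under the competing-endogenous-RNA (ceRNA)
hypothesis — but experimentally mapping these interactions at scale is slow
and expensive. Because co-regulated lncRNAs tend to share miRNA partners,
expression similarity across tissues carries predictive signal about
unobserved interactions. `spmlmi` turns that observation into a link
predictor for computational biologists who have (i) expression profiles for
both RNA classes and (ii) a partial catalogue of known interactions, and
want a ranked list of candidate pairs to validate.

## The method

Three layers are integrated into one symmetric *bilayer* block adjacency
over the N = n_lnc + n_mi nodes:

```
A = [ LSnet   LMnet ]
    [ LMnetᵀ  MSnet ]
```

where `LSnet`/`MSnet` are Pearson-correlation co-expression networks of the
z-scored lncRNA and miRNA profiles, and `LMnet` is the binary known
interaction matrix.

Scoring uses the **structural perturbation method** (SPM, a first-order
spectral estimator). Remove a random fraction *f* of links per layer
(matrix ΔA, leaving A_R = A − ΔA), eigendecompose
A_R = Σ_k λ_k x_k x_kᵀ, and shift each eigenvalue by the first-order
correction with eigenvectors held fixed:

```
Δλ_k = x_kᵀ ΔA x_k / (x_kᵀ x_k)
Ã    = Σ_k (λ_k + Δλ_k) x_k x_kᵀ
```

Averaging Ã over *t* independent perturbation draws (default t = 8,
f = 0.10) gives the prediction matrix; high-scoring zero entries of the
interaction block are the predicted missing links. The same machinery
yields the **structural-consistency index** σ_c — the fraction of removed
links recovered among the top-L scored non-links of A_R — a data-driven
measure of how intrinsically predictable a network's links are, and
`run_cv` evaluates prediction with repeated k-fold cross-validation
(held-out positives vs never-known pairs, rank-based AUC with half credit
for ties).

All stages run on synthetic group-structured data from the built-in
generator, so the complete pipeline is testable without any database
downloads; real TSV inputs of the same shape drop straight in.

## Worked example

```sh
spmlmi simulate --n-lnc 120 --n-mi 40 --seed 1 --out-dir data
spmlmi build --lnc-expr data/lnc_expression.tsv --mi-expr data/mi_expression.tsv \
             --interactions data/interactions.tsv --out net.h5
spmlmi consistency --net net.h5 --reps 10 --seed 7 --out sigma.tsv
spmlmi predict --net net.h5 --t 8 --fraction 0.10 --seed 42 \
               --out scores.h5 --ranked ranked.tsv --top 5
spmlmi cv --net net.h5 --k 5 --t 8 --repeats 10 --seed 42 --out cv.tsv
```

prints

```
wrote synthetic dataset (120 lncRNAs, 40 miRNAs, 794 interactions) to data
bilayer network: N=160 (120 lncRNAs + 40 miRNAs), 794 interaction links -> net.h5
LSnet: sigma_c = 0.5690 +/- 0.0394
MSnet: sigma_c = 0.6875 +/- 0.0884
bilayer: sigma_c = 0.4512 +/- 0.0062
score matrix (160x160, t=8) -> scores.h5
5 ranked candidates -> ranked.tsv
5-fold CV x 10: AUC = 0.8997 +/- 0.0117
```

The σ_c lines say how much of a randomly removed 10% of each network's
links the spectral scores recover (1.0 = perfect recovery; a density-matched
random graph scores ≈ 0.1 here). The AUC line is the cross-validated
probability that a held-out true interaction outranks a random unknown pair:
0.90 on this planted-structure dataset versus ≈ 0.5 when interactions are
generated independently of the co-expression groups. The top of
`ranked.tsv` holds the candidate pairs to inspect first:

```
lnc_id   mi_id    score         rank
LNC0089  MIR0028  0.4028653366  1
LNC0110  MIR0034  0.37936996    2
...
```

Every command writes a `*.manifest.json` recording the command line,
parameters, seed, package version, and input checksums.

## Layout

- `spmlmi.similarity` — expression loading, z-scoring, Pearson networks
- `spmlmi.network` — interaction lists, bilayer assembly, block extraction
- `spmlmi.spm` — perturbation sampling, first-order reconstruction, prediction
- `spmlmi.consistency` — σ_c and the layer comparison
- `spmlmi.evaluation` — k-fold CV, ROC/AUC, top-fraction recovery
- `spmlmi.synthetic` — the group-structured generator
- `spmlmi.cli` — the `spmlmi` command

See `docs/methods.md` for model assumptions, parameter choices, and known
limitations.
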