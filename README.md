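# pasl — Pathway Activity Score Learning

`pasl` learns low-dimensional representations of gene-expression data in
which the latent dimensions are **interpretable pathway activity
scores**.  Given an expression matrix `X` (n samples × p features) and a
collection of genesets (pathways, GO groups — a binary membership matrix
`G ∈ {0,1}^{g×p}`), it factorizes

```
X ≈ L · D ,      D = [D1; D2]
```

where the rows of the dictionary `D` are unit-norm *atoms* and `L` holds
the per-sample activity scores.  Unlike PCA or sparse NMF meta-genes,
each atom of `D1` is constrained to the support of exactly one geneset,
so the corresponding column of `L` reads directly as "activity of that
pathway in that sample".

The fit has two phases:

- **Inference phase** — greedy extraction of geneset-constrained
  principal-component atoms.  At each step all genesets are ranked by
  the variance of their restricted first principal component, normalized
  by the Box-Cox transform of the geneset size,
  `score_i = var_i / ((‖g_i‖₀^λ − 1)/λ)` with λ = 1/3.  The top geneset
  contributes an atom, the atom's contribution is deflated from the
  residual, and a threshold `t ∈ [0,1]` controls how often the full
  ranking is recomputed (`t=1`: re-rank every iteration, the exact
  greedy "dynamic" solution; `t=0`: rank once, "static").  The phase
  stops at `a₁` atoms or when the relative reconstruction error stops
  decreasing.
- **Discovery phase** — unconstrained sparse atoms with a fixed number
  `m` of non-zero coefficients (default 2000), extracted from the
  inference residual by truncated power iteration, capturing variance
  that no known geneset explains.

New samples are projected with the Moore–Penrose pseudoinverse,
`L_new = standardize(X_new) · D⁺`, where the standardization uses the
**training** means and standard deviations only.  On top of the scores,
**Differential Activation Analysis (DAA)** runs per-atom two-class
permutation Welch t-tests (default 10000 label permutations, add-one
p-value estimator, Benjamini–Hochberg q-values) to find the pathways
whose activity differs between phenotypes.

## Worked example

The package ships a generator for geneset-structured data with a planted
dictionary, so the full workflow runs without downloads:

```bash
pasl simulate --out sim -n 400 -p 500 --n-atoms 40 --seed 11
# simulate: wrote 400×500 matrix, 40 genesets, 40 planted atoms

pasl fit --expression sim/expression.tsv --gmt sim/genesets.gmt \
         --out fit --a1 40 --stop-tol 0 --seed 11
# fit: 40 inference + 0 discovery atoms; 0 genesets dropped

pasl recover --model fit/model --simdir sim --out matches.tsv
# {"recovered_fraction": 0.775, "size_histogram": {"30": 10, "50": 10, "100": 10, "200": 10}}
```

The simulation plants 40 atoms equally across geneset sizes
{30, 50, 100, 200}; the fitted model selects exactly 10 atoms per size
class (the Box-Cox normalization at work — without it the ranking is
heavily biased toward the 200-gene sets) and recovers 77.5 % of the
planted loading vectors at |cosine| > 0.9 despite freely overlapping
genesets and noise.  With disjoint genesets and no noise the recovery is
exact (cosine 1.0 for every atom; see `scripts/acceptance.py`).

Differential activation on the scores (here with one pathway's activity
shifted by 1.5 in the first 200 samples):

```bash
pasl daa --scores scores_shifted.tsv --labels labels.tsv \
         -B 1000 --seed 11 --top-k 3 --out daa
head -4 daa/top_atoms.tsv | cut -f1-5
# rank  atom            t                    p                     q
# 1DA   SIM_SET_30_2.1  -7.701494461691567   0.000999000999000999  0.03996003996003996
# 2DA   SIM_SET_100_5.1 -2.0089238169193013  0.04695304695304695   0.7776838546069315
# 3DA   SIM_SET_30_1.1  -1.791903737620325   0.07092907092907093   0.7776838546069315
```

The shifted pathway is ranked first (1DA) with the smallest achievable
p-value at B = 1000, `1/1001 ≈ 0.000999`; the remaining atoms are null
and their q-values show it.

The same operations are available as a library
(`pasl.fit`, `pasl.transform`, `pasl.activation_ttest`,
`pasl.synthetic.simulate`, …) on pandas DataFrames.

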