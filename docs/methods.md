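# Methods

## Model

The data model is a noisy linear factorization of a standardized
expression matrix, `X = L·D + E`, with `X ∈ R^{n×p}` (samples ×
features), a dictionary `D ∈ R^{a×p}` of unit-norm atoms and scores
`L ∈ R^{n×a}`.  The dictionary is the concatenation `D = [D1; D2]`:
every `D1` atom has its support inside exactly one geneset of the
membership matrix `G ∈ {0,1}^{g×p}` (the interpretability guarantee);
`D2` atoms are unconstrained but carry exactly `m` non-zero
coefficients.  `E` is treated as isotropic noise.

Standardization is feature-wise z-scoring with the *training* means and
standard deviations (sample SD, ddof = 1).  Features that are constant
in training map to exactly 0 (the constancy is detected with a relative
tolerance of 1e-12 on the SD, because exact float zeros do not survive
the centering arithmetic); the mask is stored in the model.  Test
samples reuse the frozen statistics, so the transform estimates nothing
from new data.

## Inference phase

For geneset `i` with support `S_i`, the restricted first principal
component of the current residual `R` is the top right-singular vector
of `R[:, S_i]`, with variance `σ₁²/(n−1)`.  The residual is **not**
re-centered per geneset or after deflation: deflation destroys column
means, and operating on the raw residual keeps the Frobenius-norm
bookkeeping exact (`‖R'‖²_F = ‖R‖²_F − ‖R·d‖²` after deflating by
`d`).  The top singular pair is computed from the smaller of the two
Gram matrices with a dense symmetric eigendecomposition — deterministic,
and cheap because geneset sizes are far below n·p.  The sign of every
loading is canonicalized so its largest-magnitude coefficient is
positive, making atoms reproducible across linear-algebra backends.

Genesets are ranked by normalized variance
`score = var / boxcox(size, λ)` with `boxcox(y, λ) = (y^λ − 1)/λ`
(`log y` at λ = 0).  The normalization compensates for the fact that
larger genesets capture more variance merely by spanning more features;
λ = 1/3 is the default.  Since `boxcox(1, λ) = 0`, singleton genesets
use the size-2 divisor — a guard that only affects ranking and is noted
in the trace.  Ties are broken by smaller geneset size, then lower
geneset index, so runs are deterministic regardless of sort stability.
`λ = None` disables normalization (raw-variance ranking), which is how
the size bias is demonstrated.

The greedy loop keeps the ranking in a queue.  Popped entries computed
on the *current* residual are accepted outright (their expected and
realized variances coincide by construction — this also avoids
float-equality pathologies).  A stale popped entry has its first PC
recomputed; it is accepted iff
`realized_normalized_variance ≥ t × expected_normalized_variance`,
otherwise the whole ranking is recomputed and the loop continues.
Default `t = 0.9`.  After accepting an atom the residual is deflated
(`R ← R − (R·d)·dᵀ`) and the accepted geneset is re-inserted with its
next PC recomputed on the deflated residual, so one geneset may
contribute several atoms.  At `t = 1` the shortcuts are disabled and
the full ranking is recomputed after every acceptance: deflation can
*increase* the restricted variance of a geneset that overlaps the
deflated atom, so only per-iteration re-ranking reproduces the dynamic
approach exactly — verified atom-for-atom against a brute-force
reference on random instances.  `t = 0` is the static approach (no
re-ranking ever).  The accepted atom itself is always the PC of
the *current* residual, whatever `t`.

Stopping: at `a₁` atoms (default 500), or when the relative
reconstruction error `‖R‖²_F / ‖X‖²_F` decreases by less than
`stop_tol` (default 1e-3) between consecutive accepted atoms.  No
tolerance is canonical here; 1e-3 of total variance per atom is the
point at which additional geneset atoms stop being distinguishable from
noise in the simulations.  Genesets whose residual block is exhausted
(zero variance) are dropped from the queue rather than terminating the
loop.

## Discovery phase

Each discovery atom approximately solves
`max ‖R·d‖²  s.t. ‖d‖₂ = 1, ‖d‖₀ = m` by truncated power iteration:
score step `u = R·d`, loading step `w = Rᵀ·u`, truncation to the top-m
magnitudes (ties to the lower index), renormalization, until the
direction stabilizes (tolerance 1e-6, max 500 iterations).  The fixed
cardinality is the contract — an ℓ₁-penalized sparse PCA would require
tuning a penalty path to hit a target support size.  The problem is
non-convex and a single start can converge to a sub-optimal support,
so the iteration is seeded deterministically from several starts (the
dense first PC truncated to m entries, the top-m columns by second
moment, and each of the five largest columns individually) and the
candidate with the largest explained variance wins; on exhaustively
enumerable instances (p ≤ 12, m ≤ 3) this reaches at least 95 % of the
best-support objective.  `a₂` atoms are extracted greedily with the
same deflation as the inference phase; `m` defaults to 2000 and is
clipped to p on small inputs.  The `a₁/a₂` split is user-set; `a₂`
defaults to 0.

## Projection and persistence

`D⁺` is the Moore–Penrose pseudoinverse (SVD, rcond = 1e-10), computed
once at fit time; `a ≪ p` makes this trivial and turns `transform` into
a single matrix product `L = Z·D⁺` — the least-squares projection of
the standardized data onto the row space of `D`.  The same projection is
used for training and new data.  Feature alignment between a model and
new data is by identifier, never by position.  Models persist as a
directory (or zip) of text artifacts — sparse coefficient triplets,
standardizer table, fit trace, JSON metadata — with coefficients written
in shortest round-tripping float64 representation and read back with
round-trip parsing, so save→load→transform is bit-identical.

## Differential Activation Analysis

Per atom, a two-sided Welch t-statistic compares scores between two
classes; Welch rather than pooled-variance because equal score variance
across phenotype groups is not a safe assumption, and the choice is
configurable in spirit by pre-scaling.  Significance comes from `B`
label permutations (default 10000) shared across atoms — one
permutation per replicate, preserving inter-atom correlations — with
the add-one estimator `p = (1 + #{|t*| ≥ |t_obs|})/(B + 1)`, so
`p ≥ 1/(B+1)`.  A tolerance of 1e-12 in the exceedance comparison makes
tied statistics (including the identity permutation) count as extreme,
which keeps the estimator consistent with exhaustive enumeration on
tiny designs.  Constant score columns have no defined t; they are
flagged and assigned p = 1.  Benjamini–Hochberg q-values are added
across atoms; the ranking is ascending p with ties broken by descending
|t|.

## Synthetic data

The generator emulates the simulation used to calibrate λ: a membership
matrix with `per_size` genesets for each size in {30, 50, 100, 200}
over p = 500 features, members drawn uniformly; a planted dictionary of
`n_atoms = 40` random unit-norm atoms, one per selected geneset,
selected equally across size classes; scores i.i.d. standard normal;
isotropic Gaussian noise; n = 400 samples.  `overlap_fraction` blends
between freely overlapping genesets (1.0, the default) and disjoint
round-robin allocation (0.0).

The default noise SD is 0.5.  At that level the per-column noise
variance (0.25) is comparable to the per-column signal of the larger
genesets (a size-s atom spreads unit variance over s columns), which is
the regime in which raw-variance ranking repeatedly selects the largest
genesets (size-200 selection frequency ≈ 0.68 instead of the planted
0.25) while the λ = 1/3 normalization restores the uniform planted
distribution.  At substantially lower noise every geneset's own planted
atom dominates its block and both rankings trivially coincide, so the
normalization would be untestable.

Recovery scoring maps learned atoms back to the raw feature space
(multiplying loadings by the training SDs and renormalizing) before
computing absolute cosines against the planted atoms — learned atoms
live in standardized space and the column-wise rescaling warps
directions (in the noiseless case the mismatch caps cosines near
√(2/π) ≈ 0.80).  Matching is greedy one-to-one on the |cosine| matrix.

What the generator does *not* emulate: probe effects, batch structure,
heavy-tailed noise, correlated scores, or the scale of real microarray
platforms (p ≈ 55 000).  Passing tests demonstrate the algorithmic
contracts (ordering optimality, recovery, calibration), not biological
performance on real cohorts.

## Problem sizes and numerical choices

The test and acceptance runs use the full simulation design
(n = 400, p = 500, 40 genesets, 10 replicates) for the normalization
experiment, p = 800 with disjoint genesets for recovery, 2000 null
atoms at B = 1000 for the DAA calibration, and instances up to
n ≤ 30, p ≤ 50, g ≤ 10 for the exact oracle comparisons — sizes at
which the brute-force references (full re-ranking per iteration,
exhaustive support enumeration, exhaustive label permutations) are
computable exactly.  Degenerate inputs are handled explicitly: all-zero
restricted blocks yield flagged zero atoms rather than exceptions, zero
residuals stop discovery early, empty dictionaries refuse to transform
with a clear message, and non-finite training values are rejected with
the offending feature names.
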