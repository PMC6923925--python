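# Methods

## The model

A bulk expression profile is treated as a linear mixture of cell-type-specific
profiles.  For gene *i*,

    b_i = Σ_j a_ij · x_j

where `b_i` is the bulk expression of gene *i*, `a_ij` the reference signature
value of gene *i* in cell type *j* (the median over that type's replicate
arrays), and `x_j ≥ 0, Σ_j x_j = 1` the unknown composition.  The coefficients
are estimated by epsilon-insensitive linear support vector regression (the
`LinearSVR` solver from scikit-learn) with the L1 / epsilon-insensitive loss:
with the default tube width ε = 0 this minimizes the mean absolute residual,
which is far less sensitive to outlying genes than a squared loss.  Raw
coefficients may be negative; they are clipped at zero and renormalized onto
the probability simplex, so every reported composition is a valid set of
relative fractions.  Absolute abundances are out of scope.

Key assumptions:

* **Linearity of mixing.**  Expression values are used on the scale they
  arrive in (typically log2 from RMA-style preprocessing), matching how the
  reference signature is built.  Mixing is exactly linear only in linear
  intensity space, so log-scale deconvolution is an approximation — a
  deliberate one, since signature and mixtures share the same scale and the
  benchmark mixtures are synthesized on that same scale.
* **Shared distribution.**  Mixtures measured on a different platform should
  first be mapped onto the reference compendium's pooled empirical
  distribution (`crossplatform_normalize`), otherwise the regression absorbs
  platform shifts into the coefficients.
* **Complete signature.**  Cell types absent from the signature are invisible;
  their signal degrades all estimates (quantified by the tissue-spiking
  benchmark below).

## Signature construction

1. **ANOVA ranking.**  One-way fixed-effects ANOVA per feature across cell
   types; features sorted by ascending p-value (ties: descending F, then
   lexicographic feature ID, for cross-platform determinism).  The
   significance flag uses raw p < `alpha` (default 0.05, configurable); no
   multiple-testing correction is applied, as the ranking — not the flag —
   drives selection.  Zero-variance features get p = 1 so they are never
   selected and the table keeps one row per input feature.
2. **Condition-number scan.**  For G = step, 2·step, … (step default 500) up
   to the significant-feature count, compute κ = σ_max/σ_min of the
   top-G-feature × all-samples matrix; keep the G with minimal κ (first wins
   on exact ties).  A low κ makes the regression stable under input
   perturbations.  The partial final bin is not scanned by default
   (configurable), mirroring a scan over "top 500, 1000, 1500, …".
   κ is exact (full SVD) by default; an `approx` mode estimates it as the
   1-norm condition of the QR triangular factor, the classic fast
   LINPACK-style estimate, for compatibility with tools that use it.
   Matrices that are rank-deficient to working precision
   (σ_min ≤ max(m,n)·eps·σ_max) report κ = ∞.
3. **Medians.**  Per-cell-type median over replicate columns, for robustness
   to outlying arrays; columns in alphabetical cell-type order unless an
   explicit order is given.
4. **Probe collapsing.**  When a probe→gene map is supplied, each gene keeps
   the probe with the highest median over *all* source samples (ties broken
   by lexicographic probe ID).  Selection and medians happen before
   collapsing.

As QA, `lda_embed` projects samples onto up to three Fisher discriminant axes
(generalized eigenproblem on the between/within-class scatter).  Since the
within-class scatter is singular whenever features outnumber samples, a
scale-aware ridge of 1e-6·trace(S_W)/p is added to its diagonal on failure
(falling back to the S_B scale when all classes are point masses); this is a
visualization aid, not part of estimation.

## Solver settings

| parameter | default | meaning |
|---|---|---|
| `epsilon` | 0 | insensitivity tube width; 0 = pure L1 regression |
| `C` | 1.0 | loss/penalty trade-off; with thousands of genes the loss dominates, so recovery is insensitive to C over orders of magnitude |
| `fit_intercept` | off | the mixture model has no intercept; fitting one lets the ridge penalty trade coefficient mass into it and biases recovered fractions by up to ~0.2 even on noiseless mixtures, so it is opt-in (for inputs with a known additive offset) |
| `standardize` | off | signature and mixture already share one normalized scale |
| `tol` / `max_iter` | 1e-6 / 10,000 | fixed, plus a fixed solver seed, so results are deterministic |

Negative coefficients are clipped then renormalized; the paper trail for this
choice is that reported compositions are nonnegative and subsets are
explicitly "normalized to a sum of 1" when cell types are aggregated
(`aggregate_cell_types` does the same after summing group members).

## Normalization conventions

* Quantile normalization assigns each column the per-rank means of the sorted
  columns; ties take the average rank (tied values map identically).  It is
  idempotent on tie-free data; averaging tied ranks reshapes the pool
  slightly, so exact idempotence holds only without ties.
* Cross-platform mapping sends a value at average-rank r of n in its sample to
  the pool quantile (r − 0.5)/n, linearly interpolated between pool order
  statistics at probabilities (k − 0.5)/m.  The midpoint convention avoids
  endpoint degeneracy; outputs stay within the pool's range and preserve
  within-sample rank order.

## Benchmarks and agreement statistics

* **Pure-cell leave-one-out**: each replicate is held out, the signature is
  rebuilt from the rest (the held-out array never enters the ANOVA, the scan
  or the medians), and the held-out profile is deconvolved.  Per-type mean ±
  SD of the own-type ("dominant") fraction summarizes accuracy; truth is 1.0.
* **In silico mixtures**: per run, one replicate per type drawn uniformly,
  weights drawn Dirichlet(1,…,1) — uniform on the simplex, the canonical
  uninformative choice for "randomly assigned" fractions — and the signature
  rebuilt from the non-component arrays.  The ledger stores components,
  weights and predictions; mixtures are exactly re-synthesizable from it.
* **Tissue spiking**: mixture = f·tissue + (1 − f)·immune per gene, f ∈
  {0.3, 0.5, 0.7} in the standard design; the tissue type is absent from the
  signature, so error grows with f.
* **Agreement**: MAPE (zero-truth entries excluded with a logged count — the
  benchmark weights are almost surely positive, so this is a guard, not a
  path); Bland–Altman differences pred − truth with 95% limits of agreement
  mean ± 1.96·SD (sample SD, n − 1); cumulative tables of |difference| at
  edges 0.01/0.02/0.05/0.10/0.20/0.50 by default.

All benchmark randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning (one child per mixture; one child per
sample in the generator), so every ledger is bit-reproducible.

## The synthetic compendium

`generate_reference` emulates a pure-cell replicate compendium on a log2-like
scale: per-gene baselines ~ N(6, 1.5²) shared across types; each of 9 types
owns a disjoint block of 200 marker genes (of 2,000) shifted up by 4.0 units
(~16-fold, a strong lineage marker); replicates add N(0, noise_sd²) with
noise_sd = 1.0, i.e. a quarter of the marker effect.  Disjoint markers keep
the signature condition number modest (κ ≈ 15–25), which is the regime the
condition scan aims for on real data.  10 replicates per type echo the
at-least-9-replicates design of real reference compendia.

What it does **not** model: probe-level effects, saturation, correlated noise
between genes, shared markers between related lineages (e.g. naive vs memory
T cells), and batch structure.  Passing desk-scale benchmarks therefore shows
the estimator and pipeline are correct and well-behaved under the stated
noise model, not that real-data accuracy matches these numbers; collinearity
between related cell types on real arrays will widen the limits of agreement.

`generate_tissue_profile` is a synthetic heavy-tailed positive lognormal
profile, independent of the marker structure — a stand-in for a non-immune
bulk tissue array in the spiking design.

## Degenerate inputs and numerical choices

* A noise-free compendium makes every scan submatrix rank-deficient (within a
  type all replicates are identical), so κ = ∞ across the whole grid and the
  scan cannot discriminate; the first grid point then wins by the tie rule.
  Noise-free signatures for testing are therefore built over all significant
  genes directly.
* Fractions are validated on construction (nonnegative, sum within 1e-9 of 1).
* Batch deconvolution reports per-sample failures as all-NaN rows and
  continues.
* Gene overlap between mixture and signature below 50% warns; below 10%
  errors.

## Problem sizes

The shipped tests and the acceptance script run entirely on the synthetic
compendium: 9 types × 10 replicates × 2,000 genes for the study-scale checks
(leave-one-out over 90 arrays; 100 in silico mixtures; 30 mixtures × 4 tissue
fractions), and smaller 3–4-type fixtures for unit tests.  These sizes keep a
full pipeline run within about a minute while leaving every statistical
property (recovery error, LoA width, MAPE growth) comfortably measurable.
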