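# Methods

## Data model

One tumor contributes paired per-nucleus counts: HER2 gene signals and
CEP17 (chromosome-17 centromere) reference signals, both non-negative
integers, for at least 20 nuclei.  All downstream modelling uses the HER2
copy-number histogram — the multiset of HER2 counts binned at integer
values.  Summaries follow the dual-probe kit conventions: the FISH ratio is
total HER2 over total CEP17 signals (equivalently a ratio of means, not a
mean of per-cell ratios), and a tumor is HER2-positive when the mean HER2
copy number strictly exceeds 2.0 per cell.  The positivity call is the
literal per-cell copy rule; the full ASCO/CAP ratio/copy decision algorithm
is deliberately not implemented.  Whether "more than two copies per cell"
should be read as the mean or as a per-cell majority is ambiguous; the mean
is used here.

## Mixture model and fitting

The copy-number distribution is modelled as

    f(x) = π₁ N(x | μ₁, σ₁) + π₂ N(x | μ₂, σ₂),   π₁ + π₂ = 1,

with the one-component fit as the monophasic special case.  Fitting is
maximum likelihood via EM on the binned data: each occupied integer bin
enters at its center with its nucleus count as a frequency weight.  With
integer counts this is *identical* to the per-cell likelihood, which is why
binned EM was chosen.

Numerical choices (all exposed via `FitOptions`):

* **σ floor, 0.25 copies** (default).  Signal counts are integers; a
  component narrower than a quarter copy is physically meaningless and
  would let the likelihood diverge on a point mass.  The M-step clamps σ
  at the floor; because the per-component likelihood is unimodal in σ,
  clamping is the *constrained* M-step maximum and EM monotonicity is
  preserved.  The per-iteration log-likelihood trace is recorded and
  asserted monotone (1e-10 slack) in the tests.
* **Initialization**: one quantile-split start (component 1 from nuclei at
  or below the weighted median, component 2 above) plus `n_starts − 1 = 4`
  seeded random perturbations; the best final log-likelihood wins, ties
  broken by the lower first-component mean.  Components are always
  reported sorted by ascending mean, so relabelling cannot change results.
* **Convergence**: relative log-likelihood change ≤ 1e-8, cap 500
  iterations.
* **Degenerate input**: a single occupied bin cannot support two
  components; `k = 2` returns the σ-floored point-mass solution with a
  `DegenerateFitWarning` instead of failing.
* **Uncertainties**: delta-method standard errors from the numerically
  evaluated observed information on the unconstrained parameterisation
  (logit π₁, μᵢ, log σᵢ); NaN where the information matrix is singular
  (e.g. a σ pinned at the floor).

Model selection uses BIC = −2 log L + p log n with n the number of nuclei
(p = 2 for one component, 5 for two).  Two components are chosen iff
BIC(k=2) < BIC(k=1) *and* both weights are at least π_min; ties favour the
simpler model.  BIC is one concrete, testable operationalisation of the
"single-peaked vs double-peaked" distinction; it is validated against an
independent EM implementation (scikit-learn) and a dense parameter-grid
search on small-support histograms.

## The heterogeneity (ITH) call

A tumor is **HH** iff all of:

1. model selection prefers two components;
2. the lower-mean component has weight π_low ≥ π_min (default 0.10 — a
   "subpopulation" must be non-negligible; no published weight cutoff
   exists, so this is a package decision, exposed as config);
3. μ_low < τ_low (default 2.0 copies, i.e. the subclone sits below two
   HER2 copies per cell);
4. the overall mean π₁μ₁ + π₂μ₂ ≥ τ_pos (default 2.0 copies — the tumor
   as a whole remains amplified).

Otherwise LH.  Every criterion's outcome is recorded in a decision trace.
The rule is monotone by construction: raising π_min or lowering τ_low can
only turn HH into LH (property-tested).  Whether the underlying measure
was originally a continuous score before thresholding is unknown; rather
than invent a score, the package exposes the boolean criteria plus the raw
fitted parameters.  Tumors failing the HER2-positivity call are still
classified — nothing is silently filtered.

## Synthetic data generator

Because no patient-level data are deposited, the generator is first-class
and defines the study conditions:

* A **clone** contributes per-nucleus HER2 counts as rounded normals
  floored at zero.  The generative family matches the fitted family on
  purpose, making parameter recovery well-posed.  Rounding inflates the
  within-clone variance by ≈ 1/12, so recovered σ̂ slightly exceeds the
  generating σ; means are preserved (verified by numerical integration in
  the tests).  CEP17 is simulated at mean 2.0, sd 0.3 (diploid
  centromere).
* A **tumor** is 1–2 clones with fractions summing to one and ≥ 20 nuclei
  (default 60 — cohort reports state only "more than 20", so 60 is a
  package choice representative of routine FISH counting).
* **HH tumors** get a low subclone (μ_low ~ U(1.2, 1.8), σ 0.4, weight
  U(0.25, 0.45)) under an amplified bulk whose mean is solved from a
  target overall mean ~N(5.0, 0.7) clipped to [4.2, 6.5] (FISH ratio
  ≈ 2.5), with the bulk mean floored at μ_low + 4σ_max so that planted
  biphasic tumors are genuinely well separated.  **LH tumors** are a
  single clone with μ ~ N(10.6, 4.4) clipped to [4.5, 18] (FISH ratio
  5.3 ± 2.2) and σ ~ U(1, 2).
* **Cohorts** couple the planted label with covariates and a pCR outcome
  drawn from conditional probability tables whose defaults match the
  published group frequencies, and ER/PgR are drawn jointly (they are
  correlated in luminal disease).
* **Seeding**: one integer master seed; `numpy.random.SeedSequence.spawn`
  derives child streams (child 0 for cohort-level draws, child i for tumor
  i), stable across runs and platforms; identical seeds give byte-identical
  outputs.

The `paper97` preset is different in kind: its 97-row covariate/outcome
table is *assigned, not sampled*, so every published pairwise margin
(pCR × {ER, PgR, grade, heterogeneity}; heterogeneity × each
characteristic; the heterogeneity × ER × PgR joint) is reproduced exactly
and the contingency statistics can be integration-tested against printed
values.  The published tables pin only pairwise margins; a consistent
patient-level joint was found once by integer feasibility over the 32
(heterogeneity × ER × PgR × grade × pCR) cells and frozen into the source.
Only the per-nucleus counts are stochastic.  One printed characteristic row
is internally inconsistent (its group counts sum to 53 ER-positive tumors
against a printed total of 52); the preset follows the total of 52, which
the outcome table and the hormone-receptor subgroup frequencies
independently confirm.

What the generator does *not* emulate: fluorescence imaging physics, signal
clumping, nucleus segmentation and truncation artifacts ("> 10" overflow
bins in reports), inter-observer counting variability, and any real OCR of
scanned reports (the image fixture is a controlled renderer whose extractor
is an exact inverse).  Passing tests therefore demonstrate correctness of
the algorithms under the stated generative model, not performance on real
diagnostic scans.

## Contingency statistics

* Univariate ORs are closed-form cross-products with Woolf 95% CIs; this
  reproduces the published ER, PgR and heterogeneity rows to their printed
  precision from the printed counts, so it is the method of record.  A zero
  cell triggers the Haldane–Anscombe +0.5 correction, always flagged.
* The published grade row is not reproducible from its own printed counts
  (cross-product 2.41 vs printed 1.79); the recomputed value is reported
  and the discrepancy flagged rather than matched.
* Fisher's exact test is two-sided by the point-probability method (sum of
  hypergeometric probabilities ≤ the observed one, 1e-7 relative slack for
  floating-point ties); it is tested against exact rational-arithmetic
  enumeration and scipy.  On the heterogeneity table this gives p = 0.0072
  (the published table prints 0.006).
* The multivariate model is logistic regression (ML, Wald CIs), not a
  proportional-hazards model: the outcome is binary pCR with no time axis
  and the published table reports odds ratios.  Under (quasi-)separation
  the MLE diverges; the package falls back to a weak-L1 surrogate point
  estimate, profile-likelihood intervals via offset refits, and
  likelihood-ratio p-values, all flagged.  Indicators are coded ER+, PgR+,
  grade 3, HH, matching the sign structure of the published univariate
  column.

## Pipeline

`run_pipeline` orchestrates input (preset, simulated cohort, cohort CSV, or
histogram directory — exactly one), fitting, classification and reporting;
every run echoes its fully defaulted configuration, seed and package
version, and re-running a configuration reproduces its outputs
byte-identically.  The CLI (`her2ith simulate|fit|classify|stats|run`) is a
thin layer over the library; exit codes are 0/1/2 for success / stage
failure / configuration error.

## Problem sizes

Default experiment scales: parameter-recovery fixtures use 2000 nuclei;
cohort recovery experiments use 200 tumors × 20 seeds at 60 nuclei per
tumor (12 000 mixture fits overall); the reference cohort has 97 tumors.
These sizes give binomial/CLT error bars comfortably inside the asserted
tolerances.

## Known limitations

* Only 1–2 components; k > 2 subclonal structure is out of scope, as are
  non-normal components and Bayesian fitting.
* The σ floor biases σ̂ upward on near-degenerate histograms (by design).
* BIC-based peak counting is conservative on small cell counts (n ≈ 20):
  weakly separated subclones may be absorbed into one component.
* Survival endpoints (PFS/OS/DFS) and HER2-low analyses are out of scope.
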