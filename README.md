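# her2ith

Quantifying HER2 intratumoral heterogeneity (ITH) from FISH copy-number
histograms, and relating it to response to anti-HER2 neoadjuvant
chemotherapy.

## The problem

In HER2-positive breast cancer, a tumor can harbour several cellular clones
with different HER2 gene copy numbers.  Such heterogeneity matters
clinically: a low-copy subclone hiding under an amplified bulk can survive
HER2-targeted therapy.  A dual-probe FISH assay counts, in each of >= 20
tumor nuclei, the HER2 gene signals and the chromosome-17 centromere
(CEP17) reference signals.  The per-tumor histogram of HER2 signals per
nucleus is then either *monophasic* (one peak — low heterogeneity, LH) or
*biphasic* (two peaks — high heterogeneity, HH).

`her2ith` makes that call objective.  The copy-number distribution x of a
tumor is modelled as a two-component Gaussian mixture

    f(x) = π₁ N(x | μ₁, σ₁) + π₂ N(x | μ₂, σ₂),

fitted by EM on the binned counts (each integer bin weighted by its nucleus
count).  The Bayesian information criterion decides between one and two
components, and a tumor is labelled **HH** when the fitted mixture shows a
genuine low-copy subpopulation inside an amplified tumor:

* two components preferred by BIC,
* subclone weight π_low >= 0.10,
* subclone mean μ_low < 2 copies,
* overall mean π₁μ₁ + π₂μ₂ >= 2 copies.

Cohort statistics then relate the HH/LH label (and ER, PgR, grade) to
pathological complete response (pCR) via 2×2 odds ratios with Woolf 95%
intervals, exp(ln OR ± 1.96·√(1/a + 1/b + 1/c + 1/d)), Fisher exact and
chi-square tests, and a multivariate logistic model.

The package is aimed at biostatisticians and translational researchers who
want a reproducible, testable implementation of this analysis; since no
patient-level data are deposited for the motivating cohort, a first-class
synthetic-data module generates clonally mixed tumors and cohorts with the
published marginal structure (including the fully assigned `paper97`
reference cohort, which reproduces every published 2×2 margin by
construction).

## Worked example

```python
import numpy as np
import her2ith as h
from her2ith.synth import simulate_tumor

# a tumor that is 40% low-copy subclone (1.5 copies) / 60% amplified bulk
spec = h.TumorSpec(
    clones=(h.CloneProfile(mean_her2=1.5, sd_her2=0.4),
            h.CloneProfile(mean_her2=6.0, sd_her2=1.0)),
    weights=(0.4, 0.6), n_cells=200, true_label="HH")
sample = simulate_tumor(spec, np.random.default_rng(0))
hist = h.histogram_from_cells(sample.cells)

print(h.fit_gmm(hist, 2).summary())
```

```
Histogram Gaussian mixture fit
==============================================
components      2
nuclei          200
log-likelihood  -370.6833
BIC             767.8581
iterations      12   converged: True
----------------------------------------------
comp   weight     mean       sd  se(mean)
   1   0.3509   1.4042   0.5760    0.0731
   2   0.6491   6.0811   0.9836    0.0902
----------------------------------------------
mixture mean    4.4400 copies
```

The fit recovers the planted mixture: a subclone of weight ~0.35 at ~1.4
copies under a bulk at ~6.1 copies, overall mean 4.44 copies.  The
classifier turns this into a label with an auditable trace:

```python
res = h.classify_ith(hist)
print(res.label, res.decision_trace)
# HH {'two_components': True, 'subclone_weight': True,
#     'subclone_low_copy': True, 'overall_amplified': True}
```

All four HH criteria hold: two components, non-negligible subclone, subclone
below 2 copies, overall mean above 2.  `h.summarize_tumor(sample.cells)`
gives the assay-level view: mean 4.44 HER2 copies/cell, HER2/CEP17 FISH
ratio 2.24, HER2-positive.

At cohort scale, the `paper97` reference cohort runs end to end from the
shell:

```bash
her2ith run --preset paper97 --seed 0 --out run/
```

which fits all 97 tumors, writes the labeled cohort CSV and per-tumor fit
JSONs, and prints the association report — HH prevalence 18/97 (18.6%), pCR
rate 28% in the HH group vs 65% in the LH group, heterogeneity OR 0.211
(95% CI 0.0682–0.654).

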