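# mrix — a biological Margin Risk Index for post-neoadjuvant HNSCC surgery

After neoadjuvant immunochemotherapy (NICT), resections in head and neck
squamous cell carcinoma (HNSCC) are increasingly performed inside the
post-treatment tumor bed, and the classical anatomical margin — "tumor
cells within x mm of the inked edge" — loses much of its prognostic
meaning.  `mrix` implements a composite **Margin Risk Index (MRIx)** that
grades the *biology* of the tissue left behind instead, together with the
full statistical machinery needed to evaluate such an index against
time-to-event outcomes.  It is aimed at biostatisticians and
translational researchers who want a tested, reproducible implementation
of the scoring rubric, a cohort simulator with the matching statistical
structure, and the survival-analysis toolchain in one place.

## The index

Four margin-biology domains are each scored 0 (low risk), 1
(intermediate) or 2 (high risk):

| domain | markers | 0 | 1 | 2 |
|---|---|---|---|---|
| histopathology | TLS density /mm² | ≥3 | 1–<3 | <1 |
| tumor burden | Pan-CK foci /mm²; Ki-67 % | 0; <5% | (0,5); 5–20% | ≥5; >20% |
| molecular | driver mutations; PD-L1 RNA fold | 0; <1 | 1; 1–2 | ≥2; >2 |
| immune | CD8⁺/FoxP3⁺ ratio; GzmB⁺ /mm² | ≥2; >200 | 1–<2; 50–200 | <1; <50 |

Two-marker domains take the worse sub-criterion.  The composite is

```
MRIx = 0.30·H + 0.25·TB + 0.25·M + 0.20·I        ∈ [0, 2]
```

with categories low (≤0.8), intermediate (0.9–1.4) and high (≥1.5) after
half-up rounding to one decimal, and an automatic high-risk override for
a resection margin ≤2 mm.

Around the index the package provides:

* `mrix.simulate` — a proportional-hazards cohort generator (biomarker
  bands at configurable marginals with exact score round-trip, clinical
  covariates, exponential/Weibull baselines calibrated in closed form to
  target event rates, administrative censoring);
* `mrix.survival` — self-contained Kaplan–Meier + Greenwood, k-sample
  log-rank, Cox PH (Efron/Breslow ties, Newton–Raphson), Harrell's
  C-index (pair-enumeration and O(n log n) paths), AIC/LRT, Breslow
  baseline hazard, fixed-horizon Hosmer–Lemeshow calibration, and
  Benjamini–Hochberg adjustment;
* `mrix.pipeline` — baseline tables, domain-level survival associations,
  the adjusted multivariable Cox model, nested model comparison
  (clinical → clinical+margin → clinical+MRIx) and a frozen-score
  external-validation workflow;
* a CLI: `mrix simulate | score | analyze | validate`.

## Worked example

```python
import mrix
from mrix import pipeline, simulate

# one patient: TLS-poor margin, some residual burden, favourable biology otherwise
res = mrix.compute_mrix((2, 1, 0, 1), margin_mm=4.1)
# MRIxResult(score=1.05, category='intermediate', override_applied=False)

# a synthetic cohort with the packaged default structure
cfg = simulate.default_training_config(n_patients=2000, seed=42)
cohort = simulate.generate_cohort(cfg)
cohort.lrc_event.mean(), cohort.dmfs_event.mean()   # 0.171, 0.200

fit = pipeline.fit_adjusted_mrix_model(cohort, "lrc")
print(fit.summary().round(3))
```

```
                                  coef     se     hr  hr_ci_low  hr_ci_high      p
differentiation=moderate         0.180  0.148  1.197      0.895       1.601  0.226
differentiation=poor             0.806  0.143  2.240      1.691       2.967  0.000
pathologic_response=mPR_not_pCR  0.221  0.148  1.248      0.934       1.666  0.134
pathologic_response=no_mPR       0.913  0.140  2.492      1.892       3.282  0.000
mrix_category=intermediate       0.703  0.120  2.021      1.599       2.554  0.000
mrix_category=high               1.037  0.167  2.820      2.034       3.909  0.000
```

The hazard ratios are the exponentiated Cox coefficients versus each
term's reference level (well differentiation, pathologic complete
response, low-risk MRIx); at n=2000 they scatter around the generating
effects of the default configuration.  Model comparison on the same
cohort shows the pattern the index is designed to produce — adding the
binary margin to the clinical model changes little (C-index 0.632 →
0.634, LRT p=0.11), while adding the MRIx category improves both
discrimination (C-index 0.669) and fit (ΔAIC ≈ −49, LRT p<0.001):

```python
pipeline.compare_models(cohort, "lrc").to_frame()
```

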