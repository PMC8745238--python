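# crclm-fm

Formal-methods classification of CT liver radiomics traces, for researchers
studying the **early prediction of colorectal-cancer liver metastases
(CRCLM)** from portal-phase CT before any lesion is visible to the eye.

Instead of feeding radiomic features to a statistical classifier, the
pipeline builds, per patient, a *formal model* — a finite labelled
transition system (LTS) encoding the slice-by-slice sequence of discretised
texture observations of the liver parenchyma — and asks a modal mu-calculus
model checker whether the model satisfies a "disease property". The property
itself is induced from labelled examples as a disjunction of discriminating
ordered patterns.

## Method at a glance

1. **Features.** For every CT slice `s` with liver ROI mask `M_s`, 22
   radiomic features are computed from scratch in five families (FIRST,
   GLDM, GLCM, GLRLM, GLSZM) following the IBSI definitions: e.g. first-order
   entropy `−Σ_g p(g) log₂ p(g)` on the 32-bin min–max quantised histogram,
   GLCM autocorrelation `Σ_{i,j} i·j·p(i,j)` averaged over the four 2D
   directions, GLSZM small-area low-gray-level emphasis
   `Σ_{g,s} p(g,s)/(s²g²)`, and so on.
2. **Selection.** Features are ranked by the information gain (bits) of an
   entropy-optimal binary split of per-patient medians against the class
   labels, and a family-restricted subset is retained.
3. **Formal model.** Each retained feature value of each slice is mapped to
   a quantile level `L1..LK` (K = 5, cuts at the pooled training quantiles),
   emitting one action `feature=Lk` per observation; a patient becomes the
   chain `s₀ →a₁ s₁ →a₂ … →aₙ sₙ`, serialised as Aldebaran `.aut`.
4. **Property induction.** Ordered subsequence patterns frequent in
   metastatic training traces (support ≥ 0.8) and absent from healthy ones
   (support = 0) are mined exhaustively and encoded as nested least-fixpoint
   reachability formulas, `mu X₁.(<a₁>(mu X₂.(<a₂>tt | <−>X₂)) | <−>X₁)`.
5. **Verification & statistics.** A patient is called *metastatic* iff the
   model checker verifies the induced property on the patient's LTS.
   Leave-one-out cross-validation produces a confusion matrix and the full
   accuracy/utility report: sensitivity, specificity, PPV/NPV, likelihood
   ratios, and Mitchell's clinical utility indices `CUI+ = sens × PPV`,
   `CUI− = spec × NPV` with qualitative grades.

The original cohort (21 healthy controls, 9 future-CRCLM cases, ~70 ROI
slices per patient) is private, so the package ships a seeded phantom
generator: Gaussian-random-field slices with class-specific standard
deviation and correlation length, elliptical ROIs, and benign lesion blobs
in both classes. See `docs/methods.md` for model details and limitations.

## Worked example

```python
from crclm_fm import PipelineConfig, run_pipeline
from crclm_fm.phantoms import PhantomConfig

report = run_pipeline(PipelineConfig(phantom=PhantomConfig(seed=1, effect_size=2.0)))
print(report["metrics"]["confusion_matrix"])
print(report["metrics"]["rendered"])
```

prints (deterministically for this seed)

```text
{'tp': 9, 'fp': 0, 'fn': 0, 'tn': 21}
{'sensitivity': '100.0%', 'specificity': '100.0%',
 'positive_predictive_value': '100.0%', 'negative_predictive_value': '100.0%',
 'positive_likelihood_ratio': 'Inf', 'negative_likelihood_ratio': '0.000',
 'test_score': '100.0%', 'prevalence': '30.0%',
 'clinical_utility_positive': '1.000', 'clinical_utility_positive_grade': 'Excellent',
 'clinical_utility_negative': '1.000', 'clinical_utility_negative_grade': 'Excellent'}
```

i.e. under a planted texture shift of twice the configured class difference,
leave-one-out cross-validation detects all 9 cases with no false positive on
the 21 controls; `Inf` is the positive-likelihood-ratio sentinel used when
specificity is exactly 1. With `effect_size=0.0` (identical classes) the
precision-first rules find no reliable marker and nobody is called positive.

The same stages are available from the shell:

```bash
crclm-fm simulate --out cohort/ --seed 1
crclm-fm extract --volume cohort/P001.nrrd --mask cohort/P001_mask.nrrd --out P001.csv
crclm-fm check --lts P001.aut --formula disease.mu   # exit code 0 iff True
crclm-fm run-all --out results/ --seed 1
```

Library users wanting scikit-learn composition can use
`crclm_fm.FormalMethodsClassifier` directly: `fit(tables, labels)` on a list
of per-patient feature tables, `predict(tables)` for new patients.

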