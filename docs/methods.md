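# Methods

This note documents the models, parameter choices and limitations behind
`crclm-fm`: a pipeline that classifies patients as "metastatic" or
"healthy" by model-checking an induced temporal-logic property on a formal
model of each patient's CT radiomics trace.

## 1. The phantom generator

The cohort the pipeline emulates — 21 healthy controls and 9 patients who
later developed colorectal-cancer liver metastases, with 56–92 segmented
portal-phase slices per patient — is private, so `crclm_fm.phantoms`
generates controllable stand-ins.

Each slice is a Gaussian random field: white noise smoothed with a Gaussian
kernel of width ℓ (the *correlation length*), renormalised to unit variance,
then scaled and shifted to the class's intensity standard deviation σ and
mean μ. The ROI is an ellipse of configurable radius (default 20 px in a
64×64 slice, ≈1250 in-mask pixels) with per-slice jitter in centre and
eccentricity. With per-slice probability 0.05 a benign "lesion" — a smooth
hyper- or hypodense Gaussian blob of radius 2–4 px and amplitude 20–40 HU —
is added inside the ROI, *in both classes*, mirroring the study design in
which angiomas and cysts were not exclusion criteria.

Defaults (healthy → case): μ 100 → 112 HU, σ 15 → 22, ℓ 2.0 → 3.5 px. The
original study publishes no ROI intensity statistics, so these are package
choices: σ and ℓ in the range of portal-phase parenchyma noise texture, and
class differences large enough to be learnable at n = 30 at `effect_size`
≈ 2. `effect_size` linearly scales all three class differences; 0 makes the
classes statistically identical (the null cohort), 1 is the default.

Two deliberate properties of this design:

* **The mean shift is invisible downstream.** All texture features operate
  on fixed-bin-count min–max quantised levels, which are invariant under
  affine intensity rescaling; and none of the 22 features is a raw mean.
  Class separation is therefore carried by σ (the dispersion features:
  IQR, MAD, robust MAD) and ℓ (the dependence/run/zone/co-occurrence
  structure). μ is retained in the generator for realism of the values only.
* **Per-patient seeds** are derived from the master seed by a fixed affine
  counter scheme (`master·1000003 + 7919·i + 1 mod 2³¹`), so any patient can
  be regenerated independently from the manifest.

What the phantom does *not* emulate: anatomically shaped livers, vessels,
scanner/kernel/contrast effects, inter-patient biological variability
(slices are i.i.d. given the class), or any spatial progression of disease
along the cranio-caudal axis. Passing end-to-end tests therefore show that
the pipeline recovers a *planted, stationary texture difference* under its
own protocol — not that it would detect pre-metastatic change on real CT.

## 2. Radiomic features

The 22 features (families FIRST, GLDM, GLCM, GLRLM, GLSZM) are implemented
from scratch following the IBSI definitions, strictly 2D and per slice,
because the upstream design ties one feature value to one slice. Choices
the source design leaves open, fixed here to standard values:

* Quantisation: equal-width bins between in-mask min and max, default 32
  bins; a constant ROI maps to level 1. Fixed bin *count* (not width) gives
  the affine invariance above.
* GLCM: distance 1, four 2D directions, symmetric accumulation, features
  averaged over directions. GLRLM likewise averaged over the four
  directions.
* GLDM: dependence tolerance α = 0; 8-connectivity. The dependence index
  used in the emphasis formulas is the size of the dependent group
  *including the centre pixel* (j = dependent neighbours + 1), so isolated
  pixels land at j = 1 and the `1/j²` weights are always defined.
* GLSZM: zones are 8-connected components of equal level.
* Robust MAD: mean absolute deviation of the closed [P10, P90] sub-sample.
* Degenerate matrices (no valid pixel pair in any direction) yield NaN
  features with a warning; downstream discretisation maps NaN to the lowest
  level, again with a warning.

Entropies are in bits throughout. Every implementation is tested to 1e-9
against independent brute-force oracles (nested-loop pair counting,
neighbour counting, explicit run scanning, flood fill) on random ROIs.

## 3. Feature selection

Labels are per patient while slices are not independent, so each patient is
summarised by its per-feature median before ranking. Each feature is scored
by the information gain of the best single binary split (all midpoints
between consecutive distinct values are candidates) — a deterministic,
inspectable stand-in for the original study's attribute-selection software,
adequate at n = 30. Ties break lexicographically on the canonical name.
Selection keeps features with gain strictly above a threshold (default 0)
whose family is in the configured set; the default family set
{FIRST, GLDM, GLSZM} mirrors the three families the source study reported
as most discriminating. Selection, like everything fitted, is re-estimated
inside each cross-validation fold.

## 4. The formal model

A patient's table of selected features is discretised into quantile levels
`L1..LK` (cuts at the pooled 1/K..(K−1)/K training quantiles, both classes
pooled; value equal to a cut maps to the lower level; duplicate cuts
collapse with a warning) and unrolled — slices in cranio-caudal order,
features in canonical order within a slice — into a linear chain LTS with
one action `feature=Lk` per observation. Chains are serialised in Aldebaran
`.aut` format.

**Choice of K.** K must be large enough that the extreme levels can be
class-exclusive. In a 21/9 cohort the metastatic class contributes ≈30% of
pooled slices, so the top level's cut sits at the (K−1)/K pooled quantile:
for K = 3 that is 66.7% < 70%, i.e. the top tercile *necessarily* contains
control slices, and over ~70 slices every control trace contains every
top-level symbol — no zero-negative-support rule can exist and the
precision-first induction below degenerates. K = 4 (cut at 75%) clears the
70% boundary with no margin and proved brittle against benign-lesion
outlier slices; the default K = 5 places the extreme cuts at 20%/80%, one
full level (10 points of pooled mass) beyond the class boundary on either
side. Larger K buys little and thins the per-level support.

## 5. Property induction and model checking

The disease property is learned as a set of **ordered subsequence
patterns** over the action alphabet: pattern `a₁…a_k` matches a trace if
the symbols occur in order, with arbitrary gaps. Subsequence (not
substring) semantics reflects that precursor texture may appear on any
slices along the liver. Mining is an exhaustive level-wise search up to
`max_len` (default 2) with apriori pruning on the positive support, keeping
patterns contained in ≥ 80% of metastatic training traces and in *no*
healthy training trace (`max_support_neg = 0`); by construction the learned
property never fires on a healthy training patient — a precision-first
design. Accepted rules are ordered deterministically (positive support
desc, length asc, lexicographic) and the top 20 are disjoined.

Each pattern is encoded as nested least-fixpoint reachability:
`φ_{k+1} = tt`, `φ_i = mu X_i.(<a_i>φ_{i+1} | <−>X_i)`; satisfaction of
`φ_1` at the initial state of a chain is provably equivalent to subsequence
containment, and this equivalence is property-tested against an
independent subsequence oracle.

The model checker implements the standard modal mu-calculus semantics by
naive Knaster–Tarski iteration on state sets (numpy boolean vectors; closed
subformulas evaluated once per check). Negation is syntactically restricted
to closed subformulas, which guarantees monotone fixpoint bodies; the
parser rejects unbound variables. On the linear chains used here (≤ ~2000
states) the naive algorithm is ample: each fixpoint stabilises in at most
|S| + 1 iterations.

## 6. Evaluation protocol and statistics

Leave-one-out cross-validation over the cohort: per fold, feature ranking,
discretisation scheme and pattern rules are re-fitted on the 29 training
patients and the held-out patient is classified by model checking. The
report carries the confusion matrix (metastatic positive), precision/PPV,
recall/sensitivity, specificity, NPV, accuracy, prevalence, LR+ and LR−,
and Mitchell's clinical utility indices CUI+ = sens × PPV and
CUI− = spec × NPV with grades Excellent (≥ 0.81), Good (≥ 0.64),
Satisfactory (≥ 0.49), Poor (< 0.49) — cut-offs that reproduce the grades
printed in the emulated study. Undefined ratios are explicit `"n/a"`
markers; an infinite LR+ is the sentinel string `"Inf"`; percentages render
to one decimal, half away from zero. Wilson intervals are available for any
proportion but are not part of the default report.

## 7. Numerical and degenerate-input conventions

* Quantile cuts use numpy's default (linear-interpolation) quantiles.
* Equal-value ties at a cut map to the lower level (left-closed).
* An empty rule set induces the property `ff`: nobody is called metastatic.
* An empty feature selection skips discretisation entirely and predicts
  "healthy" for everyone, with a warning.
* Empty ROI masks, single-class training sets, mismatched patient id sets
  and out-of-range utility values raise errors rather than propagating
  silent NaN.

## 8. Problem sizes used in the test suite

Unit tests run on miniature inputs (ROIs ≤ 8×8 against brute-force oracles,
chains ≤ 15 actions against graph oracles). The end-to-end tests run the
full emulated cohort shape — 30 patients, 56–92 slices of 64×64 pixels —
once with a planted shift (`effect_size = 2`), once as a null cohort
(`effect_size = 0`), and once more for bitwise determinism; the three runs
take on the order of half a minute in total.

## 9. Known limitations

* The phantom's benign lesions are the main confound: a control patient
  with several strong lesion slices can express case-like texture symbols
  (especially dependence entropy) that no training control showed, in which
  case leave-one-out classification can produce an occasional false
  positive or an empty rule set. Across master seeds the planted-signal
  recovery at `effect_size = 2` achieves perfect precision on most but not
  all seeds; the distributed tests fix the seed and are deterministic. A
  richer lesion model (shared lesion library, patient-level lesion
  burden) would let the miner learn to ignore the confound explicitly.
* Single-feature micro-transitions discard within-slice feature *conjunction*
  ("high dispersion AND coarse texture on the same slice"); composite
  per-slice actions would restore it at the cost of an exponentially larger
  alphabet.
* Information-gain ranking on 30 patient medians is optimistically biased
  (the best split is chosen post hoc); it is used only to order features,
  never as an inferential statistic.
* The pipeline is 2D per slice by construction; no 3D texture aggregation
  is attempted.
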