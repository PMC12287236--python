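# Methods

This note documents the models, the synthetic data they are tested on, the
numerical choices, and the limits of what the tests demonstrate.

## Data model

A slide is represented at patch resolution: a grid of 150 px patches
(nominally 20× magnification; magnification is metadata only, nothing is
rescaled). Each grid cell carries one of six tissue categories — Tumor,
Necrosis, Fibrosis, Lymphocyte, NormalLiver, Other — or Blank for removed
background. A patch is blank when more than 75% of its pixels exceed a
mean-RGB luminance of 220/255; the 75% rule is strict ("more than"), the
luminance threshold is configuration, not dogma. Blank cells are excluded
from every downstream feature computation, including boundary edges (an
edge from Tumor into Blank is not tissue boundary). Coordinates are
0-based, row-major, half-open pixel boxes; trailing partial tiles are
dropped rather than padded, matching fixed-size patch training.

## Survival objective

All three learned models (ATAT, the global encoder, the HDS network) are
trained by minimizing the mean negative Cox partial log-likelihood with
Breslow tie handling over full-cohort risk sets. Breslow was chosen over
Efron because it is the standard differentiable form for deep survival
heads; the inference-side Cox regression defaults to Breslow for
consistency (Efron is available through the fitting backend). The loss is
implemented on a small in-package reverse-mode autodiff engine over numpy
arrays; its gradients are verified against finite differences in the test
suite, and the loss value against a brute-force risk-set summation.

## ATAT

Within each tissue category c the instance matrix X_c is pooled by gated
attention: a = softmax(w·(tanh(X V) ⊙ σ(X U))), z_c = aᵀX_c. The pooled
category embeddings pass through one self-attention layer (queries, keys,
values of width `inter_dim`); the resulting context vectors are projected
to scalars and softmaxed over the categories *present in the bag*, giving
the category-importance weights γ. The slide embedding is Σ_c γ_c z_c and a
linear head maps it to risk. Two consequences are load-bearing:

* risk is exactly invariant to instance order and to duplicating all
  instances of a category (softmax attention is a weighted mean);
* because the importance-weighted sum is taken over the *raw* category
  embeddings (not the mixed attention context), the model can only use a
  category's evidence by putting importance mass on it — which is what
  makes γ an interpretability output. An earlier variant that summed the
  attention-mixed context discriminated equally well but produced
  uninformative γ; the current form is the deliberate design.

Absent categories are excluded from the importance softmax (slides without
necrosis contribute no necrosis term). Defaults: attention hidden width 32,
inter-class width 16, Adam at 5e-3, 30 epochs, fixed-seed init; all
exposed in `ATATConfig`.

## Feature views

**MM.** Per class in {Tumor, Necrosis, Lymphocyte}: area fraction of
non-Blank tissue, 4-connected component count, largest-component fraction,
and boundary-to-area ratio. These are label-map statistics, deliberately
deterministic and enumerable, so each has an exact oracle.

**CL.** Adjacency is the 4-neighborhood; J(A→B) is the fraction of
adjacencies incident to A that cross into B (0 when A is absent), the
triple-junction density is the fraction of 2×2 windows containing all
three key classes (the smallest window that can witness a three-way
junction), and each pair gets an enrichment z against `n_perm` random
relabelings of the non-Blank cells (abundances preserved, spatial
structure destroyed). `n_perm` defaults to 200 — z estimates stabilize
well before that; below ~10 the null moments are too noisy, so smaller
values are rejected. Under spatially unstructured maps the z is ~N(0,1),
which the suite checks.

**DG.** A transformer-style MIL encoder: instances are projected to
`embed_dim` (16), a learned class token is prepended, one self-attention
layer with residual connection mixes the tokens, and the class-token
output is the slide's DG vector (a linear head on it provides the
training-time risk). Token sets are canonicalized by row-unique + lexical
sort, then capped at `max_tokens` (128) by a per-slide seeded subsample —
this makes DG exactly invariant to instance order and duplication, at the
cost of treating repeated identical embeddings as one instance (harmless
for continuous embeddings, where exact repeats only arise from actual
duplication).

## HDS

The concatenated views are standardized with training-cohort mean/sd
(frozen at fit time and applied unchanged to later cohorts — validation
patients are never allowed to influence the scale), then passed through a
SELU network with LeCun-normal initialization and alpha-dropout, ending in
a linear risk unit. The published SELU constants (λ≈1.0507, α≈1.6733) are
fixed; the self-normalizing property (activation mean ≈0, variance ≈1 at
initialization) is asserted in the tests. Default widths are (32, 16) with
alpha-dropout 0.10 for 80 epochs: at the cohort scale this package targets
(hundreds of patients, ~35 features) a wider (64, 32)/0.05 network
overfit — training c-index near 0.94 while validation dropped below the
best single view — so the smaller, more regularized default was adopted;
widths and rate remain configuration.

Risk groups use the training-cohort median as cutoff with a strict
greater-than rule (a score exactly at the cutoff is low risk); on distinct
scores this splits the training cohort within one patient of half. Stage
refinement splits each designated low-risk clinical stage by HDS group and
reports per-stratum Kaplan–Meier curves with unadjusted pairwise log-rank
p values (a Bonferroni-style correction is left to the caller, since the
number of informative pairs is context-dependent); strata under two
patients are excluded and listed. The HDS+staging combination is a
two-covariate Cox fit on (HDS, ordinal stage); near-collinear inputs are
flagged by the correlation-matrix condition number and stabilized with a
small ridge penalty.

## Survival statistics

Kaplan–Meier, log-rank and Cox regression are delegated to lifelines, and
the time-dependent AUC (cumulative cases / dynamic controls with
inverse-probability-of-censoring weights from the training cohort) to
scikit-survival, each behind this package's own interfaces. Harrell's
c-index counts score ties as 1/2. CIs are the normal approximation
exp(β ± 1.96·SE). All tests are two-sided at α = 0.05. Every estimator is
cross-checked in the test suite against a brute-force enumeration oracle:
risk-set sums for the Cox likelihood, exhaustive pair counting for the
c-index and IPCW AUC, hand product-limit for KM, and O−E/V summation for
the log-rank statistic. The IPCW oracle comparisons use tie-free
(continuous) times, because conventions for coincident event/censoring
times differ across implementations at the 1e-5 level.

## Synthetic cohort

The generator is the study's stand-in for real slides, and its defaults
are the conditions the experiments assume:

* **Tissue maps** (16×16 default grid): tumor blobs grown by seeded random
  walk with 4-neighbor dilation fallback (connected, irregular margins).
  High-risk style adds a necrotic core grown inside the tumor mass
  (20–40% of it) and a lymphocyte band on the blob perimeter (80%
  occupancy); low-risk style has no necrosis and at most 1% scattered
  lymphocytes. A small Blank corner wedge mimics slide background.
* **Embeddings**: category centroid (separation 3.0 on one axis of a
  16-dim space) plus isotropic N(0, 1) noise — linearly separable but not
  trivially so, matching what a pretrained CNN embedder produces for
  visually distinct tissue.
* **Survival**: T ~ Exponential(0.02·exp(βᵀz)) months with independent
  Exponential(0.01) censoring, so a null patient has median DFS ≈ 35
  months and the cohort is ~⅓ censored — plausible for resected HCC. The
  linear predictor loads on the z-scored *true* J(Necrosis→Tumor) (β=1.5),
  J(Lymphocyte→Tumor) (β=1.0) and necrosis area fraction (β=0.5) of the
  generated maps, so "the pipeline recovers prognostic morphology" is a
  falsifiable claim, not a tautology: models see only maps, embeddings and
  outcomes, never the planted truth.
* **Cohort**: 400 patients, risk mix 0.5, event-stratified 8:2
  train/validation split. Stage and subgroup labels (stage, sex, age
  group) are assigned independently of the planted signal, so the
  stage-refinement experiment measures what HDS adds *within* a stage.

Everything is deterministic given the seed, down to the bytes of the
written files (bag archives are zip containers with fixed metadata).

What the generator does **not** emulate: H&E texture and stain variation,
pixel-level nuclear morphometry, classifier label noise correlated with
morphology, informative censoring, and inter-cohort covariate shift.
Passing tests therefore demonstrate the correctness and recovery behavior
of the algorithms, not clinical performance on real slides.

## Permutation-null controls

Negative controls permute the (time, event) pairs across the whole cohort
*before* the train/validation split; the retrained model is evaluated
against the permuted validation labels. Under this exchangeable null the
c-index concentrates at 0.5. (Evaluating a permuted-label model against
the real labels does not give a concentrated null when the feature space
has one dominant risk direction: the refit lands near ±that direction and
the c-index lands far from 0.5 with a sign set by chance.)

## Problem sizes

The recovery experiments run at 400 patients on 16×16 grids with 30/40/80
epochs for ATAT/encoder/HDS, the log-rank and chi-square calibrations at
1000–2000 replicates, and CI coverage at 400 replicates of n=100 — sizes
at which every reported property is stable across seeds while the full
suite stays desk-scale.

## Known limitations

* The patch classifier's raw-pixel backend is a small MLP; it is a
  placeholder for a real histology network and is not expected to reach
  published patch-classification AUCs on real tissue.
* The global encoder is a single-layer, single-head attention encoder;
  deeper stacks (and the published positional schemes) are out of scope.
* Cox fits assume proportional hazards, which the generator satisfies by
  construction; no PH diagnostics are included.
* The view-independence chi-square is reported for completeness; on the
  planted cohort all three views deliberately share one planted signal,
  so they test dependent there — independence holds (and is verified) only
  under null simulations.
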