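# Methods

## The problem and the model

The package targets preoperative discrimination of lung granulomatous
nodules (LGN, label 0) from lung adenocarcinoma (LAC, label 1) among
solitary pulmonary solid nodules ≤ 30 mm on CT.  Its core is an adaptive
cross-domain transfer model with three parts: a **source network**
pretrained on auxiliary labelled images; a **target network** of the
same backbone family trained on nodule patches; and a **source-domain
feature-selection network** — two meta-networks that decide *what* to
transfer and *how* to align it.

### Backbone

Both networks are six-stage convolutional backbones (3 × 3 kernels,
stride 2 per stage except the last, ReLU), with stage widths
`[64, 128, 256, 512, 1024, 1920]`.  The feature vector of an image is
the concatenation of globally average-pooled stage activations, hence
exactly **3904 features** per patient at the default widths.  A
`width_scale` multiplier shrinks every stage for desk-scale runs (0.25
→ 976 features); the extraction contract (feature width = sum of stage
widths) holds for any configuration.  The engine is a small,
deterministic numpy implementation (im2col convolutions, manual
backprop, Adam); identical seeds give bit-identical runs, which the
determinism tests rely on.

### The transfer constraint

During target training the frozen source network is run on the same
patches, and each stage adds

    λ · (1/C) Σ_c g_c · ‖(M t)_c − s_c‖² / P

to the cross-entropy loss (`t` target stage activations, `s` source
stage activations, `P` spatial positions, batch-averaged).  `M` (one
square matrix per stage, initialised to identity — "meta-net B") is
trained jointly with the target weights on this loss and absorbs
rotations/scalings between the two representations.  The gates `g` =
`sigmoid(a_c + b_c · pooled_c)` ("meta-net A") are trained once per
epoch against the **validation cohort**: a logistic probe predicts
validation labels from gated, pooled source features, with an L1
penalty (`ρ = 0.05`) on the gates.  Channels that do not help the
target task therefore see their gates fall below the 0.5
initialisation, shrinking the constraint — the mechanism that bounds
negative transfer from mismatched sources.  This validation-probe rule
is a deliberately first-order surrogate for full hypergradient
meta-learning: it is cheap, stable and testable; exact unrolled
differentiation is out of scope.

With `λ = 0` and gates frozen the trainer reduces exactly to the
non-transfer baseline (same initialisation, same batch order), which is
asserted bit-for-bit in the tests.

Training defaults (target: 10 epochs, batch 32, Adam lr 1e-3, `λ = 8`;
source pretraining: 20 epochs) were fixed by design experiments on the
synthetic task: the transfer benefit emerges in the later epochs, once
the scratch baseline has exhausted the easy intensity/size signal, and
a constraint weight of order 1–10 is needed for the matching term to
compete with the task gradient.  They are configuration values, not
tuned per run.

## Signature (TLS)

Screening strictly precedes selection.  Each of the 3904 features gets
a two-sided Mann–Whitney U test (exact enumeration when both groups
have ≤ 8 patients, tie-corrected normal approximation otherwise;
engine shared with the cohort-table Wilcoxon test); features with
p < 0.05 pass.  No multiplicity correction is applied — screening is a
liberal pre-filter, and the final selection happens downstream.

The sparse Bayesian ELM is the linear-kernel variant: ARD Bayesian
logistic regression (identity "hidden layer" plus bias) so that pruning
yields explicit feature selection; a classic random sigmoid hidden
layer is available as a config option, with selection then acting on
hidden units.  Fitting is evidence maximisation under a Laplace
approximation: Newton MAP under current precisions, then
`α_j ← (γ_j + 2a)/(w_j² + 2b)` with a weak proper Gamma hyperprior
(`a = 1`, `b = 1e-6`), pruning at `α_j > 1e4`, tolerance 1e-4 on
log-precision change, ≤ 200 iterations.  The hyperprior matters: with
the improper flat hyperprior the Laplace-approximated evidence
under-penalises weakly informative features in logistic models and the
fixed point retains a dozen null features; the weak Gamma prior
restores the expected behaviour (planted separating features retained,
permuted-label fits pruned to near-empty), which the recovery tests
check.  Exactly duplicated (standardised) columns are collapsed before
fitting — they carry no information and break identifiability.
Features are standardised on the training cohort and the transform is
frozen for validation scoring.  Scores are the logistic link on the
posterior-mode weights.

## Fusion (TLRM) and clinical statistics

Cohort-table screening dispatches by type: continuous → Wilcoxon
rank-sum; categorical → Pearson chi-square **without** continuity
correction (this reproduces the printed reference p-values to 4
decimals), falling back to a full margin-fixed enumeration Fisher exact
test (2 × k, k ≤ 5) when any expected count is below 5.  Cohen's kappa
uses the standard `(p_o − p_e)/(1 − p_e)` form and flags the degenerate
`p_e = 1` case.

The TLRM is a sparse Bayesian LASSO: Bayesian logistic regression with
a hierarchical Laplace (exponential scale-mixture) prior, optimised by
EM — per-weight ridge precision `λ/|w_j|`, Newton M-step — whose fixed
point is the L1-penalised mode.  The EM is started from a mild ridge
fit because `w = 0` is an absorbing state of the reweighting.
`prior_scale` is the penalty weight λ (larger = more shrinkage;
retained-set size is monotone non-increasing in it, tested on a grid);
the default `λ = √(n log p)` scales with the information in the data.
Standardised coefficients below `1e-3` are dropped and the survivors
refit unpenalised (vague ridge guards separation).  Continuous
covariates are standardised; binaries are coded 0/1 (women = 0,
absence = 0).  The clinical comparator is maximum-likelihood logistic
regression (statsmodels) over gender, age, lobulated shape and
spiculated sign, with a ridge fallback plus warning under separation.

## Domain similarity

Domains are compared in a shared embedding — pooled stage features of
the pretrained source network, or raw flattened pixels — via the
sliced 1-Wasserstein distance: the exact 1-D distance (quantile
matching; equal sizes reduce to mean |sorted difference|) averaged over
seeded uniform random unit projections (default 256; domains larger
than 2000 vectors are seeded-subsampled).  The estimator is symmetric,
non-negative and zero on identical vector sets (property-tested), and
on two point masses converges to `‖x − y‖ · E|u₁|`, checked against the
closed form.  Sources are ranked ascending by distance, ties broken by
name.  Exact high-dimensional optimal transport is deliberately not
used: the sliced estimator is deterministic, cheap, and has an exact
1-D oracle for testing.

## Evaluation stack

* AUC in the Mann–Whitney form (ties ½), equal to an all-pairs count
  (oracle-tested).
* DeLong structural components for the variance of one AUC, the
  correlated two-model test and 95% CIs (truncated to [0, 1]);
  degenerate zero-variance comparisons report z = 0, p = 1.
* Operating threshold: Youden index maximiser on the training cohort
  (ties → lower threshold), frozen for validation cohorts — the
  standard choice when the source material does not state a rule.
* IDI as the difference of discrimination slopes with a paired z-test.
* Hosmer–Lemeshow over g = 10 equal-count risk groups (ties assigned to
  the lower group, emptied groups merged with a warning), df = g − 2.
  The pipeline shrinks g for very small validation sets
  (`g = min(10, max(3, n/3))`).
* Decision curves: `NB(pt) = TP/n − FP/n · pt/(1−pt)` on the 0.01–1.00
  grid; pt = 1.00 has an undefined weight and is reported as missing.
* Stratified analysis: per-stratum AUC + CI and a DeLong comparison
  against the pooled cohort, with the stratum-vs-pooled covariance
  estimated from structural components on the shared samples;
  single-class strata are skipped with a flag.  A stratum equal to the
  whole cohort compares a quantity with itself and reports p = 1.

## Synthetic data: what it emulates, and what it does not

`fixtures` renders nodules in polar form on a 50 mm field of view:
lobulation = low-frequency boundary undulation, spiculation = narrow
(~1 mm) radial spikes, irregular margin = high-frequency low-amplitude
boundary roughness, on a lung-window background with seeded smoothed
texture.  Cohort covariates are sampled from class-conditional
distributions whose location/scale defaults are the whole-validation
summary statistics of the emulated study population (LGN age
53.42 ± 11.99 y vs LAC 60.13 ± 10.08 y; sizes 12.45 ± 6.66 vs
18.91 ± 7.65 mm; the printed gender/location/margin/lobulation/
spiculation proportions).  Class prevalence uses exact-count
allocation, so a 50% spec yields exactly half LAC.  Values the study
does not print — nodule core attenuation (≈ 2–36 pseudo-HU by class),
texture heterogeneity, lobulation/spiculation counts given presence —
were chosen once so that the *image* carries discriminative signal
beyond the tabulated covariates (solid benign and malignant nodules
share soft-tissue attenuation; morphology and heterogeneity carry the
margin), making the imaging signature outperform the clinical model as
in the emulated study.  Source domains share the target renderer with
probability `target_overlap` and otherwise use independent generators
(cell-like tiles, gradient/geometry images, hard-edged disks), so
distributional distance decreases monotonically in overlap.

What passing the synthetic benchmark shows: the machinery behaves
directionally as designed — matched-source transfer beats scratch
training on average, the Wasserstein ranking recovers the constructed
similarity order, more similar sources transfer better, and fusion
dominates either modality alone.  What it does not show: performance on
real CT (no scanner physics, no 3-D context, no inter-reader noise, no
site effects), nor the absolute AUC levels of any clinical cohort.

## Problem sizes

The multi-seed benchmark runs 300 patients per seed (48 px patches,
width_scale 0.25, 70/30 patient-level split), three 300-image source
domains pretrained once and reused across ten seeds, and raw-pixel
embeddings with 64 projections for the distance ranking.  These sizes
keep a full ten-seed benchmark around ten minutes on one CPU core while
leaving each directional comparison a clear margin.  The default
end-to-end pipeline config is smaller still (160 patients, 64 px) and
the full-width 3904-feature extraction is exercised at 224 px.

## Known limitations

* The meta-networks are a reference design; richer gate
  parameterisations (feature-dependent MLPs) and true bilevel updates
  are plausible extensions.
* The SBELM's Laplace approximation is known to be optimistic near
  separation; the Gamma hyperprior compensates but is itself a modelling
  choice.
* Fisher's exact test enumerates 2 × k tables only up to k = 5 and a
  bounded table space; the screening dispatcher falls back to
  chi-square beyond that, with the test name recorded.
* Per-seed transfer gains are noisy at n = 300; the package's claims are
  about multi-seed means, not single runs.
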