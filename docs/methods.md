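# Methods

`tauroi` re-implements, as a tested pipeline over synthetic data, a
cross-tracer tau-PET region-of-interest (ROI) analysis: given per-subject
regional SUVR tables for three tau tracers ([18F]flortaucipir, [18F]RO948,
[18F]MK6240), it builds theory-driven and data-driven composite ROIs,
estimates their diagnostic accuracy for separating Alzheimer's disease (AD)
dementia from cognitively unimpaired (CU) individuals and from non-AD
neurodegenerative disorders, derives Youden-index SUVR cut-points, compares
ROIs with paired DeLong tests, and summarizes whether a common ROI and
cut-off (temporal meta-ROI, ~1.35 SUVR) supports tau-positivity
classification across tracers.

No subject-level data from the original cohorts is available, so every
stage runs on a synthetic cohort generator calibrated to the published
group-level structure. This note documents the generative model, the
calibration, the statistical procedures, the open design choices, and what
the synthetic results do and do not show.

## Synthetic cohort model

**Atlas.** A Desikan–Killiany-style label set: 31 bilateral cortical
regions (62 labels) plus the bilateral amygdala, each with a nominal volume
(round mm³ values; only relative weights matter) and a coarse Braak stage
class — `I_II` (entorhinal), `III_IV` (amygdala, parahippocampal, fusiform,
inferior/middle temporal), `V_VI` (all remaining cortex). An `off_target`
class is supported (zero tau response, optional additive shift) but unused
by the default atlas.

**Latent severity.** Each subject draws a single latent tau burden
`z ~ N(mu, sd^2)` from its (group, amyloid-status) stratum. Region `r` with
stage class `c` accumulates burden through a logistic dose–response

    burden_r(z) = expit((z - theta_c) / tau)

with ordered onsets `theta_I_II <= theta_III_IV <= theta_V_VI`, so
early-stage regions saturate first — a minimal stand-in for Braak-ordered
spread. A tracer maps burden to SUVR affinely with additive Gaussian noise:

    suvr_r = a_t + b_t * burden_r + shift_c + eps,  eps ~ N(0, sigma_t^2),

truncated below at 0.05 SUVR to keep ratios positive. `b_t` encodes the
tracer's dynamic range, `shift_c` a per-stage-class additive offset (used
here to reproduce tracer-specific regional baselines), `sigma_t` per-region
measurement noise.

CU heterogeneity is a two-component mixture: the amyloid-positive stratum
(22–43% of CU depending on tracer) carries its own latent mean/SD, because a
unimodal CU distribution cannot reproduce the published CU/AD overlap.
Amyloid status is assigned as an exact count `round(n * fraction)` per group
(order shuffled by the seeded RNG), so stratum sizes — and the subset-filter
row counts below — are deterministic. AD groups are amyloid-positive by
definition. Age, sex and education are not generated (out of scope).

**Non-AD composition.** Each tracer preset reproduces the published non-AD
subtype mix (e.g. flortaucipir: 15 CBS, 18 DLB, 3 MSA, 65 PD/PDD, 14 PNFA,
6 SD, 26 bvFTD, 4 VaD, 27 PSP). The published tables lump PD/PDD; the
presets split them (40 PD + 25 PDD for flortaucipir, 27 + 20 for RO948) so
the "exclude PD without dementia" filter is well defined. Amyloid-positive
counts within PD/PDD/DLB are set so the "exclude amyloid-positive
PD/PDD/DLB" filter removes exactly 26 (flortaucipir) and 31 (RO948) rows,
with total non-AD amyloid-positive counts matching the published 29 / 52 / 0.
All non-AD subtypes share one latent distribution per stratum: the analysis
treats non-AD as a single comparison group, so subtype-specific tau
topographies (e.g. PSP subcortical binding) are not modeled.

## Calibration of the tracer presets

Preset parameters are not hand-picked: for each tracer a deterministic
least-squares fit chooses the 17 free parameters (affine map `a_t, b_t`,
class shifts, noise SD, two onset gaps, slope `tau`, and per-stratum latent
means/SDs) so the model-implied group means of the four theory-driven
composites match the published group means for CU, non-AD and AD.
Expectations under the latent normal are computed by Gauss–Hermite
quadrature (120 nodes for moments — enough to resolve steep dose–response
fits — and 40×40 for pairwise integrals). The objective combines:

* **means, hard:** residual plus a hinge penalty (weight 8) on any deviation
  above 0.02 SUVR;
* **SDs, soft:** weight 0.2 (0.15 for RO948), because the single-latent
  model cannot reproduce every published dispersion exactly;
* **AUC ordering:** a hinge on the model-implied Mann–Whitney AUC gap
  requiring the temporal meta-ROI to out-discriminate the neocortical
  meta-ROI for AD vs CU by ≥0.03 (0.05 for MK6240, whose AD group of 50
  needs a wider population gap for the sampled ordering to hold reliably) —
  this enforces the published ROI ranking;
* a small ridge to the starting point for identifiability.

Two fixed starting points per tracer are tried and the lower-cost fit kept;
the whole calibration is pure computation (no randomness) and is cached per
process (~1 minute).

Achieved fidelity: all 36 published group means (3 tracers × 3 groups × 4
composites) are matched within ±0.021 SUVR by the model and within ±0.03 in
5000-subject simulations. Dispersion is looser: RO948 CU SDs in particular
come out near 0.45 where the reported dispersion is ~0.18, because the
published RO948 pattern (CU neocortex 0.15 SUVR above non-AD with all
temporal composites equal across CU/non-AD, yet tight CU SDs) is not
jointly reachable with one latent dimension — in the real cohorts that
pattern likely reflects age-related off-target neocortical signal, which is
group-specific and outside this model. Consequently the synthetic RO948
AD-vs-CU AUCs (~0.89) sit below the published 0.98, while group means,
cohort structure, cut-point locations (~1.3–1.4 SUVR for the temporal
meta-ROI) and the ROI ranking are preserved.

## Composite ROIs

Four theory-driven composites: entorhinal; early tau (entorhinal + inferior
temporal + fusiform + parahippocampal); temporal meta-ROI (early tau +
amygdala + middle temporal, approximating Braak I–IV); neocortical meta-ROI
(approximating Braak V/VI). The published composite definitions do not
enumerate the neocortical meta-ROI; the default is every cortical label except the
temporal-meta members and the four cingulate (limbic) labels, and custom
definitions can be supplied. Hemispheres are pooled bilaterally. How
regions combine is also unstated; the default is a volume-weighted mean
(the convention for published meta-ROIs), with an unweighted mean
available; data-driven composites use the unweighted mean, mirroring a
plain average of selected regions.

## Data-driven ROIs

Per tracer and contrast:

1. **Importance.** Extra-Trees classifiers (default 500 trees, sqrt(p)
   features per split, unlimited depth) are fit inside 10-fold stratified
   cross-validation on the regional SUVR matrix; impurity-decrease
   importances are averaged over folds (mean and SD). The ensembles fit each
   tree on all training data without bagging, hence the CV loop rather than
   out-of-bag estimates.
2. **Dendrogram.** Regions are clustered by average linkage under a
   `1 − Pearson r` distance — the standard treatment for strongly collinear
   imaging features.
3. **Representatives.** For k = 1..K the tree is cut into k clusters, each
   contributing its highest-importance member (ties broken by label). The
   unweighted mean SUVR over the selected members is scored by stratified
   cross-validated AUC; the final k is the smallest within one standard
   error of the best score (a one-SE rule, favouring a minimalist ROI).

Subject order never matters: rows are canonicalized (sorted by label and
feature values) before fold assignment, so permuting the input reproduces
identical output for a fixed seed. With hyperparameters and the
accuracy-vs-k rule not specified in the published analysis, these
defaults are exposed
as arguments.

## Diagnostic statistics

* **AUC:** Mann–Whitney estimator (ties ½); invariant under strictly
  increasing transforms. CIs via DeLong placement-value variance, truncated
  to [0, 1].
* **Youden cut-point:** candidate thresholds are midpoints between
  consecutive distinct pooled values plus ±inf sentinels; a subject is
  called positive when its score is strictly greater than the threshold;
  ties in J resolve to the smallest threshold (maximizing sensitivity).
  Cut-points are therefore sample-order independent and land between group
  clusters, as published cut-points (e.g. 1.35) do.
* **Cut-point / sensitivity / specificity CIs:** stratified percentile
  bootstrap (default B = 2000, seeded), re-deriving the Youden threshold per
  replicate. The published tables do not state their CI method; exact binomial
  intervals for sens/spec would also be defensible.
* **DeLong paired test:** structural-components covariance of the placement
  values, two-sided normal p; identical score vectors give p = 1 exactly.
* **Binormal oracles:** closed-form AUC `Phi(dmu / sqrt(s0^2 + s1^2))` and
  the density-crossing Youden cut (quadratic solution; midpoint in the
  equal-variance limit) serve as analytic references in the tests.
* **Tau positivity:** strictly greater than the cut-off (a composite exactly
  at the cut-off is negative).

## Pipeline

For each tracer and contrast the report contains AUC (DeLong 95% CI),
Youden cut-point with bootstrap CIs, and sensitivity/specificity at the cut
for the four theory-driven composites and the contrast-specific data-driven
composite, plus a paired DeLong comparison of the best theory-driven ROI
(highest point AUC) against the data-driven one, and per-ROI cross-tracer
mean cut-points. Cut-points are derived on AD vs amyloid-negative CU for
the CU contrast; for AD vs non-AD the default re-derives them per contrast
(matching the published table layout, where the two contrasts carry
different cut-points), and `cutpoint_scope="ad_vs_abneg_cu"` reuses the
reference cut everywhere. Sensitivity/specificity are reported on the
cut-derivation groups, consistently with their bootstrap. Empty contrast
groups are skipped with a logged warning. Reports serialize to JSON/CSV
deterministically (AUCs print to 3 decimals, cut-points 2, sens/spec 1 in
the human-readable output).

Two subset filters mirror the published sensitivity analyses: excluding PD
without dementia, and excluding amyloid-positive PD/PDD/DLB cases; removed
row counts are logged and recorded in the report metadata.

## Numerical and reproducibility choices

All randomness flows through `numpy.random.default_rng` seeds recorded in
configs and report metadata; identical configuration gives byte-identical
cohort CSVs and report JSON. Per-(tracer, contrast) seeds are derived
arithmetically from the top-level seed. Zero-variance regions, single-class
labels, constant matrices, empty groups, B < 100 and groups smaller than 10
for the bootstrap are rejected with named errors. Problem sizes in the test
suite (e.g. 200 bootstrap-coverage replicates at n = 500/150, 1000 DeLong
null simulations at n = 100+100, 5000-subject calibration checks) were
chosen so the full suite completes in a few minutes on one CPU while
keeping Monte-Carlo error well inside the asserted tolerances.

## What passing tests do and do not show

The generator reproduces the published cohort sizes, subtype and amyloid
composition, group-level composite means, the temporal-vs-neocortical ROI
ranking, and plausible cut-point locations; it does not reproduce
voxel-level images, regional covariance beyond the single latent factor,
tracer-specific off-target topographies (meningeal uptake), within-group
non-normality, or age/sex structure. Statistical guarantees (oracle
equivalences, DeLong calibration, bootstrap coverage) hold on the binormal
and null constructions stated in the tests. Results on synthetic cohorts —
in particular the exact selected regions of the data-driven ROIs, which
depend on the real tau topography only through the latent model — are
methodological checks, not clinical claims.
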