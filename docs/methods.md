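# Methods

This note documents the models implemented in `gsspipe`, the defaults and
why they were chosen, what the synthetic data do and do not emulate, and the
numerical decisions a maintainer would want written down.

## The analysis problem

Subject-specific functional-ROI analysis asks whether an experimental
condition modulates the response of a *functional network* — a set of
regions defined per subject by a localizer contrast — rather than of fixed
anatomical coordinates.  The pipeline reproduces the standard
group-constrained subject-specific (GSS) recipe: group parcels from
overlapping individual activation maps, subject fROIs inside those parcels,
percent-signal-change (PSC) extraction, and network-level mixed-effects
inference.  The motivating contrast is naming pictures in L1 after using L2
versus after using L1, compared between a "language" network and a
domain-general "multiple demand" network; in the phantom this becomes a
condition effect planted in one of two disjoint synthetic networks.

## Synthetic data

**Geometry.**  Truth networks are ellipsoids on the common grid; voxel
membership is decided by the voxel-centre distance, so every mask has an
exactly countable oracle (a radius-3 ball contains 123 voxels).  Subject
topographies jitter the truth mask by an integer shift of up to ±2 voxels
per axis plus an optional morphological dilation/erosion step, redrawing
until at least 50% of the truth volume is covered.  This emulates the
cross-subject spatial variability that motivates subject-specific ROIs; it
does *not* emulate anatomical folding, distance-dependent spatial
correlation of activation, or partial-volume effects.

**Schedules.**  Builders are pure functions of (parameters, seed) and their
totals equal the sum of their parts exactly.  Defaults reproduce the printed
designs: the language/articulation localizer (6+6 blocks of 18 s plus 4
fixation blocks of 12 s → 264 s), the spatial-working-memory localizer
(0.5 s fixation + 4 × 1 s grids + 4 s choice/feedback per trial, 4 trials →
34 s blocks; 5+5 blocks plus 6 × 16 s fixation per run), Stroop,
verbal-fluency, and the rapid event-related picture-naming run (7 s lead-in,
55 × 2 s trials with jittered ISIs, 8 s tail → 295 s to the nearest second).
ISIs are drawn from a truncated exponential on [0.607 s, 10.144 s] and
affinely rescaled so the realized mean hits 3.091 s within 1 ms; the
original experiments optimized their event sequences with dedicated design
software, of which only the printed min/max/mean are honoured here.  Where a
printed run total disagrees with the sum of the printed parts (the
working-memory run prints 438 s but its parts sum to 436 s) the sum of parts
wins, since the block structure is what the simulation consumes.

**BOLD forward model.**  signal = baseline · (1 + Σ amp/100 · r(t)) inside
the subject's responsive mask, where r is the condition's double-gamma-
convolved boxcar scaled so one *isolated* event of that condition peaks at
1.  A planted amplitude of a therefore means "an isolated trial peaks at a
percent of baseline", and the identical scaling on the analysis side makes
simulate → fit → PSC the identity to numerical precision.  Noise is white
Gaussian innovations passed through an AR(1) recursion (lag-1 autocorrelation
equal to the AR coefficient) plus a per-voxel linear drift; defaults
white sd 1.0, AR(1) 0.3, drift half-range 2.0 in signal units on a baseline
of 100.  No physiological noise, motion, or multiband artifacts are
simulated.  Every stochastic operation takes an explicit seed; there is no
global random state.

**The standard phantom study** (the `PhantomStudyConfig` defaults): 24³ grid
of 2 mm voxels, 12 subjects, two disjoint spherical networks (radius 3.2
voxels), localizer amplitude 1%, naming amplitude 1% with a 0.07-PSC
condition effect planted in network A only, between-subject amplitude sd
0.1 (shared across conditions, so the planted contrast is exact), TR 1.4 s.
Study noise uses white sd 0.5 on baseline 100 (temporal SNR 200, in the
range of spatially smoothed fMRI), chosen so the planted 0.07 effect is
properly powered at the scaled-down subject count of the phantom; at TSNR
100 the detection test would hover near the significance boundary.  The
condition is a run-level manipulation, as in the experiment the phantom
mirrors: one naming run per critical condition per subject.

## First-level model

Voxelwise ordinary least squares against an intercept, one convolved
regressor per condition, a discrete-cosine high-pass basis (cutoff 100 s;
`floor(2·T/cutoff)` columns, kept inside the design so the residual degrees
of freedom stay explicit), and optional nuisance columns.  Rank deficiency
is an error that names the collinear columns.  Prewhitening is deliberately
omitted: with the generator's default low AR coefficient the z calibration
test (false-positive rate at z > 3.1 under pure noise ≤ 0.002) documents the
consequences directly, and the null z standard deviation stays within 5% of
1.  t statistics map to z through the t and normal distribution functions at
the model's dof (identity above dof 1000, tails clamped so z stays finite).
PSC scales the beta by the isolated-event regressor peak and divides by the
baseline estimate — the intercept by default, since in a design with an
intercept column the intercept *is* the baseline and the round trip is then
exact; the voxel temporal mean is available as an option.  Runs are combined
within subject by voxelwise inverse-variance weighting; runs with infinite
variance drop out per voxel.

Numerically perfect fits (constant or noiseless data) produce residual
variance at round-off scale; variance below 1e-24 of the signal mean square
is snapped to 0 and those voxels are masked out of z maps rather than
yielding ratio-of-round-off t values.

## GSS parcellation

Stages and defaults: top 5% most active in-mask voxels per subject
(exactly `round(0.05·|mask|)` voxels; ties broken by lexicographic voxel
index so atlases are bit-stable across platforms); overlap count across
subjects; threshold at "more than five" subjects (≥ 6 — the strict count
rule; the ~20% figure sometimes quoted alongside it is treated as
commentary); conversion to probabilities (count/n); Gaussian smoothing at
8 mm FWHM per axis (the 8×8×8 kernel is interpreted as mm FWHM, the
neuroimaging norm for 2 mm voxels; configurable), reflective boundaries,
mass-conserving away from the volume edge; watershed on the negated
smoothed map seeded at its local maxima (26-connectivity for maxima,
6-connectivity for flooding).  Parcels are restricted to voxels that
survived the subject-count threshold: smoothing leaks infinitesimal mass
across the whole volume, and letting parcels follow that support would make
them meaninglessly large.  Parcels whose mean per-subject activated size is
below 10 voxels are removed (10 itself is kept), labels re-compacted in
first-voxel order.

Validation replaces Gaussian-random-field cluster correction — whose
smoothness estimation machinery is out of scope — with an explicit rule: a
subject validates a parcel if it contains a 6-connected cluster of voxels
with z > 2 of at least `validation_min_cluster_vox` voxels.  The default
extent of 3 was set by the included pure-noise Monte Carlo
(`calibrate_cluster_extent`), which gives a ≈5% per-parcel family-wise rate
for parcels around 100–150 voxels, the size this pipeline produces; for
substantially larger parcels the calibration function should be re-run.
The brain mask for the top-fraction stage defaults to the whole volume
(the synthetic grid is "all brain"); a user-supplied mask is accepted.

## fROIs and cross-validation

A subject's fROI in a parcel is the `max(1, floor(0.10·|parcel|))`
highest-z voxels inside it (floor with a 1-voxel minimum: conservative and
never empty), ties again by voxel order.  If a subject has no positive z in
the parcel the top-k voxels are selected anyway and the case is flagged in
the log — the convention of the field, which keeps the design balanced.

Main-task extraction defines fROIs on the pooled (fixed-effects) localizer
z and extracts from the separate naming task, so no cross-validation is
needed there.  For analyses where the selection statistic and the estimate
come from the same task (the localizer-scope contrasts), across-run
cross-validation is mandatory: each fold defines the fROI on the held-in
run(s) and averages the held-out run's PSC; a single-run circular estimate
must be requested explicitly.  The selection bias this removes is
demonstrated, not assumed: under the null, circular top-10% extraction is
positively biased by construction while the CV estimate is centred at zero
(a standing regression test and part of the reproduction script).

## Mixed-effects inference

The network model is `psc ~ condition_code` with crossed random intercepts
and condition slopes for subjects and ROIs, condition deviation-coded
−0.5/+0.5 so the intercept is the grand mean and the slope the condition
difference.  For complete balanced tables the uncorrelated-random-effects
model factorises exactly: per-cell condition means and differences are
independent, each follows a balanced two-way crossed layout, and the REML
likelihood depends on the data only through six ANOVA mean squares.  The
five variance components (subject/ROI intercept and slope variances plus a
shared residual) are estimated by direct REML on those sufficient
statistics (Nelder–Mead on log-variances from moment starts; a component
collapsing to zero is equivalent to dropping that random term and is
recorded in the simplification trace).  Degrees of freedom are the
classical Satterthwaite combination — the same approximation lmerTest
reports — computed from the expected information of the strata; the
implementation is cross-checked against lmerTest in the test suite and
agrees to ~5 significant digits.  Unbalanced tables fall back to
statsmodels `MixedLM` with variance components and the fixed simplification
ladder (drop ROI slope, then subject slope), reporting residual-style
degrees of freedom.  Intercept–slope correlations are not estimated on
either path: the fitter starts from the uncorrelated maximal structure,
which is also the first step of the standard keep-it-maximal reduction.

The condition × network model adds a deviation-coded network factor and its
interaction as fixed effects, with ROIs nested in networks; on the balanced
path the network fixed effect is absorbed into per-network ROI means and
the interaction variance involves only the ROI-slope and residual
components (the shared subject slope cancels from the network difference).
With one ROI per network some variance components are structurally
unidentifiable; they are fixed at zero and flagged in the trace, and the
test then collapses to the correct subject-level paired comparison.

Per-ROI analyses are paired t tests on per-subject condition differences
(exactly what the within-ROI mixed model reduces to with one value per
subject and condition), with Benjamini–Hochberg FDR within each network.
Tests are two-sided at α = 0.05 throughout.

**Effect size.**  The headline effect size is d = 2t/√df, labelled
`d_from_t` in all output; Cohen's d_z on subject-level difference scores is
available via configuration.  The d = 2t/√df convention was adopted because
it is the definition consistent with the effect sizes customarily reported
alongside this model family; since the literature rarely states the formula,
the metric's name is always printed next to its value.

**Calibration.**  The reproduction script and acceptance tests run the
model on 500 simulated 40-subject × 20-ROI tables per setting: type-I error
at nominal 0.05 falls in [0.03, 0.07], the estimate of a true 0.07 effect
is biased by less than 5%, and 95% CI coverage lands in [92%, 98%].  In
balanced data the fixed effect equals the raw condition-mean difference
identically, regardless of the variance components — a property asserted
exactly in the tests.

## Pipeline and problem sizes

The staged pipeline (simulate → glm → parcellate → extract → analyze, plus
report) serialises everything as NIfTI-1, TSV and JSON and records a
manifest of content hashes; a stage whose config and inputs are unchanged
is a no-op, and a missing upstream artifact produces an error naming the
stage to re-run.  Volumes are written uncompressed so manifests are
byte-stable across runs.

Simulation studies use deliberately compact problem sizes — the 24³ grid
with 12 subjects for the end-to-end study, ~100-volume runs for the
Monte-Carlo experiments, 500 replicates for model calibration — chosen so a
full validation cycle completes in about a minute on a laptop while keeping
every statistical check at meaningful power.

## Known limitations

- No prewhitening: z calibration degrades as the AR(1) coefficient grows;
  the generator's default is low and the calibration test pins the
  consequence.
- The balanced-REML path assumes uncorrelated random effects; genuinely
  correlated intercepts and slopes would be partially absorbed into the
  component variances.
- Parcel validation is a calibrated cluster-extent rule, not random-field
  theory; its default extent is tied to the parcel sizes of the synthetic
  study.
- Phantom noise is spatially independent; spatially correlated noise would
  lower the effective number of independent voxels inside an fROI and widen
  PSC uncertainty relative to the phantom's.
- The synthetic "registration" is perfect: all subjects share the grid, so
  normalisation error — a real contributor to cross-subject variability —
  is represented only through the topography jitter.
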