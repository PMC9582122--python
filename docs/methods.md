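# Methods

## Study design emulated by the generator

The experiment is a two-block design: 35 cartoon images (7 stories × 5
images) are shown once in scrambled cross-story order (`Scr`) and then once
in each story's chronological order (`Seq`). Each image is on screen for
2 s; a 6 s gray screen separates series. Analysis is transition-based: an
epoch spans [−100, +500) ms around an image onset (600 samples at 1 kHz),
and transitions are classed as `first_of_experiment` (block-initial),
`isi_to_image` (series-initial after a gray screen), `image_to_image`
(within-series) or `image_to_isi` (gray-screen onset, used as an ISI
control). The default trial universe is the 28 `image_to_image` transitions
per condition (56 total) — the only reading consistent with the 44-trial
train/validate pool, 27 left-out trials per fold and 12-trial test set that
the analysis uses. The series-initial classes are kept as a separate,
optional class so the first-versus-rest habituation analysis (7 "First"
trials per condition when both initial classes are included) remains
expressible.

## Synthetic LFP model

Each site's signal is

    s(t) = A_bg · pink(t) + A_bb · g(t) · bb(t) + coupling terms

* `pink(t)` — 1/f^α background (α = 1 by default), unit variance, drawn
  directly in the frequency domain (one inverse FFT per subject block).
* `bb(t)` — band-limited (10–100 Hz) Gaussian noise, unit variance. The
  10–100 Hz band realizes the broadband (not narrowband) character of the
  condition effect: the dominant principal component of the resulting
  spectra is a >10 Hz broadband power shift.
* `g(t)` — piecewise-constant gain: 1 everywhere except the 100–500 ms
  post-onset response window of each image, where it takes the region ×
  condition × {first, rest} gain. Habituation is two-level (first vs rest),
  matching the analysis' own grouping rather than a continuous decay.
* Amplitudes default to A_bg = 1, A_bb = 0.5. No signal-to-noise figures
  exist for the real recordings, so these were chosen once to make the
  default effects comfortably detectable at desk scale (tens of sites, one
  recording's worth of trials) while leaving null configurations exactly
  null.

Default effect gains: frontal rest Scr 1.5 vs Seq 1.0, temporal rest Seq 1.5
vs Scr 1.0, first transitions 1.25 in both conditions and both regions
(equal by construction), all other regions 1.0. A gain of 1 everywhere
(`EffectSpec.null()`) makes the two conditions statistically
indistinguishable by construction.

Directed coupling is injected feed-forward: a region-level edge (source,
sink, condition, lag, coefficient) is realized per subject by adding
`coef · s_source(t − lag)` to each sink-region site (one randomly chosen
source site per sink, recorded in the ground truth), only inside the
response windows of the edge's condition. Edges are applied in topological
order of the per-condition region graph so chains propagate; cyclic graphs
and |coefficient| ≥ 1 are rejected. This makes Granger-causal ground truth
well defined: the sink is literally a lagged linear function of the source
plus noise during stimulus windows, and carries no such dependence during
the gray-screen intervals.

All randomness flows from one integer seed through named
`numpy.random.SeedSequence` children (tagged by stage and subject/site id),
so per-subject samples are bit-reproducible and independent of processing
order.

### What the generator does not emulate

Saccades and eye movements, epileptiform artifacts, photodiode
synchronization jitter, the clinical 2 kHz→1 kHz resampling path, volume
conduction, spatially correlated background between neighboring contacts,
and any narrowband oscillatory structure. Passing tests therefore
demonstrate correctness and calibration of the *analysis*, not fidelity of
real tissue; the headline numbers of the original recordings (e.g. PC1
variance share, site counts, decoding ceilings) are reference points, not
targets.

## Numerical and design choices

* **Welch parameters.** A 600-sample window divided into "eight segments
  with 50 % overlap" forces segment length ⌊600/4.5⌋ = 133; segments are
  zero-padded to 1000 points so the spectrum lands exactly on a 1 Hz grid
  (the native resolution is ≈ 7.5 Hz; adjacent 1 Hz bins are interpolated,
  not independent). Scipy realizes 7 full segments from 600 samples at
  these parameters; the segment length, taper and overlap — the quantities
  that determine the estimate — match the nominal eight-segment division.
  Epochs are z-scored first, so the PSD is amplitude-invariant; the
  per-epoch mean removal slightly depresses bins below ≈ 8 Hz, which the
  ratio normalization then cancels across conditions.
* **Normalization.** Each trial PSD is divided by the mean PSD over all of
  the site's trials, both conditions pooled (the most direct reading of
  normalizing "across all experimental conditions"); per bin the normalized
  values then average to 1, and the operation is idempotent.
* **PCA.** Centered, full deterministic SVD, fitted on the normalized
  linear-scale condition-averaged PSDs (the log transform in the source
  material is a display convention). PC1's sign is fixed so its mean
  loading above 10 Hz is positive. Subject-held-out projection fits on the
  other subjects' condition-averaged rows and centers the held-out trials
  with the fitted mean.
* **Encoding design matrix.** Two exhaustive condition indicators plus an
  intercept are rank-deficient; minimum-norm least squares is used, and the
  exported per-condition "predicted weight" (indicator weight + intercept)
  equals the condition's training mean — invariant to the parameterization,
  which is all the accuracy and decoding computations consume. Fold draws
  are without replacement, independent across folds, resampled until both
  conditions appear. The permutation p-value uses the add-one estimator
  p = (1 + #{null ≥ observed}) / (n_perm + 1); the fold index draws are
  shared between observed and null so the comparison is exchangeable. No
  fixed accuracy threshold is hard-coded: the permutation quantile defines
  significance per dataset. α = 0.05 throughout.
* **Decoding.** Trials are stimulus-indexed and pooled across subjects
  (every subject saw identical sequences), so a cross-subject pattern
  vector per trial is well defined. The 80/20 train/test split is made once
  per run, seeded and stratified by condition (56 → 44/12 with floor
  rounding). Leave-one-trial-out refits use the full 56-trial pool minus
  the tested trial. Exact correlation ties and zero-variance patterns are
  scored unsuccessful (conservative).
* **Granger causality.** Bivariate AR model comparison per direction:
  restricted = own lags, full = own + other's lags, intercept included,
  lagged samples pooled across trials without crossing trial boundaries;
  gc = ln(RSS_r / RSS_f), p from the nested-model F statistic. The AR
  order is selected by AIC on the pooled bivariate model (cap 20,
  overridable). The order matters: 1/f backgrounds need a deep own-history
  model (order ≳ 15 at 1 kHz) to be whitened, otherwise residual
  autocorrelation inflates the false-positive rate of the F test. Only
  within-subject pairs are computed — causality across subjects is
  physically meaningless. Note that for two independent series the couplet
  rule (direction of the larger gc, requiring its p < α) has a false-couplet
  rate of ≈ 1 − (1 − α)² ≈ 9.8 % at α = 0.05, since the larger-gc direction
  always carries the smaller p.
* **Contingency contrast.** The two 6×6 condition tables are stacked into a
  2 × cells layout; cells empty in both conditions are dropped (zero
  expectation) and reported. Omnibus Pearson χ² without continuity
  correction; per-cell standardized adjusted residuals give two-sided
  normal p-values, Bonferroni-multiplied by the number of tested cells
  (the correction method is not specified in the source material;
  Bonferroni is the conservative choice). Lateralization uses the exact
  hypergeometric (Fisher) test on condition × {lateralized pair, other}
  couplet counts.

## Problem sizes

The full-census configuration (13 subjects, 970 analyzed + 300 excluded
sites) runs the schedule→spectra→condition-average path in under a minute
on one CPU and is exercised by the structural test. Pairwise GC is
quadratic in sites per subject, so the orchestrated pipeline subsamples to
`gc_max_sites_per_subject` (default 12) sites per subject for the
connectivity stage; calibration and recovery tests run at 8–50 sites per
subject, 1000–2000 permutations, and 10–100 generator seeds, which keeps
the whole suite within a few minutes while leaving the Monte-Carlo bounds
statistically meaningful (bound checks are phrased as binomial tests at the
1 % level rather than point comparisons).

## Known limitations

* The generator's effects enter through a single broadband component, so
  PC1 recovery is by construction; the pipeline's behavior under competing
  narrowband oscillations is untested.
* The common average reference couples channels (each carries −1/N of every
  other), which measurably inflates background couplet counts when few
  sites per subject are referenced together; the contingency contrast is
  robust to this because the inflation is condition-symmetric.
* The AR-order conventions of the original connectivity toolbox are not
  recoverable; the AIC default is documented standard practice, not an
  equivalence claim.
* Fisher lateralization tests are exposed but not part of the default
  orchestrated report, since the small default configurations rarely
  populate both hemispheres of a region pair.
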