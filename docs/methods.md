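# Methods

This note documents the models, parameter choices and numerical
conventions behind `swalink`, and what the synthetic-data tests do and do
not establish about real recordings.

## IAT D-scoring (`swalink.iat`)

The task has seven blocks and 190 trials: two 20-trial single-category
learning blocks, two "congruent" test blocks (3–4, 60 trials), a 30-trial
reversed-assignment practice block, and two "incongruent" test blocks
(6–7, 60 trials).  The score is

    D = (mean RT incongruent − mean RT congruent) / SD_inclusive,

where the condition means use **correct trials only** from blocks 3–4 and
6–7 and the inclusive SD is the n−1 standard deviation of all included
correct trials pooled across both conditions.  |D| is the headline
behavioral measure, capturing bias strength irrespective of direction.

Choices where the scoring literature offers variants:

- **Error penalty.** The default excludes error trials from the means
  entirely; `error_penalty_ms` enables the conventional-algorithm variant
  (errors enter at block mean of correct trials + penalty, SD still from
  correct trials).
- **Practice/test split.** The default is one pooled D over blocks 3–4 vs
  6–7; `practice_test_split=True` computes D on (3 vs 6) and (4 vs 7)
  separately and averages.
- **Exclusions.** RTs above 10 s are dropped; a subject with more than
  10% of test RTs under 300 ms is flagged (not rejected).  Both
  thresholds are options.
- **Range.** |D| values beyond 2 warn but are never clamped: the ±2 range
  is an empirical property of the statistic, not part of its formula.
- Bias-strength labels use the conventional cutpoints 0.20 / 0.49 / 0.74.

## Sleep EEG processing (`swalink.sleep`)

- **Filtering**: zero-phase FIR (Hamming design, via mne), pass band
  0.5–40 Hz with 0.25 Hz transition width at the low edge and 2 Hz at the
  high edge.
- **Bad channels**: spherical-spline interpolation (order-4 splines, via
  mne's montage machinery on the package's spherical electrode layout); a
  nearest-neighbors-on-sphere inverse-distance variant is available.
  Average reference is applied last, so the per-sample channel mean is
  numerically zero.
- **Artifact masking**: an epoch is rejected when its channel-mean power
  in **either** the 0.8–4.6 Hz or the 20–40 Hz band exceeds a factor
  (defaults 2.0 and 2.5) times the centered moving average over 15
  neighboring epochs of the same stage group.  The moving average pools
  channels (channel-mean power), groups N1/N2/N3 together as NREM, is
  edge-truncated and includes the epoch itself; the two bands are
  combined with OR.  These conventions are configurable because the
  semi-automatic procedure they implement leaves them to the operator.
  Lowering a factor can only grow the rejected set (tested).
- **Spectra**: Welch with 5-s Hanning segments at 50% overlap (0.2 Hz
  resolution) on each artifact-free 30-s N2/N3 epoch, averaged over
  epochs per channel; SWA band power integrates the PSD over [0.8, 4.6]
  Hz with inclusive bin edges.  A pure in-band sinusoid of amplitude A
  recovers A²/2 within 2%.
- **Architecture**: TST = 0.5 min per sleep-stage epoch inside the
  lights-off window; efficiency = TST / time in bed; WASO = wake between
  sleep onset and the final awakening.  Sleep onset is the first epoch of
  *any* sleep stage (N1 counts) — no stricter onset rule is imposed.
- **Cycles**: an NREM period of ≥ 15 min followed by a REM period of
  ≥ 5 min closes a cycle at the REM period's end; the first REM period is
  exempt from the minimum, and trailing NREM ≥ 15 min without REM closes
  the last cycle at the final sleep epoch.  The minima follow the
  classical rule and are parameters (scaled-down synthetic nights use
  proportionally scaled minima).

## Head model and standardized inverse (`swalink.headmodel`, `swalink.inverse`)

The forward model is a homogeneous conducting sphere (default radius
40 mm, conductivity 0.33 S/m) with a 59-electrode Fibonacci cap and a
centered 6×6×6 voxel lattice at 5 mm spacing — mirror-symmetric about
x = 0 so laterality mirroring maps voxels onto voxels exactly.  Surface
potentials use the closed form obtained by summing the Legendre expansion
(verified in the tests against an independent truncated-series oracle to
~1e−15 relative error, including the central-dipole limit
V = 3·q·ê/(4πσR²)).  The gain matrix is average-reference projected, so
every column sums to zero over electrodes.

The inverse is `T = Kᵀ(KKᵀ + αH)⁺` with `H = I − 11ᵀ/n` and
`α = trace(KKᵀ)/(n_e·snr²)` (default snr = 10).  The proprietary
"manual regularization" of the original source-localization software is
not published, so this standard SNR→Tikhonov mapping is adopted and
exposed as a parameter.  Voxel estimates are standardized by the 3×3
diagonal blocks of the resolution matrix `TK` (pseudo-inverted for
robustness), which yields **zero localization error** for noiseless
single dipoles — verified for ≥ 20 random positions and orientations.

Band power is localized in the frequency domain: the scalp cross-spectral
matrix C is accumulated over Hann segments and band bins of the
artifact-free N2/N3 epochs, and the voxel value is
`trace(S_v⁻¹ · T_v C T_vᵀ)` — the power summary of the standardized
block.  (A current-density *amplitude* reading is the square root; after
per-subject normalization the two are monotone-equivalent.)  Maps are
normalized to a total current density of one and log₁₀-transformed with a
1e−12 floor applied before the log; per-cycle analyses normalize each
cycle's map separately.  For linear operators the frequency-domain
pathway is equivalent to filtering then projecting, and far cheaper.

## Statistics (`swalink.stats`)

- **Voxel-wise partial correlation**: Pearson correlation of the
  residuals of maps and behavior after least-squares projection on
  [1, covariates]; df = n − 2 − k; two-sided p from
  t = r·√(df/(1−r²)).  The vectorized implementation equals a per-voxel
  loop to 1e−12 (tested); constant voxels are excluded and reported.
- **FWER correction**: max-statistic permutations.  With covariates the
  scheme is Freedman–Lane (permute the behavior residuals from the
  covariate-only model, re-residualize, recompute voxel-wise |r|); simple
  label permutation is available.  The critical value is the
  ⌈(1−α)(n_perm+1)⌉-th order statistic of the null maxima pooled with the
  observed maximum — the (k+1)/(n_perm+1) convention that keeps the test
  level-valid at finite n_perm.  On n = 5 the sampled machinery fed all
  120 permutations reproduces exhaustive enumeration exactly (tested);
  under a global null the empirical family-wise error over 200 cohorts
  stays within two binomial standard errors of α (tested, and recomputed
  by `scripts/acceptance.py`).
- **Clusters**: 26-connectivity connected components (6 as an option);
  size = member count × spacing³; peak = member of maximal |r|, ties
  broken by lowest voxel index for reproducibility.
- **ROIs and laterality**: 15-mm spheres (123 lattice voxels on an
  unrestricted 5-mm grid) around the peak; the homologous region reverses
  the x coordinates; mirroring is an involution on the symmetric grid.
  The left/right ROI mean log densities are compared with Meng's
  dependent-correlation Z-test, with r12 the correlation between the two
  ROI means across subjects.  The one-sided upper-tail p is reported as
  the headline (the printed Z/p pairing in this literature is only
  consistent with a one-sided tail); the two-sided p is also emitted.
- **Per-cycle analyses** cover cycles 1–4 (subjects lacking a cycle are
  excluded listwise for that cycle), controlling each cycle's duration;
  a pooled cycles-2–4 analysis sums the raw maps and controls the summed
  duration.

## Synthetic cohort (`swalink.simulate`)

The generator's defaults are the study conditions: 52 subjects, 59
analysis electrodes, 500 Hz, full-length nights.

- **Behavior.** A signed latent bias trait is N(0.58, s) with s chosen so
  that scored |D| (trait + ~0.19 trial-sampling noise from ~115 test
  trials) has SD ≈ 0.27.  Trial RTs are lognormal (within-subject log-SD
  0.38; subject medians lognormal around 627 ms, log-SD 0.148, giving
  congruent means ≈ 674 ms with ≈ 101 ms between-subject SD);
  incongruent-mapping blocks are scaled by a factor solved in closed form
  so the population D equals the trait, monotone in the trait for a fixed
  seed.  Error rates are fixed per condition (≈ 3.2% congruent, ≈ 7.5%
  incongruent, matching ≈ 97%/92% accuracies) and deliberately
  trait-independent so the trait→D coupling is exactly monotone.
  Measured over 20 seeded cohorts, mean |D| ≈ 0.58 and mean congruent /
  incongruent RTs ≈ 684/878 ms.
- **Nights.** Hypnograms follow a deterministic 5-cycle grammar
  (W → N1 → N2 → N3 → N2 → [W] → REM) with per-segment lognormal jitter
  (10%) plus a global night-length factor sized to the target
  between-subject TST spread (SD ≈ 29 min); the template reproduces
  TST ≈ 435.5 min, efficiency ≈ 93%, WASO ≈ 22 min and stage percentages
  N1/N2/N3/REM ≈ 7.8/46.4/24.5/21.3% of TST, and always contains ≥ 4
  detectable cycles.  EEG epochs carry 0.8–4.6 Hz random-phase band-limited
  source activity (equivalently, an equal-amplitude sum of in-band
  sinusoids) scaled by stage (N3 1.0, N2 0.45, N1 0.15, REM 0.08, W 0.05)
  and by an exponential overnight decline (τ = 300 min on amplitude),
  projected through the lead field with white channel noise (8 µV);
  ~2% of epochs receive an 8× broadband artifact burst.
- **Planted effect.** The standardized effect-voxel latent is
  `e = r_true·s + √(1−r_true²)·u`, with s the standardized absolute
  trait, so the source-amplitude/behavior correlation converges to
  `r_true`.  The effect voxel's dipole amplitude is
  `base × 3 × (1 + 0.35·e)`: the study never reports per-subject regional
  SWA effect sizes, so these two gains are free parameters chosen once to
  make ROI correlations near −0.45 reachable at n = 52.  Dipole
  orientations are random unit vectors **shared across the cohort**
  (drawn from the cohort seed): per-subject orientations would modulate
  the projected effect power with anatomy-free noise and confound the
  planted correlation.
- **Fast path.** `simulate_current_density_cohort` emulates normalized
  source maps directly: a squared-exponential Gaussian field (length
  scale 7.5 mm) whose effect-voxel value is replaced by `e`, then
  `exp(0.3·F)` row-normalized to unit sum.  On the log scale the planted
  correlation is preserved to first order, and the effect is concentrated
  at a single voxel (no spatial spread), so whole-map peak location is an
  exact recovery criterion.

**What the synthetic tests do not show.**  The generator has no realistic
head anatomy (homogeneous sphere, 216-voxel lattice vs ~6000 cortical
voxels), no spindles/K-complexes or 1/f background, no ocular or cardiac
artifacts, no staging ambiguity (hypnograms are consumed as ground
truth), and its planted effect is a point source.  Passing tests
establish the correctness and calibration of the algorithms — scoring
formulas, spectral estimates, inverse standardization, permutation
validity, cycle rules — not that the pipeline would reproduce any
particular empirical brain–behavior correlation on real recordings.

## Problem sizes

Full-scale nights (500 Hz × ~7.8 h × 59 channels ≈ 3.3 GB per subject as
float32) are supported but the EEG-level validation suites run
deliberately small configurations chosen as desk-scale study stand-ins:
24–32 electrodes, 4³ voxel lattices, 100–128 Hz, nights scaled to ~4–5%
length with proportionally scaled cycle minima.  The raw-EEG
planted-effect recovery suite uses 24 subjects × 10 seeds at r_true = 0.8
and requires the effect voxel's 26-neighborhood to reach whole-brain
significance in ≥ 80% of seeds; the map-level recovery suite runs at the
full cohort size (n = 52, r_true = −0.6, 50 seeds, ≥ 80%).  The FWER check
uses 200 cohorts × 500 permutations × 200 voxels.  Statistical cohort
analyses always run at the full n = 52.

## Known limitations

- The EDF writer emits plain 16-bit EDF with 1-s records and integer
  sampling rates only; round trips are exact to one quantization step.
- The spherical head model cannot represent orientation selectivity of
  real cortex; localization claims are exact only in the noiseless
  single-source limit.
- `simulate_sleep_night` materializes the night in memory; full-scale
  cohorts need several GB per subject and are best generated per subject.
- Meng's test assumes bivariate normality of the underlying scores; with
  |D| (a folded quantity) it is, as in the literature it follows, an
  approximation.
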