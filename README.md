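# swalink

**Linking the intracortical distribution of sleep slow-wave activity to
implicit-bias scores.**

Regional slow-wave activity (SWA, EEG power at 0.8–4.6 Hz during NREM
sleep) is a stable, trait-like "fingerprint" of the sleeping brain.
`swalink` implements, as a tested and reusable pipeline, an analysis that
asks whether that fingerprint explains individual differences in implicit
social bias: score a race Implicit Association Test (IAT), extract
stage-gated SWA spectra from whole-night high-density EEG, project them
into source space with a standardized minimum-norm (sLORETA-style)
inverse, and correlate the relative, log-transformed current-density maps
with the absolute IAT D-score voxel by voxel, controlling for total sleep
time and correcting family-wise error with max-statistic permutations.

It is written for sleep/EEG researchers and biostatisticians who want
either the full pipeline or its pieces:

- **`swalink.iat`** — D-scoring: `D = (RT̄_incongruent − RT̄_congruent) / SD_inclusive`
  over the correct test-block trials, with the conventional exclusion
  rules, bias-strength categories and cohort summaries.
- **`swalink.sleep`** — zero-phase 0.5–40 Hz filtering, spherical-spline
  bad-channel interpolation, average referencing, 30-s epoching with
  semi-automatic artifact masking (moving-average thresholds in the
  0.8–4.6 and 20–40 Hz bands), Hanning/Welch SWA spectra, sleep
  architecture (TST, efficiency, WASO, stage percentages) and
  Feinberg–Floyd-style NREM–REM cycle segmentation.
- **`swalink.headmodel` / `swalink.inverse`** — an analytic homogeneous
  spherical head model (closed-form dipole potentials) with a 5-mm
  mirror-symmetric voxel lattice, and the standardized inverse
  `T = Kᵀ(KKᵀ + αH)⁺` with `α = trace(KKᵀ)/(n_e·snr²)`, voxel estimates
  standardized by the resolution-matrix blocks (zero localization error
  for noiseless single dipoles). Maps are normalized to a total current
  density of one and log₁₀-transformed.
- **`swalink.stats`** — voxel-wise partial Pearson correlations,
  Freedman–Lane max-|r| permutation FWER correction, 26-connected
  clusters, 15-mm spherical ROIs with laterality mirroring
  (x → −x), Meng's test for dependent correlations, and per-sleep-cycle
  repeats.
- **`swalink.simulate`** — a seeded synthetic study generator (cohort
  latent traits, 190-trial IAT tables, whole-night EEG + hypnograms, and a
  fast path that emulates normalized source maps directly) with a planted,
  tunable brain–behavior correlation, calibrated to the cohort targets
  (mean |D| ≈ 0.58, TST ≈ 435.5 min, sleep efficiency ≈ 93%).

## Worked example

```python
import numpy as np
from swalink import (CohortConfig, simulate_current_density_cohort,
                     permutation_fwer_threshold, partial_correlation,
                     extract_clusters)

cfg = CohortConfig(n_subjects=52, seed=7, r_true=-0.6)   # planted effect
cd = simulate_current_density_cohort(cfg)                # maps sum to 1
logm = np.log10(np.maximum(cd.maps, 1e-12))
res = permutation_fwer_threshold(logm, cd.behavior, cd.tst,
                                 n_perm=5000, alpha=0.05, seed=7)
clusters = extract_clusters(res.significant, cd.grid, r=res.observed.r)
peak = clusters.clusters[0].peak_index
r, p, df = partial_correlation(logm[:, peak], cd.behavior, covariates=cd.tst)
print(f"critical |r| = {res.critical_value:.3f}, "
      f"{res.significant.sum()} significant voxels")
print(f"peak voxel at {cd.grid[peak]} mm; peak r = {r:+.3f} (p = {p:.4f})")
```

prints

```
critical |r| = 0.479, 1 significant voxels
peak voxel at [-12.5  -7.5   7.5] mm; peak r = -0.599 (p = 0.0000)
```

i.e. with a planted correlation of −0.6 at one left-hemisphere voxel, the
whole-brain-corrected threshold for 52 subjects on this 216-voxel grid is
|r| ≈ 0.48, the planted voxel survives it, and its partial correlation
with the behavioral trait (controlling total sleep time) is −0.60.  (On
this fast path the effect is planted at a single voxel, so the
whole-brain peak — not a 15-mm ROI mean, which would dilute a point
effect — is the right readout; the raw-EEG route spreads the effect over
a neighborhood and is analyzed with `build_roi_sphere` ROIs, as in
`swalink run-all` below.)

The same analysis can be run from the shell on raw files:

```bash
swalink simulate --out study/ --n-subjects 52 --seed 7
swalink run-all study/manifest.json --out results/ --n-perm 5000 --seed 7
```

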