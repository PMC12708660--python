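"""Synthetic study generator: cohort latent traits, IAT trial tables,
whole-night EEG with hypnograms, and fast-path source-space SWA maps.

The generator emulates a cohort of young good sleepers (default n = 52)
whose nights follow the study's sleep-architecture averages (total sleep
time ~435.5 min, efficiency ~93%, stage mix N1/N2/N3/REM of
7.8/46.4/24.5/21.3% of TST) and whose IAT behavior reproduces the printed
moments (congruent RT ~674 ms, incongruent ~845 ms, absolute D-scores with
mean ~0.58 and SD ~0.27, accuracies ~97%/92%).  A correlation of ``r_true``
is planted between the SWA source amplitude at one voxel and the
behavioral trait, so the whole downstream pipeline (spectra →
localization → permutation statistics) can be validated end to end without
any real recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError
from .headmodel import LeadField, generate_lead_field, voxel_lattice
from .sleep import Hypnogram, SleepRecording

# ---------------------------------------------------------------------------
# IAT reaction-time model (lognormal; constants calibrated to the printed
# behavioral moments)

#: population median of the congruent-condition RT, ms
RT_MEDIAN_MS = 627.0
#: between-subject log-sd of the subject median
RT_BETWEEN_LOG_SD = 0.148
#: within-subject trial-level log-sd
RT_WITHIN_LOG_SD = 0.38
#: per-trial error probabilities (errors per 60 test trials: ~1.89 / ~4.52)
P_ERROR_CONGRUENT = 0.0315
P_ERROR_INCONGRUENT = 0.0753
P_ERROR_PRACTICE = 0.05
#: approximate sampling SD of a scored D from ~115 test trials; used to
#: split the target |D| spread into latent trait vs measurement noise
D_MEASUREMENT_SD = 0.19

#: (block, n_trials, condition) for the 7-block, 190-trial task
BLOCK_PLAN = (
    (1, 20, "learn-words"),
    (2, 20, "learn-faces"),
    (3, 30, "congruent"),
    (4, 30, "congruent"),
    (5, 30, "practice-reversed"),
    (6, 30, "incongruent"),
    (7, 30, "incongruent"),
)

#: SWA amplitude factors by stage (N3 > N2 >> REM/W)
STAGE_SWA_FACTOR = {"N3": 1.0, "N2": 0.45, "N1": 0.15, "REM": 0.08, "W": 0.05}

# night template: per-cycle minutes for N1, N2, N3, mid-cycle wake and REM.
# Sums to TST 436 min with WASO 22 and a 10-min onset latency, matching the
# target architecture; the N2 block is split 60/40 around the N3 period.
_NIGHT_N1 = (8.0, 7.0, 7.0, 6.0, 6.0)
_NIGHT_N2 = (34.0, 40.0, 44.0, 46.0, 38.0)
_NIGHT_N3 = (40.0, 30.0, 20.0, 11.0, 6.0)
_NIGHT_WAKE = (0.0, 5.0, 6.0, 6.0, 5.0)
_NIGHT_REM = (9.0, 17.0, 24.0, 24.0, 19.0)
_NIGHT_LATENCY = 10.0
_NIGHT_FINAL_WAKE = 2.0
_TEMPLATE_TST = float(sum(_NIGHT_N1) + sum(_NIGHT_N2) + sum(_NIGHT_N3) + sum(_NIGHT_REM))
#: per-segment lognormal duration jitter
_SEGMENT_JITTER_SD = 0.10


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort.

    ``r_true`` is the planted correlation between the effect-voxel source
    amplitude and the behavioral trait (absolute D); ``behavior_mean/sd``
    and ``tst_mean_min/sd_min`` are the cohort targets the generator is
    calibrated to.  ``night_scale`` shrinks every hypnogram segment for
    desk-scale runs (1.0 = full night).
    """

    n_subjects: int = 52
    seed: int = 0
    r_true: float = -0.6
    effect_voxel: int | None = None
    behavior_mean: float = 0.58
    behavior_sd: float = 0.27
    tst_mean_min: float = 435.5
    tst_sd_min: float = 29.0
    rate: float = 500.0
    n_electrodes: int = 59
    n_voxels_per_axis: int = 6
    spacing_mm: float = 5.0
    head_radius_mm: float = 40.0
    channel_noise_uv: float = 8.0
    spatial_smoothness_mm: float = 7.5
    map_log_scale: float = 0.30
    effect_cv: float = 0.35
    effect_source_gain: float = 3.0
    swa_source_namp: float = 20.0
    swa_decline_tau_min: float = 300.0
    artifact_rate: float = 0.02
    night_scale: float = 1.0

    def __post_init__(self):
        if self.n_subjects < 4:
            raise ConfigurationError("n_subjects must be >= 4")
        if abs(self.r_true) > 1.0:
            raise ConfigurationError("|r_true| must be <= 1")
        for name in ("behavior_sd", "tst_sd_min", "channel_noise_uv",
                     "spatial_smoothness_mm", "night_scale", "rate"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


def default_effect_voxel(grid: np.ndarray) -> int:
    """Lattice voxel nearest a left temporoparietal-like position (negative
    x, posterior, superior octant of the solution cube)."""
    target = np.array([-12.5, -7.5, 7.5])
    return int(np.argmin(np.linalg.norm(grid - target, axis=1)))


def _folded_normal_moments(mu: float, sd: float) -> tuple[float, float]:
    """Mean and SD of |X| for X ~ N(mu, sd)."""
    z = mu / sd
    mean = sd * np.sqrt(2.0 / np.pi) * np.exp(-0.5 * z**2) + mu * (1.0 - 2.0 * sps.norm.cdf(-z))
    var = mu**2 + sd**2 - mean**2
    return float(mean), float(np.sqrt(max(var, 1e-12)))


@dataclass
class CohortBundle:
    """Per-subject latent quantities generated before any raw data."""

    config: CohortConfig
    traits: np.ndarray        # signed latent D-scale bias trait
    behavior: np.ndarray      # |trait|: behavioral target (absolute D scale)
    effect_field: np.ndarray  # standardized latent field value at the effect voxel
    effect_amp: np.ndarray    # multiplicative SWA amplitude factor at the effect voxel
    tst: np.ndarray           # drawn total-sleep-time covariate, min
    iat_seeds: np.ndarray
    night_seeds: np.ndarray
    map_seed: int

    @property
    def n_subjects(self) -> int:
        return self.traits.size


def simulate_cohort(config: CohortConfig) -> CohortBundle:
    """Draw cohort latent traits, behavioral targets and planted effects.

    The signed trait is N(behavior_mean, s) with s chosen so that scored
    absolute D-scores (trait plus ~0.19 measurement noise) hit the target
    SD; the standardized effect-voxel field is ``r_true``-correlated with
    the standardized absolute trait.  Seeded and reproducible.
    """
    rng = np.random.default_rng(config.seed)
    latent_sd = float(np.sqrt(max(config.behavior_sd**2 - D_MEASUREMENT_SD**2, 1e-4)))
    traits = rng.normal(config.behavior_mean, latent_sd, config.n_subjects)
    behavior = np.abs(traits)
    mu_f, sd_f = _folded_normal_moments(config.behavior_mean, latent_sd)
    s = (behavior - mu_f) / sd_f
    u = rng.standard_normal(config.n_subjects)
    e = config.r_true * s + np.sqrt(1.0 - config.r_true**2) * u
    amp = np.maximum(1.0 + config.effect_cv * e, 0.05)
    tst = rng.normal(config.tst_mean_min, config.tst_sd_min, config.n_subjects)
    iat_seeds = rng.integers(0, 2**31 - 1, config.n_subjects)
    night_seeds = rng.integers(0, 2**31 - 1, config.n_subjects)
    map_seed = int(rng.integers(0, 2**31 - 1))
    return CohortBundle(
        config=config, traits=traits, behavior=behavior, effect_field=e,
        effect_amp=amp, tst=tst, iat_seeds=iat_seeds, night_seeds=night_seeds,
        map_seed=map_seed,
    )


# ---------------------------------------------------------------------------
# IAT trials


def _rt_shift_factor(trait: float, mean_rt: float, sd_rt: float) -> float:
    """Multiplicative incongruent-RT factor λ that yields a population
    D-score of ``trait``.

    Solving D = m(λ−1) / sqrt(σ²(1+λ²)/2 + m²(λ−1)²/4) for λ (equal-size
    conditions, population moments) gives a quadratic in u = λ−1.
    """
    t = float(np.clip(trait, -1.95, 1.95))
    if t == 0.0:
        return 1.0
    m, sg = mean_rt, sd_rt
    a = m**2 * (1.0 - t**2 / 4.0) - t**2 * sg**2 / 2.0
    b = -(t**2) * sg**2
    c = -(t**2) * sg**2
    disc = np.sqrt(b**2 - 4.0 * a * c)
    u = (-b + np.sign(t) * disc) / (2.0 * a)
    return float(max(1.0 + u, 0.05))


def simulate_iat_trials(trait: float, seed: int, subject: str = "S01") -> pd.DataFrame:
    """One subject's 190-trial, 7-block IAT table.

    RTs are lognormal around a subject-specific median; incongruent-mapping
    blocks (5-7) are scaled by a factor monotone in ``trait`` calibrated so
    the scored D-score equals the trait in expectation.  Error flags are
    drawn at fixed per-condition rates so that, for a fixed seed, the
    scored D is non-decreasing in the trait.
    """
    if not np.isfinite(trait):
        raise ConfigurationError("trait must be finite")
    rng = np.random.default_rng(seed)
    med = RT_MEDIAN_MS * np.exp(rng.normal(0.0, RT_BETWEEN_LOG_SD))
    mean_rt = med * np.exp(RT_WITHIN_LOG_SD**2 / 2.0)
    sd_rt = mean_rt * np.sqrt(np.exp(RT_WITHIN_LOG_SD**2) - 1.0)
    lam = _rt_shift_factor(trait, mean_rt, sd_rt)

    words = ("positive-word", "negative-word")
    faces = ("face-A", "face-B")
    rows = []
    for block, n, cond in BLOCK_PLAN:
        base = med * np.exp(rng.normal(0.0, RT_WITHIN_LOG_SD, n))
        err_u = rng.random(n)
        if cond == "learn-words":
            cats, p_err, shift = words, P_ERROR_CONGRUENT, 1.0
        elif cond == "learn-faces":
            cats, p_err, shift = faces, P_ERROR_CONGRUENT, 1.0
        elif cond == "congruent":
            cats, p_err, shift = words + faces, P_ERROR_CONGRUENT, 1.0
        elif cond == "practice-reversed":
            cats, p_err, shift = words, P_ERROR_PRACTICE, lam
        else:  # incongruent
            cats, p_err, shift = words + faces, P_ERROR_INCONGRUENT, lam
        cat_idx = rng.integers(0, len(cats), n)
        for k in range(n):
            rows.append({
                "subject": subject,
                "block": block,
                "trial": k + 1,
                "category": cats[cat_idx[k]],
                "rt_ms": float(base[k] * shift),
                "correct": bool(err_u[k] >= p_err),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hypnograms and whole-night EEG


def simulate_hypnogram(
    config: CohortConfig, seed_or_rng, night_scale: float | None = None
) -> Hypnogram:
    """Seeded cyclic hypnogram: W → N1 → N2 → N3 → N2 → (W) → REM per
    cycle, five cycles, with lognormal per-segment jitter plus a global
    night-length factor tuned to the target TST spread."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    scale = config.night_scale if night_scale is None else night_scale
    tst_scale = scale * config.tst_mean_min / _TEMPLATE_TST
    # global factor: segment jitter alone gives ~2% TST spread; the rest of
    # the target between-subject SD comes from a shared night-length factor
    global_sd = max(0.95 * config.tst_sd_min / config.tst_mean_min, 1e-3)
    g = np.exp(rng.normal(0.0, global_sd))

    def n_epochs(minutes: float, jitter: bool = True) -> int:
        if minutes <= 0:
            return 0
        m = minutes * (np.exp(rng.normal(0.0, _SEGMENT_JITTER_SD)) if jitter else 1.0)
        return max(1, int(round(2.0 * m)))

    stages: list[str] = ["W"] * max(1, int(round(2.0 * _NIGHT_LATENCY * scale)))
    for c in range(5):
        n2 = _NIGHT_N2[c] * tst_scale * g
        stages += ["N1"] * n_epochs(_NIGHT_N1[c] * tst_scale * g)
        stages += ["N2"] * n_epochs(0.6 * n2)
        stages += ["N3"] * n_epochs(_NIGHT_N3[c] * tst_scale * g)
        stages += ["N2"] * n_epochs(0.4 * n2)
        stages += ["W"] * n_epochs(_NIGHT_WAKE[c] * scale)
        stages += ["REM"] * n_epochs(_NIGHT_REM[c] * tst_scale * g)
    stages += ["W"] * max(1, int(round(2.0 * _NIGHT_FINAL_WAKE * scale)))
    return Hypnogram(stages=np.array(stages, object), lights_off_epoch=0,
                     lights_on_epoch=len(stages))


def _band_limited_noise(rng, n_rows: int, n_samples: int, rate: float,
                        band: tuple) -> np.ndarray:
    """Unit-variance noise whose spectrum is flat inside ``band`` and zero
    outside: an equal-amplitude, random-phase sum of in-band sinusoids."""
    white = rng.standard_normal((n_rows, n_samples))
    X = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples, 1.0 / rate)
    X[:, (f < band[0]) | (f > band[1])] = 0.0
    x = np.fft.irfft(X, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.maximum(sd, 1e-12)


def cohort_orientations(config: CohortConfig, lead_field: LeadField) -> np.ndarray:
    """Cohort-shared random unit dipole orientations, deterministic from the
    cohort seed.  Sharing orientations across subjects keeps the planted
    effect-voxel amplitude modulation from being confounded by
    orientation-dependent projection strength."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7_919]))
    o = rng.standard_normal((lead_field.n_voxels, 3))
    return o / np.linalg.norm(o, axis=1, keepdims=True)


def simulate_sleep_night(
    source_profile: np.ndarray,
    lead_field: LeadField,
    config: CohortConfig,
    seed: int,
    rate: float | None = None,
    night_scale: float | None = None,
    orientations: np.ndarray | None = None,
) -> tuple[SleepRecording, Hypnogram]:
    """Project per-voxel SWA sources through the lead field for one night.

    ``source_profile`` holds per-voxel dipole amplitudes (nA·m).  Each
    epoch carries 0.8-4.6 Hz random-phase source activity scaled by the
    stage factor (N3 > N2 >> REM/W) and by an exponential overnight
    decline, mixed to the scalp plus white channel noise; occasional
    epochs receive a broadband artifact burst.
    """
    source_profile = np.asarray(source_profile, float)
    if source_profile.shape != (lead_field.n_voxels,):
        raise ConfigurationError("source profile does not match the voxel grid")
    rng = np.random.default_rng(seed)
    fs = float(rate if rate is not None else config.rate)
    hyp = simulate_hypnogram(config, rng, night_scale)
    spe = int(round(30.0 * fs))
    n_e = lead_field.n_electrodes

    if orientations is None:
        orientations = cohort_orientations(config, lead_field)
    orient = np.asarray(orientations, float)
    if orient.shape != (lead_field.n_voxels, 3):
        raise ConfigurationError("orientations must be (n_voxels, 3)")
    geff = np.einsum("evk,vk->ev", lead_field.gain3, orient)

    active = np.flatnonzero(source_profile > 0)
    g_act = geff[:, active]
    amp_act = source_profile[active]

    data = np.zeros((n_e, hyp.n_epochs * spe), np.float32)
    sleep_elapsed_min = 0.0
    band = (0.8, 4.6)
    for i, stage in enumerate(hyp.stages):
        factor = STAGE_SWA_FACTOR[stage] * np.exp(
            -sleep_elapsed_min / config.swa_decline_tau_min
        )
        if stage != "W":
            sleep_elapsed_min += 0.5
        seg = np.zeros((n_e, spe))
        if active.size:
            src = _band_limited_noise(rng, active.size, spe, fs, band)
            seg = g_act @ (factor * amp_act[:, None] * src)
        noise_sd = config.channel_noise_uv
        if config.artifact_rate > 0 and rng.random() < config.artifact_rate:
            noise_sd *= 8.0
        if noise_sd > 0:
            seg = seg + rng.normal(0.0, noise_sd, (n_e, spe))
        data[:, i * spe : (i + 1) * spe] = seg
    rec = SleepRecording(
        data=data, rate=fs,
        ch_names=[f"E{i:02d}" for i in range(n_e)],
        electrode_positions=lead_field.electrode_positions,
        bad_channels=[],
    )
    return rec, hyp


def subject_source_profile(
    bundle: CohortBundle, subject: int, lead_field: LeadField
) -> np.ndarray:
    """Per-voxel dipole amplitudes for one subject: a uniform background
    plus a strengthened effect voxel scaled by the planted amplitude."""
    cfg = bundle.config
    ev = cfg.effect_voxel
    if ev is None:
        ev = default_effect_voxel(lead_field.voxel_grid)
    profile = np.full(lead_field.n_voxels, cfg.swa_source_namp)
    profile[ev] *= cfg.effect_source_gain * bundle.effect_amp[subject]
    return profile


# ---------------------------------------------------------------------------
# Fast path: normalized current-density maps without raw EEG


@dataclass
class CurrentDensityCohort:
    """Subject × voxel relative SWA maps with the matched behavior vector."""

    maps: np.ndarray      # (n_subjects, n_voxels); rows sum to 1
    behavior: np.ndarray  # (n_subjects,)
    tst: np.ndarray       # (n_subjects,), covariate
    effect_voxel: int
    grid: np.ndarray
    bundle: CohortBundle


def simulate_current_density_cohort(
    config: CohortConfig, grid: np.ndarray | None = None
) -> CurrentDensityCohort:
    """Directly emulate normalized sLORETA outputs for a cohort.

    Each subject's map is exp(γ·F) normalized to unit sum, where F is a
    spatially smooth Gaussian field (squared-exponential kernel, length
    scale ``spatial_smoothness_mm``) whose effect-voxel value is replaced
    by the planted, ``r_true``-correlated latent; on the log scale the
    planted correlation is preserved to first order.
    """
    if grid is None:
        grid = voxel_lattice(config.n_voxels_per_axis, config.spacing_mm)
    n_vox = grid.shape[0]
    ev = config.effect_voxel
    if ev is None:
        ev = default_effect_voxel(grid)
    if not 0 <= ev < n_vox:
        raise ConfigurationError("effect_voxel outside the voxel grid")
    bundle = simulate_cohort(config)
    rng = np.random.default_rng(bundle.map_seed)
    d2 = ((grid[:, None, :] - grid[None, :, :]) ** 2).sum(-1)
    K = np.exp(-0.5 * d2 / config.spatial_smoothness_mm**2)
    L = np.linalg.cholesky(K + 1e-8 * np.eye(n_vox))
    F = rng.standard_normal((config.n_subjects, n_vox)) @ L.T
    F[:, ev] = bundle.effect_field
    m = np.exp(config.map_log_scale * F)
    m /= m.sum(axis=1, keepdims=True)
    return CurrentDensityCohort(
        maps=m, behavior=bundle.behavior, tst=bundle.tst,
        effect_voxel=ev, grid=grid, bundle=bundle,
    )


def centered_lattice_subset(n_voxels: int, spacing_mm: float = 5.0) -> np.ndarray:
    """The ``n_voxels`` lattice points closest to the origin (stable order),
    drawn from a cube just large enough to contain them."""
    n_axis = 1
    while n_axis**3 < n_voxels:
        n_axis += 1
    grid = voxel_lattice(n_axis + 2, spacing_mm)
    order = np.argsort(np.linalg.norm(grid, axis=1), kind="stable")
    return grid[order[:n_voxels]]
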