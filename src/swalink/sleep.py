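"""Whole-night EEG handling: preprocessing, epoching, artifact masking,
stage-gated SWA spectra, sleep architecture and sleep-cycle segmentation.

A night is a multichannel recording in µV plus a hypnogram of 30-s stage
labels (W, N1, N2, N3, REM).  Slow-wave activity (SWA) is spectral power in
0.8-4.6 Hz; all SWA quantities are computed from artifact-free N2/N3 epochs
only.  Filtering and bad-channel spherical-spline interpolation are
delegated to mne.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .errors import (
    AlignmentError,
    ConfigurationError,
    DegenerateInputError,
    EmptySelectionError,
)

EPOCH_SEC = 30.0
STAGES = ("W", "N1", "N2", "N3", "REM")
SWA_BAND = (0.8, 4.6)
BETA_BAND = (20.0, 40.0)

#: stage groups used when pooling neighboring epochs for artifact thresholds
STAGE_GROUPS = {"W": "W", "N1": "NREM", "N2": "NREM", "N3": "NREM", "REM": "REM"}


@dataclass
class Hypnogram:
    """30-s stage labels with lights-off/on markers delimiting time in bed."""

    stages: np.ndarray  # array of str, one per 30-s epoch
    lights_off_epoch: int = 0
    lights_on_epoch: int | None = None

    def __post_init__(self):
        self.stages = np.asarray(self.stages, dtype=object)
        if self.lights_on_epoch is None:
            self.lights_on_epoch = len(self.stages)
        bad = sorted(set(self.stages) - set(STAGES))
        if bad:
            first = int(np.flatnonzero(np.isin(self.stages, bad))[0])
            raise ConfigurationError(
                f"unknown stage label(s) {bad}, first at epoch {first}"
            )
        if not (0 <= self.lights_off_epoch < self.lights_on_epoch <= len(self.stages)):
            raise ConfigurationError("invalid lights_off/lights_on markers")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    def in_bed(self) -> np.ndarray:
        mask = np.zeros(self.n_epochs, bool)
        mask[self.lights_off_epoch : self.lights_on_epoch] = True
        return mask


@dataclass
class SleepRecording:
    """Multichannel night EEG, µV, with montage positions for interpolation."""

    data: np.ndarray          # (n_channels, n_samples), µV
    rate: float               # samples/s
    ch_names: list[str]
    electrode_positions: np.ndarray | None = None  # (n_channels, 3), mm
    bad_channels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.rate <= 0:
            raise ConfigurationError("sampling rate must be positive")
        if self.data.shape[0] != len(self.ch_names):
            raise AlignmentError("channel count does not match channel names")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochedRecording:
    """30-s epochs with stage labels and per-epoch artifact flags."""

    epochs: np.ndarray    # (n_epochs, n_channels, samples_per_epoch), µV
    stages: np.ndarray
    artifact: np.ndarray  # (n_epochs,), bool
    rate: float

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def usable(self, stages=("N2", "N3")) -> np.ndarray:
        return np.isin(self.stages, stages) & ~self.artifact


@dataclass(frozen=True)
class ChannelSWASpectrum:
    psd: np.ndarray        # (n_channels, n_freqs), µV²/Hz
    freqs: np.ndarray
    band_power: np.ndarray  # (n_channels,), µV², integral over the SWA band
    n_epochs_used: int
    band: tuple = SWA_BAND


@dataclass(frozen=True)
class SleepArchitecture:
    tst_min: float
    time_in_bed_min: float
    sleep_efficiency_pct: float
    sleep_onset_latency_min: float
    waso_min: float
    pct_n1: float
    pct_n2: float
    pct_n3: float
    pct_rem: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class SleepCycle:
    index: int
    start_epoch: int
    end_epoch: int  # inclusive; last epoch of the closing REM period
    nrem_minutes: float
    rem_minutes: float


@dataclass(frozen=True)
class ArtifactParams:
    """Semi-automatic rejection: an epoch is artifactual when its
    channel-mean power in either band exceeds ``factor`` times the centered
    moving average over neighboring epochs of the same stage group."""

    factor_swa: float = 2.0
    factor_beta: float = 2.5
    window_epochs: int = 15
    swa_band: tuple = SWA_BAND
    beta_band: tuple = BETA_BAND


def preprocess_record(
    rec: SleepRecording,
    bad_channels: list[str] | None = None,
    l_freq: float = 0.5,
    h_freq: float = 40.0,
    interpolation: str = "spline",
) -> SleepRecording:
    """Zero-phase 0.5-40 Hz band-pass, spherical interpolation of bad
    channels, and average re-referencing.

    The filter is mne's zero-phase Hamming-window FIR with 0.25 Hz
    transition width at the low edge and 2 Hz at the high edge.
    ``interpolation`` may be "spline" (spherical splines, order 4) or
    "nearest" (inverse-distance blend of the nearest good electrodes on the
    sphere).
    """
    import mne

    if rec.rate < 100:
        raise ConfigurationError("sampling rate must be >= 100 Hz for preprocessing")
    bads = list(bad_channels if bad_channels is not None else rec.bad_channels)
    unknown = set(bads) - set(rec.ch_names)
    if unknown:
        raise ConfigurationError(f"unknown bad channel(s): {sorted(unknown)}")
    if len(bads) >= rec.n_channels - 1:
        raise DegenerateInputError("fewer than 2 good channels; recording unusable")

    data = mne.filter.filter_data(
        rec.data.astype(np.float64), rec.rate, l_freq, h_freq,
        l_trans_bandwidth=0.25, h_trans_bandwidth=2.0,
        fir_window="hamming", fir_design="firwin", phase="zero",
        verbose="ERROR",
    )

    if bads:
        if rec.electrode_positions is None:
            raise ConfigurationError("electrode positions required to interpolate")
        bad_idx = [rec.ch_names.index(b) for b in bads]
        good_idx = [i for i in range(rec.n_channels) if i not in bad_idx]
        if interpolation == "spline":
            info = mne.create_info(rec.ch_names, rec.rate, "eeg")
            montage = mne.channels.make_dig_montage(
                ch_pos={n: p * 1e-3 for n, p in zip(rec.ch_names, rec.electrode_positions)},
                coord_frame="head",
            )
            raw = mne.io.RawArray(data * 1e-6, info, verbose="ERROR")
            raw.set_montage(montage, verbose="ERROR")
            raw.info["bads"] = bads
            raw.interpolate_bads(origin=(0.0, 0.0, 0.0), verbose="ERROR")
            data = raw.get_data() * 1e6
        elif interpolation == "nearest":
            pos = rec.electrode_positions
            for bi in bad_idx:
                d = np.linalg.norm(pos[good_idx] - pos[bi], axis=1)
                near = np.argsort(d)[:3]
                w = 1.0 / np.maximum(d[near], 1e-6)
                data[bi] = (w @ data[[good_idx[i] for i in near]]) / w.sum()
        else:
            raise ConfigurationError(f"unknown interpolation mode {interpolation!r}")

    data -= data.mean(axis=0, keepdims=True)  # average reference
    return replace(rec, data=data, bad_channels=[])


def _band_powers_welch(x: np.ndarray, rate: float, bands: tuple) -> list[float]:
    """Channel-mean integrated power of one epoch in each band (µV²)."""
    nperseg = min(int(round(5.0 * rate)), x.shape[-1])
    f, p = signal.welch(x, fs=rate, window="hann", nperseg=nperseg,
                        noverlap=nperseg // 2, axis=-1)
    df = f[1] - f[0]
    out = []
    for band in bands:
        m = (f >= band[0] - 1e-9) & (f <= band[1] + 1e-9)
        out.append(float(p[..., m].sum(axis=-1).mean() * df))
    return out


def epoch_and_mask_artifacts(
    rec: SleepRecording,
    hyp: Hypnogram,
    params: ArtifactParams | None = None,
) -> EpochedRecording:
    """Cut the recording into labeled 30-s epochs and flag artifacts.

    Rejection uses both the 0.8-4.6 Hz and 20-40 Hz bands; the moving
    average runs over ``window_epochs`` epochs of the same stage group
    (centered, edge-truncated, self included).
    """
    params = params or ArtifactParams()
    spe = int(round(EPOCH_SEC * rec.rate))
    needed = hyp.n_epochs * spe
    if rec.n_samples < needed:
        raise AlignmentError(
            f"recording has {rec.n_samples} samples but the hypnogram spans {needed}"
        )
    epochs = rec.data[:, :needed].reshape(rec.n_channels, hyp.n_epochs, spe)
    epochs = np.ascontiguousarray(np.moveaxis(epochs, 1, 0))

    p_swa = np.empty(hyp.n_epochs)
    p_beta = np.empty(hyp.n_epochs)
    for i in range(hyp.n_epochs):
        p_swa[i], p_beta[i] = _band_powers_welch(
            epochs[i], rec.rate, (params.swa_band, params.beta_band))

    artifact = np.zeros(hyp.n_epochs, bool)
    groups = np.array([STAGE_GROUPS[s] for s in hyp.stages])
    half = params.window_epochs // 2
    for grp in np.unique(groups):
        idx = np.flatnonzero(groups == grp)
        for j, ei in enumerate(idx):
            lo, hi = max(0, j - half), min(len(idx), j + half + 1)
            win = idx[lo:hi]
            if p_swa[ei] > params.factor_swa * p_swa[win].mean():
                artifact[ei] = True
            if p_beta[ei] > params.factor_beta * p_beta[win].mean():
                artifact[ei] = True
    return EpochedRecording(epochs=epochs, stages=hyp.stages.copy(),
                            artifact=artifact, rate=rec.rate)


def compute_swa_spectra(
    ep: EpochedRecording,
    band: tuple = SWA_BAND,
    stages: tuple = ("N2", "N3"),
    seg_sec: float = 5.0,
) -> ChannelSWASpectrum:
    """Hanning-windowed Welch spectra of artifact-free N2/N3 epochs,
    averaged over epochs per channel; band power integrates the PSD over
    [0.8, 4.6] Hz with inclusive edges."""
    use = np.flatnonzero(ep.usable(stages))
    if use.size == 0:
        raise EmptySelectionError(f"no artifact-free epochs in stages {stages}")
    nperseg = min(int(round(seg_sec * ep.rate)), ep.epochs.shape[-1])
    psd_sum = None
    for i in use:
        f, p = signal.welch(ep.epochs[i], fs=ep.rate, window="hann",
                            nperseg=nperseg, noverlap=nperseg // 2, axis=-1)
        psd_sum = p if psd_sum is None else psd_sum + p
    psd = psd_sum / use.size
    df = f[1] - f[0]
    m = (f >= band[0] - 1e-9) & (f <= band[1] + 1e-9)
    return ChannelSWASpectrum(
        psd=psd, freqs=f, band_power=psd[:, m].sum(axis=1) * df,
        n_epochs_used=int(use.size), band=band,
    )


def band_cross_spectrum(
    ep: EpochedRecording,
    band: tuple = SWA_BAND,
    stages: tuple = ("N2", "N3"),
    seg_sec: float = 5.0,
    epoch_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Channel cross-spectral matrix accumulated over the SWA band.

    Returns (C, n_epochs_used) where C is the Hermitian (real part) cross
    spectrum averaged over Hann segments and band bins of the selected
    artifact-free epochs.  ``epoch_mask`` optionally restricts epochs
    further (e.g. to one sleep cycle).
    """
    use = ep.usable(stages)
    if epoch_mask is not None:
        use = use & np.asarray(epoch_mask, bool)
    idx = np.flatnonzero(use)
    if idx.size == 0:
        raise EmptySelectionError(f"no artifact-free epochs in stages {stages}")
    nperseg = min(int(round(seg_sec * ep.rate)), ep.epochs.shape[-1])
    step = nperseg // 2
    win = signal.get_window("hann", nperseg)
    scale = 1.0 / (ep.rate * (win**2).sum())
    freqs = np.fft.rfftfreq(nperseg, 1.0 / ep.rate)
    m = (freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9)
    n_ch = ep.epochs.shape[1]
    C = np.zeros((n_ch, n_ch))
    count = 0
    for i in idx:
        x = ep.epochs[i]
        for start in range(0, x.shape[-1] - nperseg + 1, step):
            seg = x[:, start : start + nperseg] * win
            X = np.fft.rfft(seg, axis=-1)[:, m]
            C += scale * (X @ X.conj().T).real
            count += 1
    return C / count, int(idx.size)


def sleep_architecture(hyp: Hypnogram) -> SleepArchitecture:
    """TST, efficiency, WASO and stage percentages from a hypnogram.

    TST counts sleep-stage epochs inside the lights-off window at 0.5 min
    each; efficiency is TST over time in bed; WASO is wake time between
    sleep onset (first epoch of any sleep stage) and the final awakening.
    """
    inbed = hyp.stages[hyp.lights_off_epoch : hyp.lights_on_epoch]
    sleep = inbed != "W"
    if not sleep.any():
        raise EmptySelectionError("no sleep epochs; architecture undefined")
    onset = int(np.flatnonzero(sleep)[0])
    last = int(np.flatnonzero(sleep)[-1])
    tst = 0.5 * float(sleep.sum())
    tib = 0.5 * float(len(inbed))
    waso = 0.5 * float((~sleep[onset : last + 1]).sum())
    counts = {s: float((inbed == s).sum()) for s in ("N1", "N2", "N3", "REM")}
    total = sum(counts.values())
    pct = {s: 100.0 * c / total for s, c in counts.items()}
    return SleepArchitecture(
        tst_min=tst,
        time_in_bed_min=tib,
        sleep_efficiency_pct=100.0 * tst / tib,
        sleep_onset_latency_min=0.5 * onset,
        waso_min=waso,
        pct_n1=pct["N1"], pct_n2=pct["N2"], pct_n3=pct["N3"], pct_rem=pct["REM"],
    )


def detect_sleep_cycles(
    hyp: Hypnogram,
    nrem_min_min: float = 15.0,
    rem_min_min: float = 5.0,
) -> list[SleepCycle]:
    """NREM-REM cycle segmentation (Feinberg-Floyd style rules).

    A cycle is an NREM period of at least ``nrem_min_min`` minutes followed
    by a REM period of at least ``rem_min_min`` minutes; the first REM
    period is exempt from the REM minimum.  Cycle boundaries fall at the
    end of the closing REM period; trailing NREM meeting the minimum but
    without subsequent REM closes the final cycle at the last sleep epoch.
    Returns an empty list when no complete cycle exists.
    """
    stages = hyp.stages[hyp.lights_off_epoch : hyp.lights_on_epoch]
    offset = hyp.lights_off_epoch
    sleep_idx = np.flatnonzero(stages != "W")
    if sleep_idx.size == 0:
        return []

    # compress into runs of (label, start, length) over the in-bed window
    runs = []
    i = 0
    while i < len(stages):
        j = i
        while j < len(stages) and stages[j] == stages[i]:
            j += 1
        runs.append((stages[i], i, j - i))
        i = j

    cycles: list[SleepCycle] = []
    nrem_ep = 0
    rem_ep = 0
    start = None
    first_rem_seen = False
    last_sleep = int(sleep_idx[-1])
    for label, rstart, rlen in runs:
        if label == "W":
            continue
        if start is None:
            start = rstart
        if label == "REM":
            qualifies = (not first_rem_seen) or (0.5 * rlen >= rem_min_min)
            first_rem_seen = True
            rem_ep += rlen
            if qualifies and 0.5 * nrem_ep >= nrem_min_min:
                cycles.append(SleepCycle(
                    index=len(cycles) + 1,
                    start_epoch=start + offset,
                    end_epoch=rstart + rlen - 1 + offset,
                    nrem_minutes=0.5 * nrem_ep,
                    rem_minutes=0.5 * rem_ep,
                ))
                nrem_ep = rem_ep = 0
                start = None
        else:
            nrem_ep += rlen
    if start is not None and 0.5 * nrem_ep >= nrem_min_min:
        cycles.append(SleepCycle(
            index=len(cycles) + 1,
            start_epoch=start + offset,
            end_epoch=last_sleep + offset,
            nrem_minutes=0.5 * nrem_ep,
            rem_minutes=0.5 * rem_ep,
        ))
    return cycles


def cycle_epoch_mask(hyp: Hypnogram, cycle: SleepCycle) -> np.ndarray:
    """Boolean epoch mask selecting one sleep cycle on the full hypnogram."""
    mask = np.zeros(hyp.n_epochs, bool)
    mask[cycle.start_epoch : cycle.end_epoch + 1] = True
    return mask
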