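"""Readers and writers for every on-disk format the pipeline touches.

Recordings travel as 16-bit EDF (µV physical units, 1-s records); the
writer here emits plain EDF and recordings are read back through
``mne.io.read_raw_edf``, so every round trip is also an independent check
of the writer.  Hypnograms, IAT trials, behavior and covariates are CSV;
voxel grids, maps and null samples are TSV; configuration, manifests and
reports are JSON with explicit seeds.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import BundleValidationError, ConfigurationError
from .inverse import CurrentDensityMap
from .sleep import STAGES, Hypnogram, SleepRecording

# ---------------------------------------------------------------------------
# EDF


def _pad(text: str, width: int) -> bytes:
    b = str(text).encode("ascii")
    if len(b) > width:
        raise ConfigurationError(f"EDF header field too long: {text!r}")
    return b.ljust(width)


def write_edf(path, rec: SleepRecording) -> None:
    """Write a recording as 16-bit EDF with 1-second data records.

    Physical units are µV with a symmetric per-channel range; the sampling
    rate must be an integer (samples per 1-s record).  The final partial
    record, if any, is zero-padded.
    """
    rate = rec.rate
    if abs(rate - round(rate)) > 1e-9:
        raise ConfigurationError("EDF writer requires an integer sampling rate")
    spr = int(round(rate))
    n_ch = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / spr))
    data = np.zeros((n_ch, n_rec * spr), np.float64)
    data[:, : rec.n_samples] = rec.data

    amax = np.maximum(np.abs(data).max(axis=1), 1.0) * (1.0 + 1e-6)
    dig_min, dig_max = -32768, 32767
    scaled = np.round(
        (data + amax[:, None]) / (2 * amax[:, None]) * (dig_max - dig_min) + dig_min
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad("X X X X", 80))
        fh.write(_pad("Startdate 01-JAN-2001 X X X", 80))
        fh.write(_pad("01.01.01", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(256 * (n_ch + 1)), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_rec), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(n_ch), 4))
        for name in rec.ch_names:
            fh.write(_pad(name, 16))
        for _ in range(n_ch):
            fh.write(_pad("", 80))
        for _ in range(n_ch):
            fh.write(_pad("uV", 8))
        for a in amax:
            fh.write(_pad(f"{-a:.6g}"[:8], 8))
        for a in amax:
            fh.write(_pad(f"{a:.6g}"[:8], 8))
        for _ in range(n_ch):
            fh.write(_pad(str(dig_min), 8))
        for _ in range(n_ch):
            fh.write(_pad(str(dig_max), 8))
        for _ in range(n_ch):
            fh.write(_pad("", 80))
        for _ in range(n_ch):
            fh.write(_pad(str(spr), 8))
        for _ in range(n_ch):
            fh.write(_pad("", 32))
        for r in range(n_rec):
            fh.write(scaled[:, r * spr : (r + 1) * spr].tobytes())


def read_edf(path, electrode_positions=None) -> SleepRecording:
    """Read an EDF recording (via mne) back into µV."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="ERROR")
    return SleepRecording(
        data=raw.get_data() * 1e6,
        rate=float(raw.info["sfreq"]),
        ch_names=list(raw.ch_names),
        electrode_positions=electrode_positions,
    )


def edf_header_info(path) -> dict:
    """Channel count, record structure and rate from a raw EDF header."""
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256 or header[:8].strip() != b"0":
            raise ConfigurationError(f"{path}: not a valid EDF header")
        n_rec = int(header[236:244])
        rec_dur = float(header[244:252])
        n_ch = int(header[252:256])
        sig = fh.read(256 * n_ch)
        if len(sig) < 256 * n_ch:
            raise ConfigurationError(f"{path}: truncated EDF signal header")
        off = n_ch * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
        spr = int(sig[off : off + 8])
    return {"n_channels": n_ch, "n_records": n_rec, "record_duration_s": rec_dur,
            "rate": spr / rec_dur}


# ---------------------------------------------------------------------------
# CSV / TSV tables


def write_hypnogram_csv(path, hyp: Hypnogram) -> None:
    pd.DataFrame({
        "epoch_index": np.arange(hyp.n_epochs),
        "stage": hyp.stages,
    }).to_csv(path, index=False)


def read_hypnogram_csv(path, lights_off_epoch=0, lights_on_epoch=None) -> Hypnogram:
    df = pd.read_csv(path)
    if not {"epoch_index", "stage"} <= set(df.columns):
        raise ConfigurationError(f"{path}: hypnogram needs epoch_index,stage columns")
    df = df.sort_values("epoch_index")
    return Hypnogram(stages=df["stage"].to_numpy(object),
                     lights_off_epoch=lights_off_epoch,
                     lights_on_epoch=lights_on_epoch)


def write_iat_csv(path, trials: pd.DataFrame) -> None:
    trials.to_csv(path, index=False)


def read_iat_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_grid_tsv(path, grid: np.ndarray) -> None:
    pd.DataFrame(grid, columns=["x_mm", "y_mm", "z_mm"]).to_csv(
        path, sep="\t", index=False)


def read_grid_tsv(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t")[["x_mm", "y_mm", "z_mm"]].to_numpy(float)


def save_map(path_base, m: CurrentDensityMap) -> None:
    """TSV of (x, y, z, value) plus a JSON metadata sidecar."""
    base = Path(path_base)
    df = pd.DataFrame(m.grid, columns=["x_mm", "y_mm", "z_mm"])
    df["value"] = m.values
    df.to_csv(base.with_suffix(".tsv"), sep="\t", index=False)
    write_json(base.with_suffix(".json"), {
        "normalized": m.normalized, "log_transformed": m.log_transformed,
        "band_hz": list(m.band), "n_epochs_used": m.n_epochs_used,
    })


def load_map(path_base) -> CurrentDensityMap:
    base = Path(path_base)
    df = pd.read_csv(base.with_suffix(".tsv"), sep="\t")
    meta = read_json(base.with_suffix(".json"))
    return CurrentDensityMap(
        values=df["value"].to_numpy(float),
        grid=df[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
        normalized=bool(meta["normalized"]),
        log_transformed=bool(meta["log_transformed"]),
        band=tuple(meta["band_hz"]),
        n_epochs_used=meta.get("n_epochs_used"),
    )


def write_maps_matrix_tsv(path, maps: np.ndarray, subjects) -> None:
    df = pd.DataFrame(maps, columns=[f"v{j}" for j in range(maps.shape[1])])
    df.insert(0, "subject", list(subjects))
    df.to_csv(path, sep="\t", index=False)


def read_maps_matrix_tsv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    subjects = df["subject"].astype(str).tolist()
    return df.drop(columns="subject").to_numpy(float), subjects


def write_spectra_tsv(path, spectrum) -> None:
    df = pd.DataFrame(spectrum.psd,
                      columns=[f"{f:.4f}" for f in spectrum.freqs])
    df.insert(0, "channel", np.arange(spectrum.psd.shape[0]))
    df.to_csv(path, sep="\t", index=False)


def write_series_csv(path, values, subjects, column: str) -> None:
    pd.DataFrame({"subject": list(subjects), column: values}).to_csv(path, index=False)


def read_series_csv(path, column: str | None = None) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path)
    col = column or df.columns[-1]
    return df[col].to_numpy(float), df["subject"].astype(str).tolist()


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# Study bundles


@dataclasses.dataclass
class SubjectPaths:
    subject: str
    edf: Path
    hypnogram: Path
    iat: Path
    lights_off_epoch: int = 0
    lights_on_epoch: int | None = None


@dataclasses.dataclass
class StudyBundle:
    """Validated per-subject file paths plus the pipeline configuration."""

    subjects: list[SubjectPaths]
    config: dict
    root: Path


IAT_COLUMNS = ("block", "trial", "category", "rt_ms", "correct")


def load_study_bundle(manifest_path) -> StudyBundle:
    """Load and validate a study manifest.

    Checks, per subject: referenced files exist, the EDF header is sane and
    matches the configured channel count, hypnogram stage labels are in the
    vocabulary, and the IAT table has the required columns.  All problems
    are aggregated into one :class:`BundleValidationError`.
    """
    manifest_path = Path(manifest_path)
    manifest = read_json(manifest_path)
    root = manifest_path.parent
    config = manifest.get("config", {})
    n_channels = config.get("n_electrodes")
    errors: list[str] = []
    subjects: list[SubjectPaths] = []
    seen = set()
    for entry in manifest.get("subjects", []):
        sid = str(entry.get("id", "?"))
        if sid in seen:
            errors.append(f"{sid}: duplicate subject id")
            continue
        seen.add(sid)
        paths = {}
        ok = True
        for key in ("edf", "hypnogram", "iat"):
            p = root / entry.get(key, f"<missing {key}>")
            paths[key] = p
            if not p.is_file():
                errors.append(f"{sid}: missing {key} file {p.name}")
                ok = False
        if not ok:
            continue
        try:
            info = edf_header_info(paths["edf"])
            if n_channels is not None and info["n_channels"] != n_channels:
                errors.append(
                    f"{sid}: EDF has {info['n_channels']} channels, "
                    f"manifest expects {n_channels}"
                )
                ok = False
        except (ConfigurationError, ValueError) as exc:
            errors.append(f"{sid}: {exc}")
            ok = False
        try:
            df = pd.read_csv(paths["hypnogram"])
            bad = sorted(set(df["stage"]) - set(STAGES))
            if bad:
                ep = int(df.loc[df["stage"].isin(bad), "epoch_index"].iloc[0])
                errors.append(f"{sid}: unknown stage {bad[0]!r} at epoch {ep}")
                ok = False
        except Exception as exc:
            errors.append(f"{sid}: unreadable hypnogram ({exc})")
            ok = False
        try:
            cols = set(pd.read_csv(paths["iat"], nrows=1).columns)
            missing = [c for c in IAT_COLUMNS if c not in cols]
            if missing:
                errors.append(f"{sid}: IAT table missing columns {missing}")
                ok = False
        except Exception as exc:
            errors.append(f"{sid}: unreadable IAT table ({exc})")
            ok = False
        if ok:
            subjects.append(SubjectPaths(
                subject=sid, edf=paths["edf"], hypnogram=paths["hypnogram"],
                iat=paths["iat"],
                lights_off_epoch=int(entry.get("lights_off_epoch", 0)),
                lights_on_epoch=entry.get("lights_on_epoch"),
            ))
    if errors:
        raise BundleValidationError(errors)
    return StudyBundle(subjects=subjects, config=config, root=root)


def write_study_bundle(directory, recordings, hypnograms, iat_tables,
                       config: dict, grid: np.ndarray | None = None) -> Path:
    """Write per-subject EDF/CSV files plus a manifest; returns its path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for sid in recordings:
        write_edf(directory / f"{sid}.edf", recordings[sid])
        write_hypnogram_csv(directory / f"{sid}_hypnogram.csv", hypnograms[sid])
        write_iat_csv(directory / f"{sid}_iat.csv", iat_tables[sid])
        entries.append({
            "id": sid, "edf": f"{sid}.edf",
            "hypnogram": f"{sid}_hypnogram.csv", "iat": f"{sid}_iat.csv",
            "lights_off_epoch": int(hypnograms[sid].lights_off_epoch),
            "lights_on_epoch": int(hypnograms[sid].lights_on_epoch),
        })
    if grid is not None:
        write_grid_tsv(directory / "voxel_grid.tsv", grid)
    manifest = directory / "manifest.json"
    write_json(manifest, {"subjects": entries, "config": config})
    return manifest
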