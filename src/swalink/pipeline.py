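"""End-to-end orchestration: score → preprocess → spectra → localize →
normalize → correlate → report, with subject-level exclusion bookkeeping
and full provenance (config, seeds, versions)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import PipelineError, SwalinkError
from .headmodel import generate_lead_field
from .iat import DScoreResult, score_iat, summarize_cohort_behavior
from .inverse import (
    CurrentDensityMap,
    build_inverse_operator,
    localize_band_power,
    normalize_log_map,
)
from .io import StudyBundle, read_edf, read_hypnogram_csv, read_iat_csv
from .simulate import CohortConfig, default_effect_voxel
from .sleep import (
    band_cross_spectrum,
    compute_swa_spectra,
    cycle_epoch_mask,
    detect_sleep_cycles,
    epoch_and_mask_artifacts,
    preprocess_record,
    sleep_architecture,
)
from .stats import (
    build_roi_sphere,
    extract_clusters,
    meng_dependent_correlation_test,
    mirror_roi,
    partial_correlation,
    per_cycle_analysis,
    permutation_fwer_threshold,
    roi_mean_density,
    voxelwise_partial_correlation,
)

logger = logging.getLogger("swalink")


@dataclasses.dataclass
class AnalysisResult:
    """Cohort-level brain-behavior statistics on normalized log maps."""

    stat_map: object                  # VoxelwiseStatMap
    permutation: object               # PermutationResult
    clusters: object                  # ClusterSet
    roi: object | None                # SphericalROI at the peak, or None
    roi_r: float | None
    roi_p: float | None
    roi_r_squared: float | None
    roi_means: np.ndarray | None
    mirror_roi: object | None
    mirror_r: float | None
    mirror_means: np.ndarray | None
    laterality: object | None         # MengResult
    log_maps: np.ndarray              # (n_subjects, n_voxels)
    grid: np.ndarray


def normalize_log_maps(maps: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    """Row-normalize nonnegative maps to unit sum, then log10 with floor."""
    maps = np.asarray(maps, float)
    totals = maps.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise PipelineError("a subject map is all-zero; cannot normalize")
    return np.log10(np.maximum(maps / totals, floor))


def analyze_cohort(
    maps: np.ndarray,
    behavior: np.ndarray,
    covariates,
    grid: np.ndarray,
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int = 0,
    roi_radius_mm: float = 15.0,
    maps_are_log: bool = False,
) -> AnalysisResult:
    """Whole-brain-corrected voxel-wise correlation analysis.

    ``maps`` are per-subject raw current-density maps (normalized and
    log-transformed here unless ``maps_are_log``); behavior is correlated
    voxel-wise controlling for the covariates, the max-statistic
    permutation threshold marks significant voxels, clusters are extracted,
    a spherical ROI is built at the strongest peak, and the homologous
    mirrored ROI is compared with Meng's test.
    """
    log_maps = np.asarray(maps, float) if maps_are_log else normalize_log_maps(maps)
    stat = voxelwise_partial_correlation(log_maps, behavior, covariates)
    perm = permutation_fwer_threshold(
        log_maps, behavior, covariates, n_perm=n_perm, alpha=alpha, seed=seed)
    clusters = extract_clusters(perm.significant, grid, r=stat.r)

    roi = roi_r = roi_p = roi_r2 = roi_means = None
    mroi = mr = mmeans = meng = None
    if len(clusters):
        peak = clusters.clusters[0].peak_index
        roi = build_roi_sphere(grid[peak], grid, radius_mm=roi_radius_mm)
        roi_means = log_maps[:, roi.voxel_indices].mean(axis=1)
        roi_r, roi_p, _ = partial_correlation(roi_means, behavior, covariates)
        roi_r2 = roi_r**2
        mroi = mirror_roi(roi, grid)
        mmeans = log_maps[:, mroi.voxel_indices].mean(axis=1)
        mr, _, _ = partial_correlation(mmeans, behavior, covariates)
        r12 = float(np.corrcoef(roi_means, mmeans)[0, 1])
        meng = meng_dependent_correlation_test(roi_r, mr, r12, behavior.size)
    return AnalysisResult(
        stat_map=stat, permutation=perm, clusters=clusters, roi=roi,
        roi_r=roi_r, roi_p=roi_p, roi_r_squared=roi_r2, roi_means=roi_means,
        mirror_roi=mroi, mirror_r=mr, mirror_means=mmeans, laterality=meng,
        log_maps=log_maps, grid=grid,
    )


@dataclasses.dataclass
class ResultsBundle:
    behavior_table: pd.DataFrame
    architecture_table: pd.DataFrame
    band_power_table: pd.DataFrame
    maps: np.ndarray
    subjects: list[str]
    analysis: AnalysisResult
    cycle_table: pd.DataFrame
    exclusions: dict
    provenance: dict

    def write(self, directory) -> None:
        from .io import write_json, write_maps_matrix_tsv

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.behavior_table.to_csv(directory / "behavior.csv", index=False)
        self.architecture_table.to_csv(directory / "architecture.csv", index=False)
        self.band_power_table.to_csv(directory / "band_power.csv", index=False)
        write_maps_matrix_tsv(directory / "maps.tsv", self.maps, self.subjects)
        stat = self.analysis.stat_map
        pd.DataFrame({
            "x_mm": self.analysis.grid[:, 0], "y_mm": self.analysis.grid[:, 1],
            "z_mm": self.analysis.grid[:, 2], "r": stat.r, "p": stat.p,
            "significant": self.analysis.permutation.significant,
        }).to_csv(directory / "stat_map.tsv", sep="\t", index=False)
        np.savetxt(directory / "null_max.tsv",
                   self.analysis.permutation.null_max[:, None], fmt="%.6f")
        self.cycle_table.to_csv(directory / "cycles.csv", index=False)
        report = {
            "critical_value": self.analysis.permutation.critical_value,
            "n_significant_voxels": int(self.analysis.permutation.significant.sum()),
            "clusters": [
                {"size_mm3": c.size_mm3, "peak_index": c.peak_index,
                 "peak_coord_mm": c.peak_coord.tolist(), "peak_abs_r": c.peak_abs_r}
                for c in self.analysis.clusters
            ],
            "roi": None if self.analysis.roi is None else {
                "center_mm": self.analysis.roi.center.tolist(),
                "radius_mm": self.analysis.roi.radius_mm,
                "n_voxels": int(self.analysis.roi.voxel_indices.size),
                "r": self.analysis.roi_r, "p": self.analysis.roi_p,
                "r_squared": self.analysis.roi_r_squared,
                "mirror_r": self.analysis.mirror_r,
            },
            "laterality": None if self.analysis.laterality is None else
                dataclasses.asdict(self.analysis.laterality),
            "exclusions": self.exclusions,
            "provenance": self.provenance,
        }
        write_json(directory / "report.json", report)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_full_pipeline(
    bundle: StudyBundle,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    snr: float = 10.0,
    roi_radius_mm: float = 15.0,
    min_subjects: int = 4,
    nrem_min_min: float = 15.0,
    rem_min_min: float = 5.0,
) -> ResultsBundle:
    """Execute the whole analysis on a validated study bundle.

    Each subject runs score → preprocess → epoch/artifact → spectra →
    localize; subjects failing any stage are excluded with a logged reason.
    Cohort statistics (voxel-wise partial correlation controlling total
    sleep time, permutation correction, clusters/ROI, laterality, per-cycle
    repeats) follow.  Fully deterministic given the bundle and seeds.
    """
    cfg = dict(bundle.config)
    cohort_cfg = CohortConfig(**{
        k: v for k, v in cfg.items()
        if k in CohortConfig.__dataclass_fields__
    }) if cfg else CohortConfig()
    lf = generate_lead_field(
        n_electrodes=cohort_cfg.n_electrodes,
        n_voxels_per_axis=cohort_cfg.n_voxels_per_axis,
        spacing_mm=cohort_cfg.spacing_mm,
        head_radius_mm=cohort_cfg.head_radius_mm,
    )
    inv = build_inverse_operator(lf, snr=snr)

    rows_beh, rows_arch, rows_bp = [], [], []
    maps, subjects, tst = [], [], []
    cycle_maps, cycle_durations = [], []
    exclusions: dict[str, str] = {}
    for sp in bundle.subjects:
        t0 = time.monotonic()
        try:
            trials = read_iat_csv(sp.iat)
            dres: DScoreResult = score_iat(trials, subject=sp.subject)
            rec = read_edf(sp.edf, electrode_positions=lf.electrode_positions)
            hyp = read_hypnogram_csv(sp.hypnogram, sp.lights_off_epoch,
                                     sp.lights_on_epoch)
            rec = preprocess_record(rec)
            ep = epoch_and_mask_artifacts(rec, hyp)
            spec = compute_swa_spectra(ep)
            arch = sleep_architecture(hyp)
            cycles = detect_sleep_cycles(hyp, nrem_min_min=nrem_min_min,
                                         rem_min_min=rem_min_min)
            C, n_used = band_cross_spectrum(ep)
            m = localize_band_power(C, inv, n_epochs_used=n_used)
            cmaps, cdur = [], []
            for cyc in cycles:
                try:
                    Cc, nc = band_cross_spectrum(
                        ep, epoch_mask=cycle_epoch_mask(hyp, cyc))
                except SwalinkError:
                    break
                cmaps.append(localize_band_power(Cc, inv, n_epochs_used=nc))
                cdur.append(cyc.nrem_minutes + cyc.rem_minutes)
        except SwalinkError as exc:
            logger.info("excluding %s: %s", sp.subject, exc)
            exclusions[sp.subject] = str(exc)
            continue
        logger.info("subject %s processed in %.1fs", sp.subject,
                    time.monotonic() - t0)
        subjects.append(sp.subject)
        rows_beh.append({"subject": sp.subject, **dres.to_dict()})
        rows_arch.append({"subject": sp.subject, **arch.to_dict()})
        rows_bp.append({"subject": sp.subject,
                        **{f"ch{i}": v for i, v in enumerate(spec.band_power)}})
        maps.append(m.values)
        tst.append(arch.tst_min)
        cycle_maps.append(cmaps)
        cycle_durations.append(cdur)

    if len(subjects) < min_subjects:
        raise PipelineError(
            f"only {len(subjects)} usable subjects (need >= {min_subjects})")

    maps = np.asarray(maps)
    behavior = np.array([r["abs_d"] for r in rows_beh])
    tst = np.asarray(tst)
    analysis = analyze_cohort(maps, behavior, tst, lf.voxel_grid,
                              n_perm=n_perm, alpha=alpha, seed=seed,
                              roi_radius_mm=roi_radius_mm)

    roi = analysis.roi
    if roi is None:
        # no whole-brain significant cluster: per-cycle repeats use the
        # default effect-region ROI so the table is still reportable
        center = lf.voxel_grid[default_effect_voxel(lf.voxel_grid)]
        roi = build_roi_sphere(center, lf.voxel_grid, radius_mm=roi_radius_mm)
    cyc_records = per_cycle_analysis(cycle_maps, behavior, cycle_durations, roi)
    cycle_table = pd.DataFrame([dataclasses.asdict(c) for c in cyc_records])

    summary = summarize_cohort_behavior(
        [score_from_row(r) for r in rows_beh])
    provenance = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "analysis_seed": seed,
        "n_perm": n_perm,
        "alpha": alpha,
        "snr": snr,
        "n_subjects_analyzed": len(subjects),
        "behavior_summary": summary.to_dict(),
    }
    return ResultsBundle(
        behavior_table=pd.DataFrame(rows_beh),
        architecture_table=pd.DataFrame(rows_arch),
        band_power_table=pd.DataFrame(rows_bp),
        maps=maps, subjects=subjects, analysis=analysis,
        cycle_table=cycle_table, exclusions=exclusions, provenance=provenance,
    )


def score_from_row(row: dict) -> DScoreResult:
    fields = {k: row[k] for k in DScoreResult.__dataclass_fields__ if k in row}
    return DScoreResult(**fields)
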