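"""Brain-behavior inference: voxel-wise partial correlations, max-statistic
permutation correction, clusters and spherical ROIs, laterality mirroring
with Meng's test for dependent correlations, and per-cycle analyses.

Family-wise error across voxels is controlled nonparametrically: the
behavioral residuals (Freedman-Lane) are permuted, the voxel-wise maximum
|r| is retained per permutation, and the critical value is the empirical
(1−α) quantile of the null maxima pooled with the observed maximum — the
(k+1)/(n_perm+1) convention that keeps the test valid at finite n_perm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from .errors import AlignmentError, ConfigurationError, DegenerateInputError
from .inverse import CurrentDensityMap


class PartialCorr(NamedTuple):
    r: float
    p: float
    df: int


def _design(n: int, covariates) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    Z = np.atleast_2d(np.asarray(covariates, float))
    if Z.shape[0] != n:
        Z = Z.T
    if Z.shape[0] != n:
        raise AlignmentError("covariate rows do not match the sample size")
    return np.column_stack([np.ones(n), Z])


def _residualize(y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return y - Z @ beta


def partial_correlation(x, y, covariates=None) -> PartialCorr:
    """Pearson correlation of x and y after projecting out [1, covariates].

    df = n − 2 − k; the two-sided p comes from t = r·√(df/(1−r²)).  With an
    intercept-only design this is the plain Pearson correlation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise AlignmentError("x and y must be equal-length vectors")
    n = x.size
    Z = _design(n, covariates)
    k = Z.shape[1] - 1
    if n < k + 3:
        raise ConfigurationError(f"need n >= k+3 (n={n}, k={k})")
    rx = _residualize(x, Z)
    ry = _residualize(y, Z)
    nx, ny = np.linalg.norm(rx), np.linalg.norm(ry)
    if nx <= 1e-12 * max(np.abs(x).max(), 1.0) or ny <= 1e-12 * max(np.abs(y).max(), 1.0):
        raise DegenerateInputError("zero residual variance after covariate adjustment")
    r = float(np.clip(rx @ ry / (nx * ny), -1.0, 1.0))
    df = n - 2 - k
    p = _r_to_p(np.array([r]), df)[0]
    return PartialCorr(r=r, p=float(p), df=df)


def _r_to_p(r: np.ndarray, df: int) -> np.ndarray:
    rr = np.clip(np.abs(r), 0.0, 1.0 - 1e-15)
    t = rr * np.sqrt(df / (1.0 - rr**2))
    return 2.0 * sps.t.sf(t, df)


def critical_r(n: int, alpha: float = 0.05, k: int = 0) -> float:
    """|r| whose two-sided p equals alpha at df = n−2−k (t-inverse)."""
    df = n - 2 - k
    t = sps.t.isf(alpha / 2.0, df)
    return float(t / np.sqrt(t**2 + df))


@dataclass(frozen=True)
class VoxelwiseStatMap:
    r: np.ndarray
    p: np.ndarray
    n: int
    k: int
    df: int
    excluded_voxels: np.ndarray  # indices of voxels constant across subjects

    @property
    def abs_r(self) -> np.ndarray:
        return np.abs(self.r)


def voxelwise_partial_correlation(
    maps: np.ndarray, behavior, covariates=None
) -> VoxelwiseStatMap:
    """Vectorized per-voxel partial correlation of maps with behavior.

    Constant voxels (zero residual variance) are excluded: their r and p
    are NaN and their indices reported.
    """
    maps = np.asarray(maps, float)
    y = np.asarray(behavior, float)
    if maps.ndim != 2 or maps.shape[0] != y.size:
        raise AlignmentError("maps must be (n_subjects, n_voxels) matching behavior")
    n = y.size
    Z = _design(n, covariates)
    k = Z.shape[1] - 1
    if n < k + 3:
        raise ConfigurationError(f"need n >= k+3 (n={n}, k={k})")
    U = maps - Z @ np.linalg.lstsq(Z, maps, rcond=None)[0]
    ry = _residualize(y, Z)
    ny = np.linalg.norm(ry)
    if ny <= 1e-12 * max(np.abs(y).max(), 1.0):
        raise DegenerateInputError("behavior constant after covariate adjustment")
    norms = np.linalg.norm(U, axis=0)
    scale = np.abs(maps).max(axis=0)
    excluded = np.flatnonzero(norms <= 1e-12 * np.maximum(scale, 1.0))
    safe = np.where(norms > 0, norms, 1.0)
    r = np.clip((ry @ U) / (safe * ny), -1.0, 1.0)
    df = n - 2 - k
    p = _r_to_p(r, df)
    r[excluded] = np.nan
    p[excluded] = np.nan
    return VoxelwiseStatMap(r=r, p=p, n=n, k=k, df=df, excluded_voxels=excluded)


@dataclass(frozen=True)
class PermutationResult:
    null_max: np.ndarray       # per-permutation maximum |r| over voxels
    critical_value: float
    significant: np.ndarray    # boolean voxel mask
    observed: VoxelwiseStatMap
    n_perm: int
    alpha: float
    seed: int | None
    scheme: str
    #: order-statistic convention: the critical value is the
    #: ⌈(1−α)(n_perm+1)⌉-th order statistic of {null maxima ∪ observed max}
    convention: str = "ceil((1-alpha)*(n_perm+1)) over null+observed"


def permutation_fwer_threshold(
    maps: np.ndarray,
    behavior,
    covariates=None,
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int | None = 0,
    scheme: str = "freedman-lane",
    permutations: np.ndarray | None = None,
) -> PermutationResult:
    """Max-statistic permutation threshold controlling family-wise error.

    Freedman-Lane: behavior is residualized on the covariates, residuals
    are permuted with a seeded generator, and voxel-wise |r| is recomputed;
    the per-permutation maximum over voxels forms the null.  Voxels whose
    observed |r| exceeds the critical value are significant.  ``scheme``
    "labels" permutes the raw behavior instead.  An explicit permutation
    array (n_perm, n) may be supplied, e.g. for exhaustive enumeration.
    """
    maps = np.asarray(maps, float)
    y = np.asarray(behavior, float)
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError("alpha must be in (0, 1)")
    if permutations is None and n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    n = y.size
    if np.std(y) == 0:
        raise DegenerateInputError("constant behavior cannot be permuted")
    observed = voxelwise_partial_correlation(maps, y, covariates)
    obs_abs = np.where(np.isnan(observed.r), -np.inf, np.abs(observed.r))

    Z = _design(n, covariates)
    U = maps - Z @ np.linalg.lstsq(Z, maps, rcond=None)[0]
    norms = np.linalg.norm(U, axis=0)
    ok = norms > 0
    Un = U[:, ok] / norms[ok]

    if permutations is not None:
        perms = np.asarray(permutations, int)
        n_perm = perms.shape[0]
    else:
        if math.lgamma(n + 1) < math.log(n_perm):
            warnings.warn(
                f"n! < n_perm: only {math.factorial(n)} distinct permutations exist",
                stacklevel=2,
            )
        rng = np.random.default_rng(seed)
        perms = np.stack([rng.permutation(n) for _ in range(n_perm)])

    if scheme not in ("freedman-lane", "labels"):
        raise ConfigurationError(f"unknown permutation scheme {scheme!r}")
    source = _residualize(y, Z) if scheme == "freedman-lane" else y
    E = source[perms]                          # (n_perm, n)
    # residualize each permuted vector on Z, then correlate with unit maps
    E = E - (E @ Z) @ np.linalg.pinv(Z.T @ Z) @ Z.T
    En = np.linalg.norm(E, axis=1)
    if np.any(En <= 0):
        raise DegenerateInputError("a permuted behavior vector is constant")
    R = (E / En[:, None]) @ Un                 # (n_perm, V_ok)
    null_max = np.abs(R).max(axis=1)

    combined = np.sort(np.concatenate([null_max, [obs_abs.max()]]))
    k_order = math.ceil((1.0 - alpha) * (n_perm + 1))
    critical = float(combined[k_order - 1])
    significant = obs_abs > critical
    return PermutationResult(
        null_max=null_max, critical_value=critical, significant=significant,
        observed=observed, n_perm=n_perm, alpha=alpha, seed=seed, scheme=scheme,
    )


# ---------------------------------------------------------------------------
# Clusters and ROIs


@dataclass(frozen=True)
class Cluster:
    voxel_indices: np.ndarray
    size_mm3: float
    peak_index: int
    peak_coord: np.ndarray
    peak_abs_r: float


@dataclass(frozen=True)
class ClusterSet:
    clusters: tuple

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)


def _grid_to_ijk(grid: np.ndarray, spacing: float) -> np.ndarray:
    origin = grid.min(axis=0)
    ijk = np.round((grid - origin) / spacing).astype(int)
    if not np.allclose(grid, origin + ijk * spacing, atol=1e-6 * spacing):
        raise AlignmentError("grid is not a regular lattice at the given spacing")
    return ijk


def extract_clusters(
    mask: np.ndarray,
    grid: np.ndarray,
    r: np.ndarray | None = None,
    spacing_mm: float | None = None,
    connectivity: int = 26,
) -> ClusterSet:
    """Connected components of significant voxels on the lattice.

    26-connectivity by default (6 available); cluster size is member count
    times spacing³; the peak is the member with maximal |r| (ties broken by
    lowest voxel index).
    """
    mask = np.asarray(mask, bool)
    if mask.size != grid.shape[0]:
        raise AlignmentError("mask length does not match the grid")
    if not mask.any():
        return ClusterSet(clusters=())
    if spacing_mm is None:
        d = np.linalg.norm(grid[1:] - grid[:-1], axis=1)
        spacing_mm = float(d[d > 0].min())
    ijk = _grid_to_ijk(grid, spacing_mm)
    shape = ijk.max(axis=0) + 1
    vol = np.zeros(shape, bool)
    vol[tuple(ijk[mask].T)] = True
    structure = (np.ones((3, 3, 3), bool) if connectivity == 26
                 else ndimage.generate_binary_structure(3, 1))
    labels, n_lab = ndimage.label(vol, structure=structure)
    lab_per_voxel = np.where(mask, labels[tuple(ijk.T)], 0)
    absr = np.abs(r) if r is not None else np.zeros(grid.shape[0])
    clusters = []
    for lab in range(1, n_lab + 1):
        members = np.flatnonzero(lab_per_voxel == lab)
        peak = members[int(np.argmax(absr[members]))]  # argmax → lowest index on ties
        clusters.append(Cluster(
            voxel_indices=members,
            size_mm3=float(members.size * spacing_mm**3),
            peak_index=int(peak),
            peak_coord=grid[peak].copy(),
            peak_abs_r=float(absr[peak]),
        ))
    clusters.sort(key=lambda c: (-c.size_mm3, c.peak_index))
    return ClusterSet(clusters=tuple(clusters))


@dataclass(frozen=True)
class SphericalROI:
    center: np.ndarray
    radius_mm: float
    voxel_indices: np.ndarray


def build_roi_sphere(
    center, grid: np.ndarray, radius_mm: float = 15.0
) -> SphericalROI:
    """Grid voxels within ``radius_mm`` (Euclidean, inclusive) of a center."""
    center = np.asarray(center, float)
    if radius_mm < 0:
        raise ConfigurationError("radius must be >= 0")
    d = np.linalg.norm(grid - center, axis=1)
    members = np.flatnonzero(d <= radius_mm + 1e-9)
    if members.size == 0:
        raise AlignmentError("ROI sphere does not intersect the grid")
    return SphericalROI(center=center, radius_mm=float(radius_mm),
                        voxel_indices=members)


def mirror_roi(roi: SphericalROI, grid: np.ndarray) -> SphericalROI:
    """Reverse the x-coordinate of the center and every member voxel.

    Members map onto the grid voxels at the mirrored coordinates; on an
    x-symmetric grid this is an involution preserving cardinality.
    """
    lookup = {tuple(np.round(c, 6)): i for i, c in enumerate(grid)}
    members = []
    for i in roi.voxel_indices:
        c = grid[i] * np.array([-1.0, 1.0, 1.0])
        j = lookup.get(tuple(np.round(c, 6)))
        if j is not None:
            members.append(j)
    if not members:
        raise AlignmentError("mirrored ROI has no grid voxels")
    center = roi.center * np.array([-1.0, 1.0, 1.0])
    return SphericalROI(center=center, radius_mm=roi.radius_mm,
                        voxel_indices=np.sort(np.array(members)))


def roi_mean_density(m: CurrentDensityMap, roi: SphericalROI) -> float:
    """Arithmetic mean of the (log-transformed, normalized) map over the
    ROI's member voxels."""
    if m.values.shape[0] != m.grid.shape[0]:
        raise AlignmentError("map values and grid are inconsistent")
    if roi.voxel_indices.max() >= m.grid.shape[0]:
        raise AlignmentError("ROI indices outside the map's grid")
    return float(np.mean(m.values[roi.voxel_indices]))


# ---------------------------------------------------------------------------
# Meng's test for dependent correlations


@dataclass(frozen=True)
class MengResult:
    r1: float
    r2: float
    r12: float
    n: int
    z: float
    p_one_sided: float
    p_two_sided: float


def meng_dependent_correlation_test(
    r1: float, r2: float, r12: float, n: int
) -> MengResult:
    """Meng-Rosenthal-Rubin Z-test comparing two correlations that share
    one variable.

    z_i = atanh(r_i); r̄² = (r1²+r2²)/2; f = min(1, (1−r12)/(2(1−r̄²)));
    h = (1 − f·r̄²)/(1 − r̄²); Z = (z1−z2)·√((n−3)/(2(1−r12)·h)).  The
    one-sided p is the upper normal tail of Z; the two-sided p doubles it.
    """
    if abs(r1) >= 1.0 or abs(r2) >= 1.0:
        raise DegenerateInputError("|r| = 1 gives an infinite Fisher z")
    if abs(r12) > 1.0:
        raise ConfigurationError("|r12| must be <= 1")
    if n < 4:
        raise ConfigurationError("n must be >= 4")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    rbar2 = (r1**2 + r2**2) / 2.0
    f = min(1.0, (1.0 - r12) / (2.0 * (1.0 - rbar2)))
    h = (1.0 - f * rbar2) / (1.0 - rbar2)
    z = float((z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - r12) * h)))
    p_one = float(sps.norm.sf(z))
    return MengResult(r1=float(r1), r2=float(r2), r12=float(r12), n=int(n),
                      z=z, p_one_sided=p_one,
                      p_two_sided=float(min(1.0, 2.0 * sps.norm.sf(abs(z)))))


# ---------------------------------------------------------------------------
# Per-cycle analyses


@dataclass(frozen=True)
class CycleCorrelation:
    cycle: str
    n: int
    r: float
    p: float
    df: int
    r_squared: float


def per_cycle_analysis(
    cycle_maps: list,
    behavior,
    cycle_durations: list,
    roi: SphericalROI,
    max_cycles: int = 4,
    min_subjects: int = 4,
) -> list[CycleCorrelation]:
    """ROI partial correlations repeated for each sleep cycle.

    ``cycle_maps[i]`` is subject i's list of raw (pre-normalization)
    CurrentDensityMaps, one per detected cycle; ``cycle_durations[i]`` the
    matching durations in minutes.  For each of the first ``max_cycles``
    cycles, subjects lacking that cycle are excluded listwise; the cycle's
    maps are normalized and log-transformed, averaged over the ROI, and
    partially correlated with behavior controlling that cycle's duration.
    A pooled cycles-2..max analysis (summed raw maps, summed duration) is
    appended with cycle label "2-4".
    """
    from .inverse import normalize_log_map

    behavior = np.asarray(behavior, float)
    n_subj = len(cycle_maps)
    if behavior.size != n_subj or len(cycle_durations) != n_subj:
        raise AlignmentError("cycle maps, durations and behavior disagree in length")
    out: list[CycleCorrelation] = []
    for c in range(max_cycles):
        have = [i for i in range(n_subj) if len(cycle_maps[i]) > c]
        if len(have) < min_subjects:
            warnings.warn(f"cycle {c + 1}: only {len(have)} subjects; skipped",
                          stacklevel=2)
            continue
        vals = np.array([
            roi_mean_density(normalize_log_map(cycle_maps[i][c]), roi) for i in have
        ])
        dur = np.array([cycle_durations[i][c] for i in have])
        r, p, df = partial_correlation(vals, behavior[have], covariates=dur)
        out.append(CycleCorrelation(cycle=str(c + 1), n=len(have), r=r, p=p,
                                    df=df, r_squared=r**2))
    # pooled cycles 2..max_cycles
    have = [i for i in range(n_subj) if len(cycle_maps[i]) >= max_cycles]
    if len(have) >= min_subjects:
        vals, dur = [], []
        for i in have:
            pooled = cycle_maps[i][1]
            summed = pooled.values.copy()
            for c in range(2, max_cycles):
                summed = summed + cycle_maps[i][c].values
            pooled = CurrentDensityMap(values=summed, grid=pooled.grid,
                                       band=pooled.band)
            vals.append(roi_mean_density(normalize_log_map(pooled), roi))
            dur.append(float(np.sum(cycle_durations[i][1:max_cycles])))
        r, p, df = partial_correlation(np.array(vals), behavior[have],
                                       covariates=np.array(dur))
        out.append(CycleCorrelation(cycle=f"2-{max_cycles}", n=len(have), r=r,
                                    p=p, df=df, r_squared=r**2))
    else:
        warnings.warn("pooled cycles analysis skipped: too few subjects with "
                      f"{max_cycles} cycles", stacklevel=2)
    return out
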