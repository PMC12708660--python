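"""Standardized minimum-norm (sLORETA-style) source estimation.

The inverse is the Tikhonov-regularized minimum-norm operator
``T = Kᵀ (K Kᵀ + αH)⁺`` built on average-referenced gains, with
``H = I − 11ᵀ/n`` the average-reference operator and
``α = trace(K Kᵀ)/(n_electrodes · snr²)`` — the standard mapping of an
assumed signal-to-noise ratio onto the regularization weight.  Voxel
estimates are standardized by the 3×3 diagonal blocks of the resolution
matrix ``T K``, which gives zero localization error for noiseless single
dipoles.  Band power is localized from the scalp cross-spectral matrix and
summarized per voxel as the trace of the standardized 3×3 block; maps are
then normalized to a total current density of one and log-transformed
(base 10) for statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    AlignmentError,
    InputIntegrityError,
    NormalizationError,
    NumericalConditioningError,
)
from .headmodel import LeadField


@dataclass(frozen=True)
class InverseOperator:
    transform: np.ndarray       # (n_voxels*3, n_electrodes)
    block_inverses: np.ndarray  # (n_voxels, 3, 3) standardization divisors
    alpha: float
    snr: float
    lead_field: LeadField

    @property
    def n_voxels(self) -> int:
        return self.block_inverses.shape[0]

    @property
    def transform3(self) -> np.ndarray:
        return self.transform.reshape(self.n_voxels, 3, -1)


@dataclass(frozen=True)
class CurrentDensityMap:
    """Per-voxel SWA current-density power, optionally relative and/or log."""

    values: np.ndarray
    grid: np.ndarray
    normalized: bool = False
    log_transformed: bool = False
    band: tuple = (0.8, 4.6)
    n_epochs_used: int | None = None


def build_inverse_operator(lf: LeadField, snr: float = 10.0) -> InverseOperator:
    """Build the standardized inverse for a lead field.

    Requires an average-reference-projected lead field and ``snr > 0``.
    """
    if snr <= 0:
        raise NumericalConditioningError("snr must be positive")
    K = lf.gain
    if not lf.average_referenced:
        K = K - K.mean(axis=0, keepdims=True)
    n_e = K.shape[0]
    H = np.eye(n_e) - np.ones((n_e, n_e)) / n_e
    KKt = K @ K.T
    alpha = float(np.trace(KKt) / (n_e * snr**2))
    try:
        M = np.linalg.pinv(KKt + alpha * H, hermitian=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological input
        raise NumericalConditioningError(str(exc)) from exc
    if not np.all(np.isfinite(M)):
        raise NumericalConditioningError("inverse operator contains non-finite values")
    T = K.T @ M
    n_vox = lf.n_voxels
    T3 = T.reshape(n_vox, 3, n_e)
    K3 = K.reshape(n_e, n_vox, 3)
    # resolution-matrix diagonal blocks S_v = (T K)_{vv}
    S = np.einsum("vae,evb->vab", T3, K3)
    Sinv = np.stack([np.linalg.pinv(S[v], hermitian=True) for v in range(n_vox)])
    return InverseOperator(transform=T, block_inverses=Sinv, alpha=alpha,
                           snr=float(snr), lead_field=lf)


def standardized_map(inv: InverseOperator, scalp: np.ndarray) -> np.ndarray:
    """sLORETA standardized power per voxel for one scalp sample/topography:
    ``ĵ_vᵀ S_v⁻¹ ĵ_v`` with ``ĵ_v = T_v φ``."""
    phi = np.asarray(scalp, float)
    if phi.shape != (inv.transform.shape[1],):
        raise AlignmentError("scalp vector does not match the operator")
    j = inv.transform3 @ phi           # (V, 3)
    return np.einsum("va,vab,vb->v", j, inv.block_inverses, j)


def localize_band_power(
    C: np.ndarray,
    inv: InverseOperator,
    n_epochs_used: int | None = None,
    psd_tol: float = 1e-6,
) -> CurrentDensityMap:
    """Standardized band current-density power from a scalp cross-spectrum.

    Voxel value = trace(S_v⁻¹ · T_v C T_vᵀ) ≥ 0.  ``C`` must be symmetric
    positive semidefinite up to ``psd_tol`` (relative to its largest
    eigenvalue).
    """
    C = np.asarray(C, float)
    n_e = inv.transform.shape[1]
    if C.shape != (n_e, n_e):
        raise AlignmentError("cross-spectrum does not match the operator")
    if not np.allclose(C, C.T, atol=1e-8 * max(np.abs(C).max(), 1.0)):
        raise InputIntegrityError("cross-spectrum is not symmetric")
    w = np.linalg.eigvalsh(C)
    if w.min() < -psd_tol * max(w.max(), 1e-30):
        raise InputIntegrityError("cross-spectrum is not positive semidefinite")
    T3 = inv.transform3
    B = np.einsum("vae,ef,vbf->vab", T3, C, T3)
    values = np.einsum("vab,vba->v", inv.block_inverses, B)
    values = np.maximum(values, 0.0)
    return CurrentDensityMap(values=values, grid=inv.lead_field.voxel_grid,
                             normalized=False, log_transformed=False,
                             n_epochs_used=n_epochs_used)


def normalize_log_map(
    m: CurrentDensityMap, log: bool = True, floor: float = 1e-12
) -> CurrentDensityMap:
    """Normalize to a total current density of one, then (optionally)
    log10-transform with a floor applied before the log."""
    if m.log_transformed:
        raise NormalizationError("map is already log-transformed")
    values = np.asarray(m.values, float)
    if np.any(values < 0):
        raise NormalizationError("map has negative values")
    total = values.sum()
    if total <= 0:
        raise NormalizationError("all-zero map cannot be normalized")
    rel = values / total
    if not log:
        return replace(m, values=rel, normalized=True)
    return replace(m, values=np.log10(np.maximum(rel, floor)),
                   normalized=True, log_transformed=True)
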