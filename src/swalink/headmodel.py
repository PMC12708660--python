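"""Analytic single-sphere EEG forward model and lead fields.

The head is a homogeneous conducting sphere; the surface potential of a
current dipole inside it has a closed form obtained by summing the classical
Legendre expansion.  With the dipole at distance ``f`` from the center,
eccentricity ``a = f/R``, electrode direction ``ê``, dipole-position
direction ``b̂``, ``x = ê·b̂`` and ``g = |ê − a·b̂|``::

    V = (4πσR²)⁻¹ · [ (q·b̂)·S1 + q·(ê − x·b̂)·T ]
    S1 = 2(x − a)/g³ + (1/g − 1)/a            (S1 → 3x as a → 0)
    T  = 2/g³ + (g + 1) / (g·(1 − a·x + g))

Both sums follow from the generating function of the Legendre polynomials;
the tangential factor uses ``t̂·sinγ = ê − x·b̂`` so no division by ``sinγ``
is needed.  The solution space is a regular, mirror-symmetric voxel lattice
strictly inside the electrode sphere, with one free dipole per voxel
(three gain columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

#: default tissue conductivity, S/m
DEFAULT_CONDUCTIVITY = 0.33

#: default radius of the spherical phantom head, mm
DEFAULT_HEAD_RADIUS_MM = 40.0

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class LeadField:
    """Average-reference-projected forward gains for a voxel lattice.

    ``gain`` maps a stacked dipole-moment vector (voxel-major x,y,z order,
    nA·m) to electrode potentials in µV.
    """

    gain: np.ndarray                 # (n_electrodes, n_voxels * 3)
    electrode_positions: np.ndarray  # (n_electrodes, 3), mm
    voxel_grid: np.ndarray           # (n_voxels, 3), mm
    spacing_mm: float
    head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM
    average_referenced: bool = True
    conductivity: float = field(default=DEFAULT_CONDUCTIVITY, repr=False)

    @property
    def n_electrodes(self) -> int:
        return self.gain.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.voxel_grid.shape[0]

    @property
    def gain3(self) -> np.ndarray:
        """Gains reshaped to (n_electrodes, n_voxels, 3)."""
        return self.gain.reshape(self.n_electrodes, self.n_voxels, 3)


def electrode_cap_positions(
    n_electrodes: int = 59,
    head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM,
    max_polar_deg: float = 120.0,
) -> np.ndarray:
    """Quasi-uniform Fibonacci layout on a spherical cap, in mm.

    Deterministic; mimics a high-density EEG cap covering the scalp down to
    ``max_polar_deg`` from the vertex.
    """
    if n_electrodes < 4:
        raise ConfigurationError("need at least 4 electrodes for a cap layout")
    i = np.arange(n_electrodes)
    cos_max = np.cos(np.deg2rad(max_polar_deg))
    cos_theta = 1.0 - (1.0 - cos_max) * (i + 0.5) / n_electrodes
    sin_theta = np.sqrt(1.0 - cos_theta**2)
    phi = i * _GOLDEN_ANGLE
    pos = np.column_stack(
        [sin_theta * np.cos(phi), sin_theta * np.sin(phi), cos_theta]
    )
    return head_radius_mm * pos


def voxel_lattice(n_voxels_per_axis: int = 6, spacing_mm: float = 5.0) -> np.ndarray:
    """Regular isotropic lattice centered at the origin, in mm.

    Mirror-symmetric about x = 0 by construction (coordinates are odd
    multiples of ``spacing/2`` for even axis counts), so laterality
    mirroring maps grid voxels onto grid voxels exactly.
    """
    if n_voxels_per_axis < 1:
        raise ConfigurationError("n_voxels_per_axis must be >= 1")
    c = (np.arange(n_voxels_per_axis) - (n_voxels_per_axis - 1) / 2.0) * spacing_mm
    xx, yy, zz = np.meshgrid(c, c, c, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])


def sphere_scalp_gain(
    electrode_positions: np.ndarray,
    dipole_positions: np.ndarray,
    head_radius_mm: float,
    conductivity: float = DEFAULT_CONDUCTIVITY,
) -> np.ndarray:
    """Closed-form surface potentials of unit dipoles in a homogeneous sphere.

    Returns gains of shape (n_electrodes, n_dipoles, 3) in µV per nA·m for
    dipoles oriented along x, y, z.  Electrodes must lie on the sphere
    surface; dipoles strictly inside it.
    """
    R = head_radius_mm * 1e-3
    e = np.asarray(electrode_positions, float) * 1e-3
    b = np.asarray(dipole_positions, float) * 1e-3
    if not np.allclose(np.linalg.norm(e, axis=1), R, rtol=1e-6):
        raise ConfigurationError("electrodes must lie on the head sphere surface")
    f = np.linalg.norm(b, axis=1)
    if np.any(f >= R * (1.0 - 1e-9)):
        raise ConfigurationError("dipole (voxel) outside or on the head sphere")

    a = f / R  # (P,)
    # safe unit vector for the (exactly solvable) central-dipole limit
    b_hat = np.where(f[:, None] > 1e-12 * R, b / np.maximum(f, 1e-300)[:, None], [0.0, 0.0, 1.0])
    e_hat = e / R

    x = e_hat @ b_hat.T                       # (E, P)
    g = np.sqrt(np.maximum(1.0 - 2.0 * a * x + a**2, 1e-300))
    with np.errstate(divide="ignore", invalid="ignore"):
        s1 = 2.0 * (x - a) / g**3 + np.where(a > 1e-12, (1.0 / g - 1.0) / np.maximum(a, 1e-300), x)
    # (1/g - 1)/a → x as a → 0, handled by the `where` above
    t = 2.0 / g**3 + (g + 1.0) / (g * (1.0 - a * x + g))

    scale = 1.0 / (4.0 * np.pi * conductivity * R**2)
    # V = scale * [ (q·b̂) S1 + q·(ê − x b̂) T ]  → gain per Cartesian moment
    gain = scale * (
        s1[:, :, None] * b_hat[None, :, :]
        + t[:, :, None] * (e_hat[:, None, :] - x[:, :, None] * b_hat[None, :, :])
    )
    # V per A·m → µV per nA·m
    return gain * 1e-3


def generate_lead_field(
    n_electrodes: int = 59,
    n_voxels_per_axis: int = 6,
    spacing_mm: float = 5.0,
    head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM,
    conductivity: float = DEFAULT_CONDUCTIVITY,
    average_reference: bool = True,
) -> LeadField:
    """Build the analytic spherical lead field for a centered voxel lattice.

    Deterministic given its arguments.  Raises :class:`ConfigurationError`
    when the lattice does not fit strictly inside the electrode sphere or
    fewer than 16 electrodes are requested.
    """
    if n_electrodes < 16:
        raise ConfigurationError("n_electrodes must be >= 16")
    grid = voxel_lattice(n_voxels_per_axis, spacing_mm)
    if np.linalg.norm(grid, axis=1).max() >= head_radius_mm:
        raise ConfigurationError(
            "voxel lattice does not fit strictly inside the head sphere; "
            "reduce n_voxels_per_axis/spacing or enlarge head_radius_mm"
        )
    elec = electrode_cap_positions(n_electrodes, head_radius_mm)
    gain3 = sphere_scalp_gain(elec, grid, head_radius_mm, conductivity)
    gain = gain3.reshape(n_electrodes, -1)
    if average_reference:
        gain = gain - gain.mean(axis=0, keepdims=True)
    return LeadField(
        gain=gain,
        electrode_positions=elec,
        voxel_grid=grid,
        spacing_mm=float(spacing_mm),
        head_radius_mm=float(head_radius_mm),
        average_referenced=average_reference,
        conductivity=conductivity,
    )
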