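"""Analytic magnetic field models and their projection onto channels.

Implements the four source/field families the toolkit needs:

* uniform reference fields,
* the five independent first-order gradients, completed to symmetric
  traceless tensors (so simulated "coil" fields are Maxwell-consistent in a
  source-free region),
* the free-space point magnetic dipole (the phantom's spiral coils),
* the tangential current dipole in a homogeneous conducting sphere (Sarvas
  closed form), used as the physical lead field for sensitivity analyses.

All quantities are SI (tesla, metres, A·m² / A·m).  mu0/4pi is fixed at
exactly 1e-7 T·m/A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import as_vector3
from .errors import DegenerateGeometryError, InvalidArgumentError

MU0_OVER_4PI = 1.0e-7  # T·m/A, exact by convention here
R_MIN = 0.005  # m, guard radius around point sources

#: gradient coefficient ordering: dBx/dx, dBx/dy, dBx/dz, dBz/dz, dBy/dz
GRADIENT_ORDER = ("dBx/dx", "dBx/dy", "dBx/dz", "dBz/dz", "dBy/dz")


def gradient_tensor(coeffs5) -> np.ndarray:
    """Complete 5 driven gradient coefficients to a symmetric traceless tensor.

    The five independent components fix Gxx, Gxy, Gxz, Gzz, Gyz; symmetry and
    zero trace (Gyy = -(Gxx + Gzz)) supply the rest, so that B(r) = G·r is
    both divergence- and curl-free.
    """
    c = np.asarray(coeffs5, dtype=float)
    if c.shape != (5,) or not np.all(np.isfinite(c)):
        raise InvalidArgumentError("coeffs5 must be a finite 5-vector")
    gxx, gxy, gxz, gzz, gyz = c
    return np.array(
        [
            [gxx, gxy, gxz],
            [gxy, -(gxx + gzz), gyz],
            [gxz, gyz, gzz],
        ]
    )


def gradient_basis_tensors(amplitude: float = 1.0) -> np.ndarray:
    """The 5 unit gradient patterns as (5,3,3) tensors, scaled by amplitude."""
    out = np.empty((5, 3, 3))
    for k in range(5):
        e = np.zeros(5)
        e[k] = amplitude
        out[k] = gradient_tensor(e)
    return out


@dataclass(frozen=True)
class UniformField:
    """A spatially uniform field with the given vector amplitude (tesla)."""

    amplitude_vector: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "amplitude_vector",
                           as_vector3(self.amplitude_vector, "amplitude_vector"))

    def at(self, position) -> np.ndarray:
        return np.broadcast_to(self.amplitude_vector,
                               np.asarray(position, dtype=float).shape).copy()


@dataclass(frozen=True)
class GradientField:
    """A linear field B(r) = G·r defined by 5 gradient coefficients (T/m)."""

    coeffs5: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.coeffs5, dtype=float)
        if c.shape != (5,):
            raise InvalidArgumentError("coeffs5 must have shape (5,)")
        object.__setattr__(self, "coeffs5", c)

    @property
    def tensor(self) -> np.ndarray:
        return gradient_tensor(self.coeffs5)

    def at(self, position) -> np.ndarray:
        return np.asarray(position, dtype=float) @ self.tensor.T


def evaluate_coil_field(uniform: UniformField, gradient: GradientField, position) -> np.ndarray:
    """Field of a combined uniform + gradient pattern at ``position``."""
    p = np.asarray(position, dtype=float)
    return uniform.amplitude_vector + p @ gradient.tensor.T


@dataclass(frozen=True)
class MagneticDipole:
    """Point magnetic dipole: position (m) and moment (A·m²)."""

    position: np.ndarray
    moment: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "position", as_vector3(self.position, "position"))
        object.__setattr__(self, "moment", as_vector3(self.moment, "moment"))


@dataclass(frozen=True)
class CurrentDipole:
    """Tangential current dipole inside a homogeneous conducting sphere."""

    position: np.ndarray
    moment: np.ndarray  # A·m
    sphere_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "position", as_vector3(self.position, "position"))
        object.__setattr__(self, "moment", as_vector3(self.moment, "moment"))
        object.__setattr__(self, "sphere_origin",
                           as_vector3(self.sphere_origin, "sphere_origin"))


def magnetic_dipole_field(dipole: MagneticDipole, r_obs, r_min: float = R_MIN) -> np.ndarray:
    """Free-space field of a point magnetic dipole at observer(s) ``r_obs``.

    B = (mu0/4pi) (3 (m·r̂) r̂ − m) / |r|³ with r the source→observer vector.
    Raises :class:`DegenerateGeometryError` if any observer is within
    ``r_min`` of the source.
    """
    obs = np.atleast_2d(np.asarray(r_obs, dtype=float))
    r = obs - dipole.position
    dist = np.linalg.norm(r, axis=1)
    if np.any(dist < r_min):
        raise DegenerateGeometryError(
            f"observer within {r_min * 1e3:.1f} mm of the dipole"
        )
    rhat = r / dist[:, None]
    mdot = rhat @ dipole.moment
    B = MU0_OVER_4PI * (3.0 * mdot[:, None] * rhat - dipole.moment) / dist[:, None] ** 3
    return B[0] if np.asarray(r_obs).ndim == 1 else B


def current_dipole_field_sphere(dipole: CurrentDipole, r_obs, r_min: float = R_MIN) -> np.ndarray:
    """External field of a current dipole in a homogeneous conducting sphere.

    Sarvas closed form.  The field is exactly zero for a radial dipole (silent
    source) and for a dipole at the sphere origin.  Observers must lie
    strictly outside the source radius.
    """
    obs = np.atleast_2d(np.asarray(r_obs, dtype=float))
    r = obs - dipole.sphere_origin
    r0 = dipole.position - dipole.sphere_origin
    q = dipole.moment

    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    if np.any(a < r_min):
        raise DegenerateGeometryError("observer within the guard radius of the dipole")
    rn = np.linalg.norm(r, axis=1)
    if np.any(rn <= np.linalg.norm(r0) - 1e-12):
        raise DegenerateGeometryError("observer inside the source radius")

    q_x_r0 = np.cross(q, r0)
    if np.linalg.norm(q_x_r0) == 0.0:
        # radial dipole or dipole at origin: magnetically silent outside
        B = np.zeros_like(obs)
        return B[0] if np.asarray(r_obs).ndim == 1 else B

    adotr = np.einsum("ij,ij->i", a_vec, r)
    F = a * (rn * a + rn**2 - (r @ r0))
    gradF = (
        (a**2 / rn + adotr / a + 2.0 * a + 2.0 * rn)[:, None] * r
        - (a + 2.0 * rn + adotr / a)[:, None] * r0
    )
    B = MU0_OVER_4PI / F[:, None] ** 2 * (
        F[:, None] * q_x_r0 - (r @ q_x_r0)[:, None] * gradF
    )
    return B[0] if np.asarray(r_obs).ndim == 1 else B


def channel_signal(B, orientation, gain: float) -> float | np.ndarray:
    """Project a field vector onto a channel: signal = gain · (u · B)."""
    u = np.asarray(orientation, dtype=float)
    if abs(np.linalg.norm(u) - 1.0) > 1e-9:
        raise InvalidArgumentError("orientation must be a unit vector")
    return gain * (np.asarray(B, dtype=float) @ u)


def _resolve_geometry(geometry) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Accept a SensorArray, calibration results, or (pos, ori, gain) triple."""
    if hasattr(geometry, "channel_matrices"):
        return geometry.channel_matrices()
    positions, orientations, gains = geometry
    return (np.asarray(positions, dtype=float),
            np.asarray(orientations, dtype=float),
            np.asarray(gains, dtype=float))


def source_field(source, positions: np.ndarray) -> np.ndarray:
    """Field of a magnetic or current dipole at an (N,3) block of positions."""
    if isinstance(source, MagneticDipole):
        return magnetic_dipole_field(source, positions)
    if isinstance(source, CurrentDipole):
        return current_dipole_field_sphere(source, positions)
    raise InvalidArgumentError(f"unsupported source type {type(source).__name__}")


def lead_field(source, geometry) -> np.ndarray:
    """Per-channel forward signal vector l (N,) for a unit-defined source.

    Element i is the source field at channel i's position projected onto its
    orientation and scaled by its gain.
    """
    positions, orientations, gains = _resolve_geometry(geometry)
    B = source_field(source, positions)
    return gains * np.einsum("ij,ij->i", B, orientations)
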