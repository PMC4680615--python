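"""Resistance functions of a prolate spheroid.

A tethered cell is modelled as a rigid prolate spheroid with semi-major
axis ``a`` and semi-minor axis ``b``.  In Stokes flow the drag force and
torque on the spheroid are anisotropic.  We use the classical closed-form
resistance functions (Oberbeck 1876; Perrin 1934), normalized by the
*semi-major* axis:

    F = 6 pi mu a * alpha * U       (translation)
    T = 8 pi mu a^3 * beta * omega  (rotation)

so that every coefficient tends to 1 in the sphere limit.  With
eccentricity ``e = sqrt(1 - (b/a)^2)`` and ``L = ln((1+e)/(1-e))``:

    alpha_par  = (8/3)  e^3            / (-2e + (1+e^2) L)
    alpha_perp = (16/3) e^3            / ( 2e + (3e^2-1) L)
    beta_par   = (4/3)  e^3 (1-e^2)    / ( 2e - (1-e^2) L)
    beta_perp  = (4/3)  e^3 (2-e^2)    / (-2e + (1+e^2) L)

"par"/"perp" are relative to the symmetry (long) axis.  The shape factor

    Gamma = (a^2 - b^2) / (a^2 + b^2)

controls how the ambient rate of strain rotates the spheroid (Gamma = 0
for a sphere, -> 1 for a needle).

The orientation-dependent drag tensors are built from a unit orientation
vector ``d`` as ``A = alpha_par d d + alpha_perp (I - d d)`` and
similarly ``B`` from the betas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CellGeometry",
    "DragCoefficients",
    "eccentricity",
    "translational_coefficients",
    "rotational_coefficients",
    "shape_factor",
    "drag_tensor",
]

# Below this eccentricity the closed forms suffer catastrophic
# cancellation (absolute error ~1e-16/e^2); switch to their Taylor
# series, whose truncation error O(e^8) is below 1e-16 there.
_SERIES_ECCENTRICITY = 1e-2


@dataclass(frozen=True)
class CellGeometry:
    """Prolate spheroid cell body: semi-axes in micrometres, a >= b > 0."""

    semi_major_um: float
    semi_minor_um: float

    def __post_init__(self) -> None:
        if not (self.semi_minor_um > 0):
            raise ValueError("semi-minor axis must be positive")
        if self.semi_major_um < self.semi_minor_um:
            raise ValueError(
                "oblate geometry (a < b) is not supported; need a >= b"
            )

    @property
    def aspect_ratio(self) -> float:
        return self.semi_major_um / self.semi_minor_um

    @classmethod
    def from_aspect_ratio(
        cls, aspect_ratio: float, semi_major_um: float = 1.0
    ) -> "CellGeometry":
        if aspect_ratio < 1:
            raise ValueError("aspect ratio must be >= 1 (prolate)")
        return cls(semi_major_um, semi_major_um / aspect_ratio)


@dataclass(frozen=True)
class DragCoefficients:
    """Dimensionless resistance scalars of a prolate spheroid."""

    alpha_par: float
    alpha_perp: float
    beta_par: float
    beta_perp: float
    gamma: float

    @classmethod
    def from_geometry(cls, geom: CellGeometry) -> "DragCoefficients":
        a_par, a_perp = translational_coefficients(geom)
        b_par, b_perp = rotational_coefficients(geom)
        return cls(a_par, a_perp, b_par, b_perp, shape_factor(geom))


def eccentricity(geom: CellGeometry) -> float:
    """Meridional eccentricity e = sqrt(1 - (b/a)^2), in [0, 1)."""
    ratio = geom.semi_minor_um / geom.semi_major_um
    return float(np.sqrt(max(0.0, 1.0 - ratio * ratio)))


def translational_coefficients(geom: CellGeometry) -> tuple[float, float]:
    """(alpha_par, alpha_perp): drag force = 6 pi mu a alpha U."""
    e = eccentricity(geom)
    if e < _SERIES_ECCENTRICITY:
        e2 = e * e
        a_par = 1.0 - e2 * (2.0 / 5.0 + e2 * (17.0 / 175.0 + e2 * 128.0 / 2625.0))
        a_perp = 1.0 - e2 * (3.0 / 10.0 + e2 * (57.0 / 700.0 + e2 * 907.0 / 21000.0))
        return a_par, a_perp
    L = np.log((1 + e) / (1 - e))
    a_par = (8.0 / 3.0) * e**3 / (-2 * e + (1 + e * e) * L)
    a_perp = (16.0 / 3.0) * e**3 / (2 * e + (3 * e * e - 1) * L)
    return float(a_par), float(a_perp)


def rotational_coefficients(geom: CellGeometry) -> tuple[float, float]:
    """(beta_par, beta_perp): drag torque = 8 pi mu a^3 beta omega."""
    e = eccentricity(geom)
    if e < _SERIES_ECCENTRICITY:
        e2 = e * e
        b_par = 1.0 - e2 * (6.0 / 5.0 - e2 * (27.0 / 175.0 + e2 * 64.0 / 2625.0))
        b_perp = 1.0 - e2 * (9.0 / 10.0 - e2 * (18.0 / 175.0 - e2 / 5250.0))
        return b_par, b_perp
    L = np.log((1 + e) / (1 - e))
    b_par = (4.0 / 3.0) * e**3 * (1 - e * e) / (2 * e - (1 - e * e) * L)
    b_perp = (4.0 / 3.0) * e**3 * (2 - e * e) / (-2 * e + (1 + e * e) * L)
    return float(b_par), float(b_perp)


def shape_factor(geom: CellGeometry) -> float:
    """Gamma = (a^2 - b^2)/(a^2 + b^2), in [0, 1) for a prolate body."""
    a2 = geom.semi_major_um**2
    b2 = geom.semi_minor_um**2
    return float((a2 - b2) / (a2 + b2))


def drag_tensor(
    orientation: np.ndarray, scalar_par: float, scalar_perp: float
) -> np.ndarray:
    """Uniaxial tensor  s_par d d + s_perp (I - d d)  for unit vector d.

    Its eigenvalues are {s_par, s_perp, s_perp} with d the s_par
    eigenvector; used for both the translation tensor A and the rotation
    tensor B.
    """
    d = np.asarray(orientation, dtype=float)
    if d.shape != (3,):
        raise ValueError("orientation must be a 3-vector")
    if abs(np.linalg.norm(d) - 1.0) > 1e-9:
        raise ValueError("orientation must be a unit vector (within 1e-9)")
    dd = np.outer(d, d)
    return scalar_perp * np.eye(3) + (scalar_par - scalar_perp) * dd
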