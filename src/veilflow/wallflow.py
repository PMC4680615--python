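"""Stokeslet flow near a no-slip wall and derived ambient-flow quantities.

A tethered cell pumping fluid is modelled as a point force (stokeslet) in
Stokes flow above a rigid no-slip plane at z = 0, the fluid occupying
z > 0.  The wall's back-flow is represented by an image system beneath
the plane:

``leading``
    only the sign-reversed stokeslet at the mirror point (the "image
    cell").  This is the leading-order far-field approximation and the
    default used by the tether dynamics.
``blake``
    the full image system of Blake (1971): mirror stokeslet plus a
    stokeslet doublet and a source doublet, which cancels the velocity
    on z = 0 exactly.

Units: lengths in micrometres, time in seconds, forces in piconewtons,
viscosity in Pa s.  This unit system is self-consistent for Stokes flow
(1 pN / (Pa s * um) = 1 um/s), so no conversion factors appear in the
formulas.  Oxygen diffusivity is stored in cm^2/s, the unit in which it
is usually quoted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FluidProperties",
    "PointForce",
    "AmbientFlow",
    "stokeslet",
    "image_system",
    "total_velocity",
    "velocity_gradient",
    "ambient_at",
    "decay_exponent",
    "advect_tracers",
]

CM2_TO_UM2 = 1e8  # cm^2 -> um^2


@dataclass(frozen=True)
class FluidProperties:
    """Viscosity (Pa s) and solute diffusivity (cm^2/s) of the medium.

    Defaults are water and a small solute such as oxygen.
    """

    viscosity_pa_s: float = 1e-3
    diffusivity_cm2_s: float = 1e-5

    def __post_init__(self) -> None:
        if self.viscosity_pa_s <= 0 or self.diffusivity_cm2_s <= 0:
            raise ValueError("viscosity and diffusivity must be positive")

    @property
    def diffusivity_um2_s(self) -> float:
        return self.diffusivity_cm2_s * CM2_TO_UM2


WATER = FluidProperties()


@dataclass(frozen=True)
class PointForce:
    """Point force (pN) applied to the fluid at a position (um) above the wall."""

    position_um: np.ndarray
    force_pn: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "position_um", np.asarray(self.position_um, dtype=float)
        )
        object.__setattr__(self, "force_pn", np.asarray(self.force_pn, dtype=float))
        if self.position_um.shape != (3,) or self.force_pn.shape != (3,):
            raise ValueError("position and force must be 3-vectors")
        if self.position_um[2] <= 0:
            raise ValueError("point force must sit above the wall (z > 0)")

    @property
    def height_um(self) -> float:
        return float(self.position_um[2])


@dataclass(frozen=True)
class AmbientFlow:
    """Local flow experienced by a cell: velocity u (um/s), angular
    velocity Omega = curl(u)/2 (1/s) and rate of strain E (1/s)."""

    velocity: np.ndarray
    angular_velocity: np.ndarray
    rate_of_strain: np.ndarray

    def __post_init__(self) -> None:
        if abs(np.trace(self.rate_of_strain)) > 1e-9 * (
            1.0 + np.abs(self.rate_of_strain).max()
        ):
            raise ValueError("rate of strain must be traceless (incompressibility)")


# ---------------------------------------------------------------------------
# elementary singularities (work with complex coordinates so that
# machine-precision complex-step differentiation is available)

def _oseen_velocity(force, r, mu):
    """Oseen tensor velocity of a stokeslet: u = (F + (F.r) r / |r|^2) / (8 pi mu |r|)."""
    d = np.sqrt(r[0] ** 2 + r[1] ** 2 + r[2] ** 2)
    fr = force[0] * r[0] + force[1] * r[1] + force[2] * r[2]
    return (force + fr * r / d**2) / (8.0 * np.pi * mu * d)


def _oseen_gradient(force, r, mu):
    """Analytic gradient d u_i / d x_l of the Oseen velocity."""
    d = np.linalg.norm(r)
    eye = np.eye(3)
    fr = force @ r
    g = (
        -np.outer(force, r) / d**3
        + np.outer(r, force) / d**3
        + fr * eye / d**3
        - 3.0 * fr * np.outer(r, r) / d**5
    )
    return g / (8.0 * np.pi * mu)


def _blake_correction(force, x, source, mu):
    """Blake's higher-order image corrections (stokeslet doublet + source
    doublet), evaluated at x for a stokeslet at ``source``.

    With R = x - x* (x* the mirror point at height -h) and the mirror
    signature M = (1, 1, -1):

        u_i = (2 h / 8 pi mu) * F_k M_k d/dR_k [ h R_i/R^3
                - (delta_i3 / R + R_i R_3 / R^3) ]
    """
    h = source[2]
    R = np.array(
        [x[0] - source[0], x[1] - source[1], x[2] + h], dtype=np.result_type(x, 1.0)
    )
    d = np.sqrt(R[0] ** 2 + R[1] ** 2 + R[2] ** 2)
    sign = np.array([1.0, 1.0, -1.0])
    u = np.zeros(3, dtype=R.dtype)
    for i in range(3):
        acc = 0.0
        for k in range(3):
            dik = 1.0 if i == k else 0.0
            d3k = 1.0 if k == 2 else 0.0
            di3 = 1.0 if i == 2 else 0.0
            term = h * (dik / d**3 - 3.0 * R[i] * R[k] / d**5)
            term += di3 * R[k] / d**3
            term -= (dik * R[2] + d3k * R[i]) / d**3 - 3.0 * R[i] * R[2] * R[k] / d**5
            acc = acc + force[k] * sign[k] * term
        u[i] = 2.0 * h * acc / (8.0 * np.pi * mu)
    return u


# ---------------------------------------------------------------------------

def stokeslet(
    force: PointForce, eval_point: np.ndarray, fluid: FluidProperties = WATER
) -> np.ndarray:
    """Unbounded-fluid stokeslet velocity (um/s) at ``eval_point``."""
    x = np.asarray(eval_point, dtype=float)
    r = x - force.position_um
    if np.linalg.norm(r) == 0.0:
        raise ValueError("cannot evaluate the stokeslet at its singular point")
    return _oseen_velocity(force.force_pn, r, fluid.viscosity_pa_s)


def image_system(
    force: PointForce,
    eval_point: np.ndarray,
    fluid: FluidProperties = WATER,
    mode: str = "leading",
) -> np.ndarray:
    """Velocity (um/s) of the wall's image system only (no self flow).

    ``leading``: sign-reversed stokeslet at the mirror point.
    ``blake``: adds doublet corrections so stokeslet + image vanishes on z=0.
    """
    if mode not in ("leading", "blake"):
        raise ValueError(f"unknown image mode {mode!r}; use 'leading' or 'blake'")
    x = np.asarray(eval_point, dtype=float)
    mirror = force.position_um * np.array([1.0, 1.0, -1.0])
    r = x - mirror
    mu = fluid.viscosity_pa_s
    u = _oseen_velocity(-force.force_pn, r, mu)
    if mode == "blake":
        u = u + _blake_correction(force.force_pn, x, force.position_um, mu)
    return u


def total_velocity(
    forces: PointForce | Iterable[PointForce],
    eval_point: np.ndarray,
    fluid: FluidProperties = WATER,
    mode: str = "blake",
) -> np.ndarray:
    """Stokeslet plus image velocity, superposed over one or more forces."""
    if isinstance(forces, PointForce):
        forces = [forces]
    u = np.zeros(3)
    for f in forces:
        u = u + stokeslet(f, eval_point, fluid) + image_system(
            f, eval_point, fluid, mode
        )
    return u


def velocity_gradient(
    force: PointForce,
    eval_point: np.ndarray,
    fluid: FluidProperties = WATER,
    mode: str = "leading",
) -> np.ndarray:
    """Gradient G_il = d u_i / d x_l of the image-system velocity.

    The mirror stokeslet part is differentiated analytically; the Blake
    doublet corrections by a complex-step derivative, which is exact to
    machine precision (no truncation error, unlike finite differences).
    """
    if mode not in ("leading", "blake"):
        raise ValueError(f"unknown image mode {mode!r}")
    x = np.asarray(eval_point, dtype=float)
    mirror = force.position_um * np.array([1.0, 1.0, -1.0])
    mu = fluid.viscosity_pa_s
    grad = _oseen_gradient(-force.force_pn, x - mirror, mu)
    if mode == "blake":
        step = 1e-200
        for l in range(3):
            xc = x.astype(complex)
            xc[l] += 1j * step
            du = _blake_correction(force.force_pn, xc, force.position_um, mu)
            grad[:, l] += np.imag(du) / step
    return grad


def ambient_at(
    force: PointForce,
    eval_point: np.ndarray,
    fluid: FluidProperties = WATER,
    mode: str = "leading",
) -> AmbientFlow:
    """Ambient flow (u, Omega, E) of the image system at ``eval_point``.

    Only the wall-induced back flow enters: a cell's own unbounded
    stokeslet exerts no net force or torque on itself.
    """
    u = image_system(force, eval_point, fluid, mode)
    g = velocity_gradient(force, eval_point, fluid, mode)
    omega = 0.5 * np.array(
        [g[2, 1] - g[1, 2], g[0, 2] - g[2, 0], g[1, 0] - g[0, 1]]
    )
    strain = 0.5 * (g + g.T)
    # remove the numerical trace residue so AmbientFlow's invariant holds
    strain -= np.eye(3) * (np.trace(strain) / 3.0)
    return AmbientFlow(velocity=u, angular_velocity=omega, rate_of_strain=strain)


def decay_exponent(
    sampler: Callable[[float], np.ndarray],
    r_min: float,
    r_max: float,
    n_points: int = 20,
) -> float:
    """Least-squares slope of log|u| against log r.

    ``sampler(r)`` returns the velocity (vector or speed) at distance r.
    A stokeslet gives -1; a force-free cell sitting on a wall gives -3.
    """
    if n_points < 3:
        raise ValueError("need at least 3 sample points to fit a slope")
    rs = np.geomspace(r_min, r_max, n_points)
    speeds = np.array([np.linalg.norm(np.atleast_1d(sampler(r))) for r in rs])
    slope, _ = np.polyfit(np.log(rs), np.log(speeds), 1)
    return float(slope)


def advect_tracers(
    forces: PointForce | Sequence[PointForce],
    tracer_positions: np.ndarray,
    dt: float,
    duration: float,
    fluid: FluidProperties = WATER,
    mode: str = "blake",
) -> pd.DataFrame:
    """Advect passive tracers with classical RK4 in the total flow field.

    Returns a tidy track table (track_id, time_s, x_um, y_um, z_um).
    Tracers are confined to the fluid half space z >= 0.
    """
    if isinstance(forces, PointForce):
        forces = [forces]
    pos = np.atleast_2d(np.asarray(tracer_positions, dtype=float)).copy()
    if pos.shape[1] != 3:
        raise ValueError("tracer positions must be (n, 3)")
    for f in forces:
        if np.min(np.linalg.norm(pos - f.position_um, axis=1)) == 0.0:
            raise ValueError("a tracer starts at a point-force singularity")
    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt

    def vel(p):
        return total_velocity(forces, p, fluid, mode)

    records = []
    for tid in range(pos.shape[0]):
        p = pos[tid].copy()
        for t in times:
            records.append((tid, t, p[0], p[1], p[2]))
            k1 = vel(p)
            k2 = vel(p + 0.5 * dt * k1)
            k3 = vel(p + 0.5 * dt * k2)
            k4 = vel(p + dt * k3)
            p = p + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            p[2] = max(p[2], 0.0)  # the wall is impenetrable
    return pd.DataFrame(
        records, columns=["track_id", "time_s", "x_um", "y_um", "z_um"]
    )
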