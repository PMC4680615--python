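"""Orientation dynamics of a cell anchored to a wall by a rigid stalk.

A prolate-spheroid cell of semi-major axis ``a`` sits at the tip of a
rigid, inextensible stalk of length ``l`` anchored at the origin of a
no-slip wall (z = 0).  The stalk direction is the unit vector ``r`` and
the cell's propulsive axis is the unit vector ``d``; the cell exerts the
force ``-f0 d`` on the fluid (a cell pointing away from the wall pumps
fluid toward it).  The ambient flow the cell feels is the wall's image
system evaluated at the cell centre (its own unbounded stokeslet exerts
no net force or torque on itself).

Two balances close the dynamics:

* Stalk swing - the net force at the anchor must point along the stalk
  (carried as tension), which yields d(r)/dt with a Lagrange multiplier
  enforcing tangency r . dr/dt = 0.
* Cell torque balance about the stalk attachment point - three torques
  act on the cell: the drag of translating on the arm of length ``a``
  (L1), the rotational drag relative to the ambient vorticity (L2), and
  the rate-of-strain torque on the non-spherical body (L3).  Solving
  L1 + L2 + L3 = 0 for d(d)/dt gives

      dd/dt = [ 3 (A u)_perp + 4 a beta_perp (Omega x d)
                + 4 a beta_perp Gamma (E d)_perp ] / (a (3 alpha_perp + 4 beta_perp))

  where X_perp = X - (d.X) d.  In the sphere limit with pure uniform
  flow this reduces to dd/dt = 3 u_perp / (7 a).

The upright configuration r = d = e3 is a fixed point.  It is stable
for stalks longer than the critical length

      l_c = 4 beta_perp Gamma a / (3 alpha_perp),

about a quarter cell length for T. majus and 0.44 a for Uronemella, so
real stalks (10-100 um) are comfortably in the stable regime.  The
azimuthal angles chi, xi of d and r decouple by rotational symmetry;
the reduced dynamics live in the polar angles (theta, phi).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, fsolve

from .spheroid import CellGeometry, DragCoefficients, drag_tensor
from .wallflow import WATER, AmbientFlow, FluidProperties, PointForce, ambient_at

__all__ = [
    "TetherState",
    "DynamicsParams",
    "TorqueDecomposition",
    "FixedPoint",
    "StabilityReport",
    "PhasePortrait",
    "Trajectory",
    "cell_ambient",
    "stalk_rate",
    "orientation_rate",
    "torque_decomposition",
    "polar_rate",
    "reduced_rates",
    "integrate",
    "critical_length",
    "linear_stability",
    "eigenvalue_crossing_length",
    "phase_portrait",
    "timescales",
]

E3 = np.array([0.0, 0.0, 1.0])


def _unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector")
    if abs(np.linalg.norm(v) - 1.0) > 1e-9:
        raise ValueError(f"{name} must be a unit vector (within 1e-9)")
    return v


@dataclass(frozen=True)
class TetherState:
    """Configuration of a tethered cell.

    ``stalk_direction`` (r) points from the anchor to the cell,
    ``cell_orientation`` (d) along the propulsive axis, and
    ``stalk_length_um`` is the stalk length l.  The polar angles theta
    (of d) and phi (of r) are measured from the wall normal e3; chi and
    xi are the corresponding azimuths.
    """

    stalk_direction: np.ndarray
    cell_orientation: np.ndarray
    stalk_length_um: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "stalk_direction", _unit(self.stalk_direction, "stalk_direction")
        )
        object.__setattr__(
            self,
            "cell_orientation",
            _unit(self.cell_orientation, "cell_orientation"),
        )
        if self.stalk_direction[2] <= 0:
            raise ValueError("the cell must sit above the wall (r . e3 > 0)")
        if self.stalk_length_um <= 0:
            raise ValueError("stalk length must be positive")

    @classmethod
    def from_angles(
        cls,
        theta: float,
        phi: float,
        stalk_length_um: float,
        chi: float = 0.0,
        xi: float = 0.0,
    ) -> "TetherState":
        d = np.array(
            [np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi), np.cos(theta)]
        )
        r = np.array(
            [np.sin(phi) * np.cos(xi), np.sin(phi) * np.sin(xi), np.cos(phi)]
        )
        return cls(r, d, stalk_length_um)

    @property
    def cell_position_um(self) -> np.ndarray:
        return self.stalk_length_um * self.stalk_direction

    @property
    def theta(self) -> float:
        return float(np.arccos(np.clip(self.cell_orientation[2], -1.0, 1.0)))

    @property
    def phi(self) -> float:
        return float(np.arccos(np.clip(self.stalk_direction[2], -1.0, 1.0)))

    @property
    def chi(self) -> float:
        return float(np.arctan2(self.cell_orientation[1], self.cell_orientation[0]))

    @property
    def xi(self) -> float:
        return float(np.arctan2(self.stalk_direction[1], self.stalk_direction[0]))


@dataclass(frozen=True)
class DynamicsParams:
    """Cell geometry, fluid, propulsive force and image-flow approximation."""

    geometry: CellGeometry
    fluid: FluidProperties = WATER
    force_pn: float = 40.0
    image_mode: str = "leading"
    drag: DragCoefficients = field(init=False)

    def __post_init__(self) -> None:
        if self.force_pn <= 0:
            raise ValueError("propulsive force must be positive")
        object.__setattr__(self, "drag", DragCoefficients.from_geometry(self.geometry))

    @property
    def semi_major_um(self) -> float:
        return self.geometry.semi_major_um


@dataclass(frozen=True)
class TorqueDecomposition:
    """The three torques (pN um) of the cell torque balance and the cell's
    angular velocity omega (1/s); L1 + L2 + L3 = 0 at a solution."""

    translation_drag: np.ndarray  # L1
    rotation_drag: np.ndarray  # L2
    strain_torque: np.ndarray  # L3
    angular_velocity: np.ndarray

    @property
    def residual(self) -> np.ndarray:
        return self.translation_drag + self.rotation_drag + self.strain_torque


def cell_ambient(state: TetherState, params: DynamicsParams) -> AmbientFlow:
    """Image-system ambient flow at the cell centre."""
    force = PointForce(
        position_um=state.cell_position_um,
        force_pn=-params.force_pn * state.cell_orientation,
    )
    return ambient_at(force, state.cell_position_um, params.fluid, params.image_mode)


def _mobility_pieces(state: TetherState, params: DynamicsParams):
    d = state.cell_orientation
    dr = params.drag
    A = drag_tensor(d, dr.alpha_par, dr.alpha_perp)
    Ainv = drag_tensor(d, 1.0 / dr.alpha_par, 1.0 / dr.alpha_perp)
    return d, dr, A, Ainv


def stalk_rate(
    state: TetherState, params: DynamicsParams, ambient: AmbientFlow
) -> np.ndarray:
    """d(r)/dt of the stalk direction.

    The force balance at the anchor reads
    0 = r x { f0 d + 6 pi mu a A (u - l dr/dt) }; the component along r
    is carried by stalk tension T, introduced as a Lagrange multiplier
    fixed by the tangency constraint r . dr/dt = 0.
    """
    d, dr, A, Ainv = _mobility_pieces(state, params)
    r = state.stalk_direction
    mu_a6pi = 6.0 * np.pi * params.fluid.viscosity_pa_s * params.semi_major_um
    rhs = params.force_pn * d + mu_a6pi * (A @ ambient.velocity)
    tension = (r @ (Ainv @ rhs)) / (r @ (Ainv @ r))
    return (Ainv @ (rhs - tension * r)) / (mu_a6pi * state.stalk_length_um)


def orientation_rate(
    state: TetherState, params: DynamicsParams, ambient: AmbientFlow
) -> np.ndarray:
    """d(d)/dt of the cell orientation from the torque balance (see module
    docstring); exactly tangent to d, and flow-alignment only as a -> 0."""
    d, dr, A, _ = _mobility_pieces(state, params)
    a = params.semi_major_um
    u, Om, E = ambient.velocity, ambient.angular_velocity, ambient.rate_of_strain

    def perp(v):
        return v - (d @ v) * d

    num = (
        3.0 * perp(A @ u)
        + 4.0 * a * dr.beta_perp * np.cross(Om, d)
        + 4.0 * a * dr.beta_perp * dr.gamma * perp(E @ d)
    )
    return num / (a * (3.0 * dr.alpha_perp + 4.0 * dr.beta_perp))


def torque_decomposition(
    state: TetherState, params: DynamicsParams
) -> TorqueDecomposition:
    """Evaluate L1, L2, L3 at the state's self-consistent rates.

    L1 = a d x {6 pi mu a A (u - a dd/dt)}   (arm-translation drag)
    L2 = 8 pi mu a^3 B (Omega - omega)        (rotation drag)
    L3 = 8 pi mu a^3 beta_perp Gamma d x (E d) (rate-of-strain torque)
    with omega = (Omega . d) d + d x dd/dt.
    """
    ambient = cell_ambient(state, params)
    ddot = orientation_rate(state, params, ambient)
    d, dr, A, _ = _mobility_pieces(state, params)
    a = params.semi_major_um
    mu = params.fluid.viscosity_pa_s
    B = drag_tensor(d, dr.beta_par, dr.beta_perp)
    omega = (ambient.angular_velocity @ d) * d + np.cross(d, ddot)
    L1 = a * np.cross(d, 6.0 * np.pi * mu * a * (A @ (ambient.velocity - a * ddot)))
    L2 = 8.0 * np.pi * mu * a**3 * (B @ (ambient.angular_velocity - omega))
    L3 = (
        8.0
        * np.pi
        * mu
        * a**3
        * dr.beta_perp
        * dr.gamma
        * np.cross(d, ambient.rate_of_strain @ d)
    )
    return TorqueDecomposition(L1, L2, L3, omega)


def polar_rate(
    theta: float, phi: float, params: DynamicsParams, stalk_length_um: float
) -> float:
    """Closed-form d(theta)/dt of the coplanar reduced dynamics.

    t_s dtheta/dt = [ (9/16) beta_perp a Gamma (3 + cos 2 theta)
                      - 3 l alpha_perp cos(theta) cos(phi) ]
                    * cos^2(phi) sin(theta) / (a (3 alpha_perp + 4 beta_perp))

    with the swing timescale t_s = 6 pi mu a l / f0.  The first
    (destabilizing) term is the rate-of-strain twist toward the image
    cell, the second (stabilizing, proportional to l) is alignment with
    the back flow.  Setting the bracket to zero at theta -> 0, phi = 0
    gives a marginal length (3/4) beta_perp Gamma a / alpha_perp, i.e.
    9/16 of the critical length from the full coupled linearization;
    this closed form is kept as the qualitative single-angle picture and
    the full dynamics as the quantitative one (see docs/methods.md).
    """
    a = params.semi_major_um
    dr = params.drag
    ts = (
        6.0
        * np.pi
        * params.fluid.viscosity_pa_s
        * a
        * stalk_length_um
        / params.force_pn
    )
    bracket = (9.0 / 16.0) * dr.beta_perp * a * dr.gamma * (
        3.0 + np.cos(2.0 * theta)
    ) - 3.0 * stalk_length_um * dr.alpha_perp * np.cos(theta) * np.cos(phi)
    rate = (
        bracket
        * np.cos(phi) ** 2
        * np.sin(theta)
        / (a * (3.0 * dr.alpha_perp + 4.0 * dr.beta_perp))
    )
    return float(rate / ts)


def reduced_rates(
    theta: float, phi: float, params: DynamicsParams, stalk_length_um: float
) -> tuple[float, float]:
    """(dtheta/dt, dphi/dt) of the full dynamics restricted to a common
    azimuthal plane (the restriction is exact: coplanar states stay
    coplanar by mirror symmetry).  Valid for |phi| < pi/2 (cell above
    the wall)."""
    if abs(phi) >= np.pi / 2:
        raise ValueError("|phi| must be < pi/2 (cell above the wall)")
    state = TetherState.from_angles(theta, phi, stalk_length_um)
    ambient = cell_ambient(state, params)
    rdot = stalk_rate(state, params, ambient)
    ddot = orientation_rate(state, params, ambient)
    e_th = np.array([np.cos(theta), 0.0, -np.sin(theta)])
    e_ph = np.array([np.cos(phi), 0.0, -np.sin(phi)])
    return float(ddot @ e_th), float(rdot @ e_ph)


@dataclass(frozen=True)
class Trajectory:
    """Time series of a tethered-cell integration."""

    time_s: np.ndarray
    stalk_direction: np.ndarray  # (n, 3)
    cell_orientation: np.ndarray  # (n, 3)
    stalk_length_um: float
    max_norm_drift: float = 0.0  # worst raw |v|-1 before renormalization

    @property
    def theta(self) -> np.ndarray:
        return np.arccos(np.clip(self.cell_orientation[:, 2], -1.0, 1.0))

    @property
    def phi(self) -> np.ndarray:
        return np.arccos(np.clip(self.stalk_direction[:, 2], -1.0, 1.0))


def integrate(
    state0: TetherState,
    params: DynamicsParams,
    duration_s: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_out: int = 200,
) -> Trajectory:
    """Integrate the coupled stalk + orientation dynamics.

    The state is carried in Cartesian unit vectors (r, d) - never in
    angles - so there is no coordinate singularity at theta = 0 or pi.
    Both rates are exactly tangent to their vectors; a weak feedback
    term kappa (1 - |v|^2) v (zero on the unit sphere) keeps the norms
    from drifting over long runs.  The ambient flow is recomputed from
    the current cell position at every right-hand-side evaluation.
    """
    ell = state0.stalk_length_um
    tau_f, _ = timescales(params, ell)
    kappa = 10.0 / tau_f

    def rhs(t, y):
        r, d = y[:3], y[3:]
        rn, dn = r / np.linalg.norm(r), d / np.linalg.norm(d)
        state = TetherState(rn, dn, ell)
        ambient = cell_ambient(state, params)
        rdot = stalk_rate(state, params, ambient)
        ddot = orientation_rate(state, params, ambient)
        return np.concatenate(
            [
                rdot + kappa * (1.0 - r @ r) * r,
                ddot + kappa * (1.0 - d @ d) * d,
            ]
        )

    y0 = np.concatenate([state0.stalk_direction, state0.cell_orientation])
    t_eval = np.linspace(0.0, duration_s, n_out)
    sol = solve_ivp(
        rhs, (0.0, duration_s), y0, t_eval=t_eval, rtol=rtol, atol=atol, method="RK45"
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed: {sol.message}; last state {sol.y[:, -1]}"
        )
    rhat = sol.y[:3].T.copy()
    dhat = sol.y[3:].T.copy()
    rn = np.linalg.norm(rhat, axis=1)
    dn = np.linalg.norm(dhat, axis=1)
    drift = float(max(np.abs(rn - 1.0).max(), np.abs(dn - 1.0).max()))
    return Trajectory(
        time_s=sol.t,
        stalk_direction=rhat / rn[:, None],
        cell_orientation=dhat / dn[:, None],
        stalk_length_um=ell,
        max_norm_drift=drift,
    )


def critical_length(drag: DragCoefficients, geometry: CellGeometry) -> float:
    """Critical stalk length l_c = 4 beta_perp Gamma a / (3 alpha_perp), um.

    Zero for a sphere; stalks longer than l_c make the upright fixed
    point stable.
    """
    return (
        4.0
        * drag.beta_perp
        * drag.gamma
        * geometry.semi_major_um
        / (3.0 * drag.alpha_perp)
    )


def _reduced_jacobian(
    params: DynamicsParams,
    stalk_length_um: float,
    theta: float = 0.0,
    phi: float = 0.0,
    step: float = 1e-6,
) -> np.ndarray:
    J = np.zeros((2, 2))
    for j, (dth, dph) in enumerate(((step, 0.0), (0.0, step))):
        fp = reduced_rates(theta + dth, phi + dph, params, stalk_length_um)
        fm = reduced_rates(theta - dth, phi - dph, params, stalk_length_um)
        J[:, j] = (np.array(fp) - np.array(fm)) / (2.0 * step)
    return J


@dataclass(frozen=True)
class FixedPoint:
    theta: float
    phi: float
    eigenvalues: np.ndarray
    classification: str  # stable / unstable / saddle / marginal


@dataclass(frozen=True)
class StabilityReport:
    fixed_points: list[FixedPoint]
    critical_length_um: float
    stalk_length_um: float

    @property
    def stable(self) -> bool:
        return any(fp.classification == "stable" for fp in self.fixed_points)


def _classify(eigs: np.ndarray, marginal_scale: float) -> str:
    re = eigs.real
    if np.any(np.abs(re) < marginal_scale):
        return "marginal"
    if np.all(re < 0):
        return "stable"
    if np.all(re > 0):
        return "unstable"
    return "saddle"


def linear_stability(
    params: DynamicsParams, stalk_length_um: float
) -> StabilityReport:
    """Eigenvalues of the linearized (theta, phi) dynamics at the upright
    fixed point (0, 0) and the inverted one (pi, 0)."""
    tau_f, _ = timescales(params, stalk_length_um)
    marginal = 1e-10 / tau_f
    fps = []
    for th in (0.0, np.pi):
        J = _reduced_jacobian(params, stalk_length_um, theta=th)
        eigs = np.linalg.eigvals(J)
        fps.append(FixedPoint(th, 0.0, eigs, _classify(eigs, marginal)))
    return StabilityReport(
        fixed_points=fps,
        critical_length_um=critical_length(params.drag, params.geometry),
        stalk_length_um=stalk_length_um,
    )


def eigenvalue_crossing_length(
    params: DynamicsParams, lo_um: float, hi_um: float
) -> float:
    """Stalk length at which the leading eigenvalue of the upright fixed
    point crosses zero, found by bisection.  Compare with the closed form
    ``critical_length``; the two linearizations need not coincide exactly
    because the closed form drops the swing/orientation coupling."""

    def leading(ell):
        return float(np.max(np.linalg.eigvals(_reduced_jacobian(params, ell)).real))

    return float(brentq(leading, lo_um, hi_um, xtol=1e-6 * hi_um))


@dataclass(frozen=True)
class PhasePortrait:
    theta_grid: np.ndarray
    phi_grid: np.ndarray
    dtheta: np.ndarray  # (n_phi, n_theta)
    dphi: np.ndarray
    fixed_points: list[FixedPoint]
    basin: np.ndarray | None  # 1 in basin, 0 escaped, -1 undetermined


def phase_portrait(
    params: DynamicsParams,
    stalk_length_um: float,
    n_theta: int = 41,
    n_phi: int = 17,
    phi_margin: float = 0.1,
    compute_basin: bool = True,
    basin_stride: int = 2,
    convergence_tol: float = 1e-3,
    time_cap_tau_s: float = 200.0,
) -> PhasePortrait:
    """Reduced (theta, phi) vector field, its fixed points, and the basin
    of attraction of the upright state.

    theta spans the closed interval [-pi, pi] (so the inverted-cell
    fixed point appears at both plot edges, as in a wrapped portrait);
    phi spans the physical range (-pi/2, pi/2) minus ``phi_margin``.
    Basin membership is decided by integrating each (sub-sampled) grid
    point until it comes within ``convergence_tol`` of the upright fixed
    point (in basin), the stalk falls flat (|phi| -> pi/2, escaped), or
    a time cap of ``time_cap_tau_s`` slow timescales elapses
    (undetermined).
    """
    thetas = np.linspace(-np.pi, np.pi, n_theta)
    phi_max = np.pi / 2 - phi_margin
    phis = np.linspace(-phi_max, phi_max, n_phi)
    dth = np.zeros((n_phi, n_theta))
    dph = np.zeros((n_phi, n_theta))
    for i, ph in enumerate(phis):
        for j, th in enumerate(thetas):
            dth[i, j], dph[i, j] = reduced_rates(th, ph, params, stalk_length_um)

    # fixed points: refine coarse-grid seeds, keep solutions in the domain
    tau_f, tau_s = timescales(params, stalk_length_um)
    marginal = 1e-10 / tau_f

    def fun(y):
        th = float(np.clip(y[0], -np.pi - 0.5, np.pi + 0.5))
        ph = float(np.clip(y[1], -phi_max, phi_max))
        return reduced_rates(th, ph, params, stalk_length_um)

    fps: list[FixedPoint] = []
    seeds = [(t, p) for t in np.linspace(-np.pi, np.pi, 9) for p in (-0.7, 0.0, 0.7)]
    for seed in seeds:
        sol, info, ier, _ = fsolve(fun, seed, full_output=True)
        if ier != 1 or np.max(np.abs(fun(sol))) > 1e-8 / tau_f:
            continue
        th, ph = float(sol[0]), float(sol[1])
        if not (-np.pi - 1e-6 <= th <= np.pi + 1e-6 and abs(ph) < phi_max):
            continue
        th = float(np.clip(th, -np.pi, np.pi))
        # theta = -pi and +pi are the same physical configuration: keep one
        if abs(th + np.pi) < 1e-4:
            th = float(np.pi)
        if any(abs(th - f.theta) < 1e-4 and abs(ph - f.phi) < 1e-4 for f in fps):
            continue
        eigs = np.linalg.eigvals(
            _reduced_jacobian(params, stalk_length_um, theta=th, phi=ph)
        )
        fps.append(FixedPoint(th, ph, eigs, _classify(eigs, marginal)))
    fps.sort(key=lambda f: (f.theta, f.phi))

    basin = None
    if compute_basin:
        basin = -np.ones((n_phi, n_theta), dtype=np.int8)
        cap = time_cap_tau_s * tau_s

        def rhs(t, y):
            return reduced_rates(y[0], y[1], params, stalk_length_um)

        def near_origin(t, y):
            return np.hypot(y[0], y[1]) - convergence_tol

        near_origin.terminal = True

        def stalk_flat(t, y):
            return abs(y[1]) - (np.pi / 2 - 1e-3)

        stalk_flat.terminal = True

        for i in range(0, n_phi, basin_stride):
            for j in range(0, n_theta, basin_stride):
                y0 = [thetas[j], phis[i]]
                if np.hypot(*y0) <= convergence_tol:
                    basin[i, j] = 1
                    continue
                sol = solve_ivp(
                    rhs,
                    (0.0, cap),
                    y0,
                    events=[near_origin, stalk_flat],
                    rtol=1e-6,
                    atol=1e-9,
                )
                if sol.t_events[0].size:
                    basin[i, j] = 1
                elif sol.t_events[1].size:
                    basin[i, j] = 0
                # else: time cap hit -> stays -1 (undetermined)
    return PhasePortrait(thetas, phis, dth, dph, fps, basin)


def timescales(params: DynamicsParams, stalk_length_um: float) -> tuple[float, float]:
    """(tau_fast, tau_slow): the stalk-alignment timescale
    tau_f = 6 pi mu a l / f0 and the righting timescale
    tau_s = 8 pi mu l^2 / f0 = l / u_s; tau_f/tau_s = (3/4) a/l."""
    mu = params.fluid.viscosity_pa_s
    tau_f = 6.0 * np.pi * mu * params.semi_major_um * stalk_length_um / params.force_pn
    tau_s = 8.0 * np.pi * mu * stalk_length_um**2 / params.force_pn
    return tau_f, tau_s
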