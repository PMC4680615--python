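"""Synthetic data emulating the veil-forming-microbe experiments.

Four generators produce the raw inputs the measurement pipeline
consumes, each with explicit seeds and physically motivated defaults:

* ``generate_stalk_tracks`` - positions of cells anchored to a slide
  whose stalks elongate at a constant rate, plus localization noise.
* ``simulate_chamber`` - a thin (effectively 2-D) observation chamber:
  oxygen diffuses in from gas-permeable edges, is consumed by swimming
  cells, and the cells do a biased random walk toward their preferred
  oxygen concentration, so they collapse from a uniform mixture into a
  dense band (an aerotactic front) at that concentration.
* ``stern_volmer_image`` - the fluorescence of an oxygen-quenched dye,
  I = I0 / (1 + K_sv c), imaging a given oxygen field.
* ``generate_veil_series`` - scattered-light intensity of accumulating
  veil material, proportional to the time-integrated cell number.

The chamber model is deliberately minimal: pure diffusion with Dirichlet
edges, point-sink consumption, drift-diffusion walkers.  No fluid flow,
no attachment kinetics, no veil mechanics - just enough structure for a
front to form at a controllable concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import gaussian_filter

__all__ = [
    "ChamberConfig",
    "ChamberState",
    "generate_stalk_tracks",
    "simulate_chamber",
    "stern_volmer_image",
    "generate_veil_series",
]


def generate_stalk_tracks(
    rate_um_s: float,
    n_tracks: int = 10,
    duration_s: float = 30.0,
    dt_s: float = 1.0,
    noise_sd_um: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Tracks of anchored cells drifting as their stalks elongate.

    Each cell moves from a random origin along a random in-plane
    direction at ``rate_um_s``; independent Gaussian localization noise
    of ``noise_sd_um`` is added to both coordinates.  Returns a tidy
    table (track_id, time_s, x_um, y_um) sampled at ``dt_s``.
    """
    if rate_um_s < 0 or dt_s <= 0:
        raise ValueError("rate must be >= 0 and dt > 0")
    if duration_s < dt_s:
        raise ValueError("duration must be at least one sampling interval")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_s + 0.5 * dt_s, dt_s)
    frames = []
    for tid in range(n_tracks):
        angle = rng.uniform(0.0, 2.0 * np.pi)
        origin = rng.uniform(0.0, 100.0, size=2)
        direction = np.array([np.cos(angle), np.sin(angle)])
        xy = origin + np.outer(times * rate_um_s, direction)
        xy += rng.normal(0.0, noise_sd_um, size=xy.shape)
        frames.append(
            pd.DataFrame(
                {
                    "track_id": tid,
                    "time_s": times,
                    "x_um": xy[:, 0],
                    "y_um": xy[:, 1],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class ChamberConfig:
    """Parameters of the 2-D observation-chamber simulation.

    Concentrations are in percent of air saturation (% atm); lengths in
    cm; times in s.  Defaults give a 1.5 cm square chamber at 128x128
    resolution, air-saturated edges and interior, 300 cells, and the
    ciliate's preferred concentration of 7% atm.
    """

    nx: int = 128
    ny: int = 128
    side_cm: float = 1.5
    diffusivity_cm2_s: float = 1e-5
    boundary_pct: float = 100.0
    initial_pct: float = 100.0
    n_cells: int = 300
    consumption_pct_cm2_s: float = 2e-5  # per-cell sink strength
    consumption_sigma_px: float = 2.0  # smeared over the cell's swimming range
    cell_diffusivity_cm2_s: float = 1e-5  # motility of the random walk
    chemotactic_strength_cm_s_per_pct: float = 5e-4
    drift_cap_cm_s: float = 2.5e-3
    preferred_pct: float = 7.0
    gradient_floor_pct_cm: float = 1e-3
    i0: float = 1.0
    k_sv_per_pct: float = 0.05
    cell_image_sigma_px: float = 1.0
    dt_s: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 3:
            raise ValueError("grid must be at least 3x3")
        if not (0.0 < self.preferred_pct < 100.0):
            raise ValueError("preferred concentration must be in (0, 100) % atm")
        for name in (
            "diffusivity_cm2_s",
            "consumption_pct_cm2_s",
            "cell_diffusivity_cm2_s",
            "chemotactic_strength_cm_s_per_pct",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def dx_cm(self) -> float:
        return self.side_cm / self.nx

    def stability_number(self) -> float:
        return self.diffusivity_cm2_s * self.dt_s / self.dx_cm**2


@dataclass(frozen=True)
class ChamberState:
    """One stored frame of the chamber simulation.

    ``cell_image`` / ``cell_image_prev`` are the scattered-light images
    of the cells at this time and one step (dt) earlier, so sequential
    frame differencing can be exercised exactly as on the microscope.
    """

    time_s: float
    oxygen_pct: np.ndarray  # (ny, nx)
    cell_positions_cm: np.ndarray  # (n, 2) columns x, y
    fluorescence: np.ndarray
    cell_image: np.ndarray
    cell_image_prev: np.ndarray
    seed: int


def stern_volmer_image(
    oxygen_pct: np.ndarray, i0: float = 1.0, k_sv_per_pct: float = 0.05
) -> np.ndarray:
    """Fluorescence of an oxygen-quenched dye: I = I0 / (1 + K_sv c)."""
    c = np.asarray(oxygen_pct, dtype=float)
    if np.any(c < 0):
        raise ValueError("oxygen concentrations must be non-negative")
    return i0 / (1.0 + k_sv_per_pct * c)


def _render_cells(
    positions_cm: np.ndarray, config: ChamberConfig
) -> np.ndarray:
    """Scattered-light image of the cells: a blurred point per cell."""
    img = np.zeros((config.ny, config.nx))
    if positions_cm.size:
        cols = np.clip(
            (positions_cm[:, 0] / config.dx_cm).astype(int), 0, config.nx - 1
        )
        rows = np.clip(
            (positions_cm[:, 1] / config.dx_cm).astype(int), 0, config.ny - 1
        )
        np.add.at(img, (rows, cols), 1.0)
    return gaussian_filter(img, config.cell_image_sigma_px)


def _laplacian(c: np.ndarray, dx: float) -> np.ndarray:
    lap = np.zeros_like(c)
    lap[1:-1, 1:-1] = (
        c[2:, 1:-1] + c[:-2, 1:-1] + c[1:-1, 2:] + c[1:-1, :-2] - 4.0 * c[1:-1, 1:-1]
    ) / dx**2
    return lap


def simulate_chamber(
    config: ChamberConfig,
    duration_s: float = 24000.0,
    stride: int = 400,
) -> list[ChamberState]:
    """Run the chamber model and return the stored frames.

    Explicit first-order time stepping: oxygen diffuses (Dirichlet
    edges at ``boundary_pct``), each cell removes oxygen from its pixel,
    and cells take drift-diffusion steps with drift
    ``-chi (c - c*) grad(c) / (|grad(c)| + eps)`` (capped at
    ``drift_cap_cm_s``): above the preferred concentration they descend
    the gradient, below it they climb, so they gather on the c = c*
    contour.  Deterministic for a given config (the seed is part of it).
    """
    if config.stability_number() > 0.25:
        raise ValueError(
            "explicit diffusion unstable: D dt / dx^2 = "
            f"{config.stability_number():.3f} > 0.25; reduce dt"
        )
    rng = np.random.default_rng(config.seed)
    dx = config.dx_cm
    dt = config.dt_s
    c = np.full((config.ny, config.nx), float(config.initial_pct))
    c[0, :] = c[-1, :] = config.boundary_pct
    c[:, 0] = c[:, -1] = config.boundary_pct
    pos = rng.uniform(0.0, config.side_cm, size=(config.n_cells, 2))
    prev_img = _render_cells(pos, config)

    n_steps = int(round(duration_s / dt))
    states: list[ChamberState] = []
    noise_sd = np.sqrt(2.0 * config.cell_diffusivity_cm2_s * dt)
    for step in range(n_steps + 1):
        if step % stride == 0:
            states.append(
                ChamberState(
                    time_s=step * dt,
                    oxygen_pct=c.copy(),
                    cell_positions_cm=pos.copy(),
                    fluorescence=stern_volmer_image(
                        c, config.i0, config.k_sv_per_pct
                    ),
                    cell_image=_render_cells(pos, config),
                    cell_image_prev=prev_img.copy(),
                    seed=config.seed,
                )
            )
        if step == n_steps:
            break
        prev_img = _render_cells(pos, config)
        # oxygen: diffusion + Dirichlet edges - point-sink consumption
        c = c + config.diffusivity_cm2_s * dt * _laplacian(c, dx)
        if config.n_cells:
            cols = np.clip((pos[:, 0] / dx).astype(int), 0, config.nx - 1)
            rows = np.clip((pos[:, 1] / dx).astype(int), 0, config.ny - 1)
            sink = np.zeros_like(c)
            np.add.at(sink, (rows, cols), config.consumption_pct_cm2_s * dt / dx**2)
            # a fast-swimming cell spreads its consumption over the area it
            # sweeps between field updates, not a single pixel
            c -= gaussian_filter(sink, config.consumption_sigma_px)
        np.clip(c, 0.0, None, out=c)
        c[0, :] = c[-1, :] = config.boundary_pct
        c[:, 0] = c[:, -1] = config.boundary_pct
        # cells: chemotactic drift toward c = c* plus motility noise
        if config.n_cells:
            gy, gx = np.gradient(c, dx)
            local_c = c[rows, cols]
            g = np.column_stack([gx[rows, cols], gy[rows, cols]])
            gnorm = np.linalg.norm(g, axis=1) + config.gradient_floor_pct_cm
            speed = config.chemotactic_strength_cm_s_per_pct * (
                local_c - config.preferred_pct
            )
            speed = np.clip(speed, -config.drift_cap_cm_s, config.drift_cap_cm_s)
            drift = -speed[:, None] * g / gnorm[:, None]
            pos = pos + drift * dt + rng.normal(0.0, noise_sd, size=pos.shape)
            # reflect at the chamber walls
            pos = np.abs(pos)
            pos = config.side_cm - np.abs(config.side_cm - pos)
    return states


def generate_veil_series(
    cell_count: np.ndarray,
    dt_s: float = 10.0,
    production_rate: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Scattered-light intensity of veil accumulating from cell stalks.

    Every cell sheds stalk material at a constant rate, so the amount of
    veil - and the light it scatters - tracks the running time-integral
    of the cell count (trapezoid rule).  Gaussian measurement noise of
    ``noise_sd`` (a.u.) is added to the intensity.
    """
    counts = np.asarray(cell_count, dtype=float)
    if counts.ndim != 1 or counts.size < 2:
        raise ValueError("cell_count must be a 1-D array with >= 2 samples")
    if np.any(counts < 0):
        raise ValueError("cell counts must be non-negative")
    rng = np.random.default_rng(seed)
    times = np.arange(counts.size) * dt_s
    integrated = cumulative_trapezoid(counts, times, initial=0.0)
    intensity = production_rate * integrated
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=intensity.shape)
    return pd.DataFrame(
        {
            "time_s": times,
            "cell_count": counts,
            "integrated_cell_number": integrated,
            "scattered_intensity": intensity,
        }
    )
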