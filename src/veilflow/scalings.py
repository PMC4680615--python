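"""Advection-vs-diffusion feeding scalings for a filter-feeding microbe.

A sessile cell pulling fluid past itself generates an advective nutrient
flux j_a ~ u c ~ f0 c / (8 pi mu r), while diffusion supplies
j_d ~ D c / r.  Their ratio is scale free:

    Pe = j_a / j_d = f0 / (8 pi D mu)

so the cell's influence on its chemical environment is set by the force
it exerts measured against a "diffusive force" f_d = 8 pi D mu built
from the water viscosity and the nutrient diffusivity alone.  For
oxygen in water f_d is about 25 pN: a cell must exert tens of
piconewtons before advection beats diffusion, which is an order of
magnitude above the ~1 pN typical of bacteria like E. coli.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .presets import OrganismPreset
from .wallflow import WATER, FluidProperties

__all__ = [
    "ScalingReport",
    "stokes_force",
    "diffusive_force",
    "peclet",
    "scaling_report",
]

_PN_PER_N = 1e12


def stokes_force(
    radius_um: float, speed_um_s: float, fluid: FluidProperties = WATER
) -> float:
    """Stokes drag 6 pi mu a U in pN for a cell of radius a swimming at U.

    Used to infer the propulsive force from the free-swimming speed.
    """
    if radius_um <= 0 or speed_um_s < 0:
        raise ValueError("radius must be > 0 and speed >= 0")
    a_m = radius_um * 1e-6
    u_m = speed_um_s * 1e-6
    return 6.0 * np.pi * fluid.viscosity_pa_s * a_m * u_m * _PN_PER_N


def diffusive_force(fluid: FluidProperties = WATER) -> float:
    """Diffusive force f_d = 8 pi D mu in pN."""
    d_m2 = fluid.diffusivity_cm2_s * 1e-4
    return 8.0 * np.pi * d_m2 * fluid.viscosity_pa_s * _PN_PER_N


def peclet(force_pn: float, fluid: FluidProperties = WATER) -> float:
    """Peclet number Pe = f0 / (8 pi D mu), dimensionless."""
    if force_pn <= 0:
        raise ValueError("force must be positive")
    return force_pn / diffusive_force(fluid)


@dataclass(frozen=True)
class ScalingReport:
    """Feeding scalings of one organism/parameter set.

    ``stokes_force_pn`` is the 6 pi mu a U estimate from the swim speed;
    ``stated_force_pn`` the organism's (possibly rounded) catalogued
    force, used for the Peclet number when provided.  j_a/j_d carry the
    scale-free parts of the advective and diffusive fluxes (c/r factors
    cancel in the ratio).
    """

    stokes_force_pn: float
    stated_force_pn: float
    diffusive_force_pn: float
    peclet: float

    @property
    def advective_flux_scale(self) -> float:
        return self.stated_force_pn  # j_a ~ f0 c / (8 pi mu r); scale ~ f0

    @property
    def diffusive_flux_scale(self) -> float:
        return self.diffusive_force_pn  # j_d ~ D c / r ~ f_d c / (8 pi mu r)


def scaling_report(
    radius_um: float | None = None,
    speed_um_s: float | None = None,
    force_pn: float | None = None,
    fluid: FluidProperties = WATER,
    preset: OrganismPreset | None = None,
) -> ScalingReport:
    """Build a ScalingReport from a preset or explicit (a, U[, f0]).

    The Peclet number uses the stated force when given (presets carry
    the catalogued rounded force), otherwise the Stokes estimate.
    """
    if preset is not None:
        radius_um = preset.radius_um
        speed_um_s = preset.swim_speed_um_s
        force_pn = preset.force_pn
    if radius_um is None or speed_um_s is None:
        raise ValueError("need an organism preset or explicit radius and speed")
    f_stokes = stokes_force(radius_um, speed_um_s, fluid)
    f_stated = force_pn if force_pn is not None else f_stokes
    f_d = diffusive_force(fluid)
    return ScalingReport(
        stokes_force_pn=f_stokes,
        stated_force_pn=f_stated,
        diffusive_force_pn=f_d,
        peclet=f_stated / f_d,
    )
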