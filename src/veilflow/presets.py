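"""Organism presets for the two veil-forming microbes.

Both organisms are microaerophilic filter feeders that anchor to surfaces
with a mucous stalk: *Thiovulum majus*, a large sulfur-oxidizing bacterium
driven by ~100 flagella, and *Uronemella*, a ciliate driven by ~100 cilia.
The numbers collected here are the measured single-cell traits used as
defaults throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class OrganismPreset:
    """Single-cell traits of a veil-forming microbe.

    Attributes
    ----------
    name : str
        Preset identifier.
    diameter_um : float
        Cell diameter (along the major axis), micrometres.
    aspect_ratio : float
        Prolate aspect ratio a/b of the cell body (>= 1).
    force_pn : float
        Propulsive force the tethered cell exerts on the fluid, piconewtons.
    swim_speed_um_s : float
        Free-swimming speed, micrometres per second.
    preferred_oxygen_pct : float
        Oxygen concentration at which cells accumulate, in percent of
        air saturation (% atm).
    elongation_rate_um_s : float
        Rate at which the anchored cell's mucous stalk elongates, um/s.
    """

    name: str
    diameter_um: float
    aspect_ratio: float
    force_pn: float
    swim_speed_um_s: float
    preferred_oxygen_pct: float
    elongation_rate_um_s: float

    @property
    def radius_um(self) -> float:
        """Semi-major axis a in micrometres."""
        return 0.5 * self.diameter_um


THIOVULUM = OrganismPreset(
    name="thiovulum",
    diameter_um=8.5,
    aspect_ratio=1.3,
    force_pn=40.0,
    swim_speed_um_s=500.0,
    preferred_oxygen_pct=4.0,
    elongation_rate_um_s=0.65,
)

URONEMELLA = OrganismPreset(
    name="uronemella",
    diameter_um=25.0,
    aspect_ratio=2.0,
    force_pn=50.0,
    swim_speed_um_s=250.0,
    preferred_oxygen_pct=7.0,
    elongation_rate_um_s=1.5,
)

PRESETS: dict[str, OrganismPreset] = {p.name: p for p in (THIOVULUM, URONEMELLA)}


def get_preset(name: str) -> OrganismPreset:
    """Look up an organism preset by name (case-insensitive)."""
    try:
        return PRESETS[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown organism preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
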