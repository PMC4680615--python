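"""Why a filter feeder must exert tens of piconewtons.

The ratio of advected to diffused nutrient flux around a point-forced
cell is Pe = f0 / (8 pi D mu): the force measured against a "diffusive
force" f_d set only by the water viscosity and the oxygen diffusivity.
f_d is about 25 pN, so a ~1 pN swimmer like E. coli cannot stir its own
nutrient field, while both veil formers sit at Pe ~ 2 - just past the
threshold where pumping beats diffusion.
"""

from veilflow.presets import PRESETS
from veilflow.scalings import peclet, scaling_report

print(f"{'organism':<12}{'stokes f (pN)':>14}{'stated f (pN)':>14}"
      f"{'f_d (pN)':>10}{'Pe':>6}")
for preset in PRESETS.values():
    rep = scaling_report(preset=preset)
    print(f"{preset.name:<12}{rep.stokes_force_pn:>14.1f}"
          f"{rep.stated_force_pn:>14.1f}{rep.diffusive_force_pn:>10.2f}"
          f"{rep.peclet:>6.2f}")
print(f"{'E. coli':<12}{'':>14}{1.0:>14.1f}{25.13:>10.2f}{peclet(1.0):>6.2f}")
print("\nPe > 1 means the cell's own flow delivers oxygen faster than diffusion.")
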