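"""Resistance coefficients and critical stalk lengths of the two microbes.

Both veil formers are prolate cells: the bacterium is nearly spherical
(aspect ratio 1.3), the ciliate more elongated (aspect ratio 2).  The
coefficients below normalize the Stokes drag force 6*pi*mu*a*alpha*U and
torque 8*pi*mu*a^3*beta*omega by the semi-major axis a, and Gamma is the
shape factor controlling how the ambient rate of strain twists the cell.
A tethered cell stays upright only if its stalk is longer than
l_c = 4*beta_perp*Gamma*a/(3*alpha_perp) - a fraction of a cell radius
for both organisms, so real 10-100 um stalks are comfortably stable.
"""

from veilflow.presets import PRESETS
from veilflow.spheroid import CellGeometry, DragCoefficients
from veilflow.tether import critical_length

print(f"{'organism':<12}{'a/b':>5}{'a_par':>8}{'a_perp':>8}"
      f"{'b_par':>8}{'b_perp':>8}{'Gamma':>8}{'lc/a':>7}")
for preset in PRESETS.values():
    geom = CellGeometry.from_aspect_ratio(preset.aspect_ratio, preset.radius_um)
    c = DragCoefficients.from_geometry(geom)
    lc = critical_length(c, geom) / geom.semi_major_um
    print(f"{preset.name:<12}{preset.aspect_ratio:>5.1f}{c.alpha_par:>8.2f}"
          f"{c.alpha_perp:>8.2f}{c.beta_par:>8.2f}{c.beta_perp:>8.2f}"
          f"{c.gamma:>8.2f}{lc:>7.2f}")
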