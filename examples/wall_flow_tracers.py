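"""The wall screens a pumping cell - unless it stands on a stalk.

A tethered cell is a point force above a no-slip wall.  The wall's back
flow (image system) cancels most of the pumping if the cell sits at its
own radius; raising the cell on a stalk restores the slow 1/r decay of
an unbounded stokeslet over the feeding range a << r << l.  Tracers
advected in the full (Blake) flow trace the vortex loops seen around
real tethered cells.
"""

import numpy as np

from veilflow.presets import URONEMELLA
from veilflow.wallflow import (
    PointForce, advect_tracers, decay_exponent, total_velocity,
)

a = URONEMELLA.radius_um
f0 = URONEMELLA.force_pn

stalked = PointForce(np.array([0.0, 0.0, 80 * a]), np.array([0.0, 0.0, -f0]))
slope_stalk = decay_exponent(
    lambda r: total_velocity(stalked, np.array([r, 0.0, 80 * a]), mode="blake"),
    2 * a, 8 * a)
attached = PointForce(np.array([0.0, 0.0, a]), np.array([0.0, 0.0, -f0]))
c = np.cos(np.radians(45))
slope_wall = decay_exponent(
    lambda r: total_velocity(attached, np.array([r * c, 0.0, r * c]), mode="blake"),
    10 * a, 100 * a)
print(f"log-log decay of |u|: stalked cell {slope_stalk:+.2f} (stokeslet-like, 1/r)")
print(f"                      wall-height cell {slope_wall:+.2f} (screened, 1/r^3)")

wall_speed = np.linalg.norm(total_velocity(attached, np.array([50.0, 0.0, 0.0]), mode="blake"))
print(f"|u| on the wall (blake image system): {wall_speed:.2e} um/s  (no-slip)")

force = PointForce(np.array([0.0, 0.0, 10 * a]), np.array([0.0, 0.0, -f0]))
starts = np.array([[3 * a, 0.0, 18 * a], [6 * a, 0.0, 14 * a]])
tracks = advect_tracers(force, starts, dt=0.02, duration=4.0)
for tid, tr in tracks.groupby("track_id"):
    xyz = tr[["x_um", "y_um", "z_um"]].to_numpy()
    print(f"tracer {tid}: start ({xyz[0,0]:.0f}, {xyz[0,2]:.0f}) um -> "
          f"end ({xyz[-1,0]:.1f}, {xyz[-1,2]:.1f}) um after 4 s")
print("Tracers sweep down past the cell and recirculate off the wall.")
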