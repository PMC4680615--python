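# veilflow

Low-Reynolds-number hydrodynamics and collective aerotaxis of
veil-forming microbes.

The sulfur-oxidizing bacterium *Thiovulum majus* and the ciliate
*Uronemella* — phylogenetically unrelated — have converged on the same
lifestyle: each cell tethers itself to a surface by a mucous stalk,
pumps water past its body with ~40–50 pN of force, and accumulates with
its neighbours at a preferred oxygen concentration, where the shed
stalks entangle into a centimetre-scale mucous "veil". `veilflow`
implements the single-cell physics that makes this possible and a
synthetic-data + measurement stack for the collective experiments. It
is aimed at biophysicists modelling tethered microswimmers near
boundaries and at anyone who needs a tested reference implementation of
the pieces:

* **Prolate-spheroid resistance functions** (Oberbeck/Perrin closed
  forms) normalized by the semi-major axis: drag `F = 6πμa·α·U`,
  torque `T = 8πμa³·β·ω`, shape factor `Γ = (a²−b²)/(a²+b²)`.
* **Stokeslet image systems** beneath a no-slip wall — the leading
  "image cell" and the exact Blake system — with analytic/complex-step
  gradients giving the ambient (u, Ω, E) a tethered cell feels, plus
  RK4 tracer advection.
* **Tethered-cell orientation dynamics**: the stalk-swing force balance
  and the cell torque balance

      ∂d̂/∂t = [3(Au)⊥ + 4aβ⊥(Ω×d̂) + 4aβ⊥Γ(Ed̂)⊥] / (a(3α⊥+4β⊥)),

  their fixed points, linear stability, phase portraits and basins of
  attraction, and the critical stalk length `ℓ_c = 4β⊥Γa/(3α⊥)` above
  which a tethered cell rights itself (0.26 a / 0.44 a for the two
  organisms).
* **Feeding scalings**: the Peclet number `Pe = f₀/(8πDμ)` comparing a
  cell's advective oxygen supply with diffusion; the diffusive force
  `f_d = 8πDμ ≈ 25 pN` that a filter feeder must beat.
* **Synthetic experiments + measurement pipeline**: stalk-elongation
  tracks, a 2-D oxygen/chemotaxis chamber that forms an aerotactic
  band, Stern–Volmer oxygen imaging (`I = I₀/(1+K_sv·c)`), veil
  scattered-light series — and the stages that re-measure each of them
  (per-track line fits, calibration/inversion, frame differencing,
  front detection, production-rate fits).

## Worked example

Tethered-cell stability for the ciliate preset (aspect ratio 2, cell
radius 12.5 µm, 50 pN) on a stalk of 10 cell radii:

```sh
$ python examples/tether_stability.py
stalk l = 125 um; tau_f = 0.59 s, tau_s = 7.85 s, l_c = 5.5 um (0.44 a)

  t (s)   theta    phi     (radians; both -> 0 as the cell rights itself)
    0.0   0.400  0.100
    7.9   0.024  0.028
   15.7   0.001  0.002
   23.6   0.000  0.000
...
upright fixed point eigenvalues: [-2.57 -0.36] 1/s  -> stable
```

A cell tilted 0.4 rad first aligns with its stalk within ~τ_f, then the
back-flow reflected off the wall (the "image cell") pushes cell and
stalk upright over a few τ_s ≈ 8 s. The two negative eigenvalues
confirm the upright state is attracting; the critical stalk length
(5.5 µm, 0.44 cell radii) is far shorter than real 10–100 µm stalks.

The other examples are one capability each: `drag_coefficients.py`
(the resistance-coefficient table for both organisms),
`feeding_scalings.py` (why Pe ≈ 2 separates these microbes from
ordinary bacteria), `wall_flow_tracers.py` (surface screening: 1/r vs
1/r³ decay, no-slip check, tracer loops), `chamber_front.py` (band
formation at the preferred oxygen concentration, re-measured from the
image stack), `stalk_and_veil.py` (elongation and veil-production
recovery under noise).

There is also a thin CLI for shell use:

```sh
$ veilflow drag-coeffs --aspect 2
aspect  alpha_par  alpha_perp  beta_par  beta_perp  gamma
2       0.60       0.69        0.20      0.38       0.60

$ veilflow synth chamber --preset uronemella --out runs/chamber
$ veilflow measure front --frames runs/chamber/cell_images.tif \
    --oxygen runs/chamber/oxygen_pct.tif
```

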