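# Methods

`veilflow` models the single-cell physics behind veil formation in two
unrelated microbes — the sulfur bacterium *Thiovulum majus* and the
ciliate *Uronemella* — and provides a synthetic-data / measurement stack
for the collective experiments (aerotactic band formation, stalk
elongation, veil accumulation). This note records the models, the
parameter choices and the numerical decisions, and what the synthetic
tests do and do not demonstrate about real data.

## Unit system

All hydrodynamic code works in micrometres, seconds and piconewtons,
with viscosity in Pa·s. This system is exactly self-consistent for
Stokes flow — 1 pN/(Pa·s·µm) = 1 µm/s and 1 Pa·s·µm³/s = 1 pN·µm — so
no conversion factors appear inside formulas and none can be wrong.
Chamber-scale quantities use the units they are quoted in experimentally
(cm, cm²/s, percent of air saturation for oxygen); conversions happen
only at those interfaces.

## Prolate-spheroid resistance functions (`spheroid`)

Cells are rigid prolate spheroids, semi-axes `a ≥ b`. The classical
closed-form resistance functions (Oberbeck/Perrin) are normalized by the
**semi-major** axis: drag `F = 6πμa·α·U`, torque `T = 8πμa³·β·ω`, with
α∥, α⊥, β∥, β⊥ functions of the eccentricity `e = sqrt(1−(b/a)²)`. This
normalization makes every coefficient → 1 in the sphere limit and is
the one under which the catalogued two-decimal values for both organisms
(α∥ = 0.82, α⊥ = 0.86, β∥ = 0.54, β⊥ = 0.65 at aspect 1.3; 0.60, 0.69,
0.20, 0.38 at aspect 2) emerge from the closed forms. The shape factor
`Γ = (a²−b²)/(a²+b²)` controls the rate-of-strain torque.

Numerics: below `e = 0.01` the closed forms cancel catastrophically
(absolute error ≈ 1e−16/e²), so the code switches to their Taylor
series through O(e⁶), whose truncation error is below 1e−16 there; the
two branches agree to ~1e−12 at the switch. Oblate bodies (`a < b`)
are rejected — no veil former is oblate and the oblate branches of the
resistance functions are different formulas.

## Wall flow (`wallflow`)

A pumping cell is a point force (stokeslet) in Stokes flow above a
rigid no-slip wall at z = 0. Two image-system approximations:

* `leading` — a sign-reversed stokeslet at the mirror point ("image
  cell"). This is the far-field approximation used by the tether
  dynamics by default, because the orientation model is itself a
  far-field construction.
* `blake` — the full image system (mirror stokeslet + stokeslet doublet
  + source doublet), which satisfies no-slip on the wall exactly; used
  for sensitivity checks and for tracer advection, where streamlines
  near the wall matter.

Sign convention: a cell with orientation d̂ exerts `−f₀d̂` on the fluid,
so a cell pointing away from the wall pumps fluid toward it, and the
image back-flow pushes the cell away from the wall.

The ambient flow a cell feels is the **image-system part only** (u, Ω =
½∇×u, E = ½(∇u+∇uᵀ)), evaluated at the cell centre: a force-free
body gains no net force or torque from its own unbounded stokeslet.
Gradients of the mirror stokeslet are analytic; the Blake doublet terms
are differentiated by a complex-step derivative (step 1e−200), which is
exact to machine precision and avoids finite-difference truncation.
Finite-size (Faxén) corrections are out of scope — the cell is a point.

Tracer advection uses classical fixed-step RK4 in the total field, with
the wall enforced as a hard floor (the Blake field already vanishes
there; the clamp only guards integrator overshoot).

## Tethered-cell dynamics (`tether`)

State: stalk direction r̂ (anchor → cell), cell orientation d̂, rigid
stalk length ℓ. Two coupled balances:

**Stalk swing.** The net force at the anchor must point along the stalk
(carried as tension): `0 = r̂ × {f₀d̂ + 6πμa A(u − ℓ ∂r̂/∂t)}` with
`A = α∥d̂d̂ + α⊥(I−d̂d̂)`. The component along r̂ is closed by a
Lagrange multiplier (the stalk tension) fixed by `r̂·∂r̂/∂t = 0`,
giving a closed-form rate. With no ambient flow and d̂ ⊥ r̂ the cell
swings along its own axis, so the swing speed is set by the *parallel*
drag: `|∂r̂/∂t| = f₀/(6πμa α∥ ℓ)`.

**Cell torque balance** about the stalk–cell attachment point, three
torques summing to zero: the drag of translating the cell centre on its
arm of length a (`L₁ = a d̂ × 6πμa A(u − a ∂d̂/∂t)`), rotational drag
relative to the ambient vorticity (`L₂ = 8πμa³ B(Ω−ω)` with
`B = β∥d̂d̂ + β⊥(I−d̂d̂)`), and the rate-of-strain torque on the
non-spherical body (`L₃ = 8πμa³ β⊥Γ d̂×(E·d̂)`). Substituting
`ω = (Ω·d̂)d̂ + d̂×∂d̂/∂t` and solving gives

    ∂d̂/∂t = [ 3(Au)⊥ + 4aβ⊥(Ω×d̂) + 4aβ⊥Γ(Ed̂)⊥ ] / (a(3α⊥+4β⊥)),

where `X⊥ = X − (d̂·X)d̂`. Internal consistency is tested by evaluating
L₁+L₂+L₃ at the solved rates (residual < 1e−9 of the torque scale), and
the sphere limit reduces to pure flow alignment `∂d̂/∂t = 3u⊥/(7a)`.
As a → 0 the Ω and E contributions vanish: a small cell only feels the
local velocity.

**Fixed points and stability.** The upright state r̂ = d̂ = ê₃ is a
fixed point by axisymmetry. It is stable iff the stalk exceeds the
critical length

    ℓ_c = 4 β⊥ Γ a / (3 α⊥),

0.26 a for the bacterium and 0.44 a for the ciliate — both far shorter
than real stalks (10–100 µm), so tethered cells right themselves. Two
independent routes to the threshold are exposed and deliberately *not*
reconciled:

* `critical_length` — the closed form above;
* `eigenvalue_crossing_length` — bisection on the leading eigenvalue of
  the finite-difference Jacobian of the reduced (θ, φ) dynamics at the
  origin. For aspect ratio 2 this crossing sits at ≈ 0.29 a, about 0.6
  of the closed form.

The package also carries the single-angle closed form (`polar_rate`)

    t_s ∂θ/∂t = [ (9/16)β⊥aΓ(3+cos2θ) − 3ℓα⊥cosθcosφ ] cos²φ sinθ / (a(3α⊥+4β⊥)),

whose own linearization gives a marginal length (3/4)β⊥Γa/α⊥ = (9/16)ℓ_c.
The three thresholds differ because each drops different couplings (the
single-angle form freezes φ; the closed form ℓ_c comes from the coupled
linearization with far-field image flow). The package treats the full
reduced dynamics as the quantitative statement and surfaces the
discrepancy rather than forcing agreement; all three agree that the
threshold is a fraction of a cell radius, which is the ecological point.

**Integration.** The state is integrated in Cartesian unit vectors
(r̂, d̂) — never in angles — so there is no coordinate singularity at
θ = 0 or π. Adaptive RK45 at rtol 1e−8; the rates are exactly tangent,
and a weak feedback `κ(1−|v|²)v` with `κ = 10/τ_f` (identically zero on
the unit sphere) plus output renormalization keeps norms at 1e−8 over
long runs. The raw pre-renormalization drift is reported
(`Trajectory.max_norm_drift`, ~2×rtol in practice) so the polish cannot
hide integration error. The ambient flow is recomputed from the current
cell position at every right-hand-side evaluation.

**Timescales.** Righting is two-stage: fast alignment of cell with
stalk on `τ_f = 6πμaℓ/f₀` (≈ 0.5 s for a = 10 µm, ℓ = 100 µm, f₀ =
40 pN), then slow righting by the image back-flow `u_s ~ f₀/8πμℓ` on
`τ_s = ℓ/u_s = 8πμℓ²/f₀` (≈ 6 s for the same numbers), with
`τ_f/τ_s = (3/4)(a/ℓ)`. Integrated trajectories reproduce this
ordering; the measured time ratio matches (3/4)(a/ℓ) within a factor ~2
at ℓ = 10a and degrades for much longer stalks, where the slow
eigenvalue is no longer 1/τ_s to leading order.

**Phase portrait.** The dynamics are rotationally symmetric about ê₃,
so coplanar (θ, φ) states stay coplanar and carry the full topology.
The portrait spans θ ∈ [−π, π] (closed, so the wrapped inverted-cell
point is visible at both edges) and the physical band |φ| < π/2 − margin
(beyond it the cell would be under the wall; at |φ| = π/2 the leading
image is singular). Census at aspect 2, ℓ = 10a: one stable point at
the origin; one saddle at (±π, 0) — the inverted cell, reported once;
and two unstable spiral points near ±(1.75, −1.37), where the stalk
lies nearly flat and the cell's height above the wall approaches the
critical length. The basin of the upright state is roughly the strip
|θ| < π/2 with curved corners set by those spirals. Basin membership is
decided by integrating each (sub-sampled) grid point until it comes
within 1e−3 rad of the origin (in), the stalk falls flat (out), or
200 τ_s elapse (undetermined — reported, not fatal). Marginal
eigenvalues (|Re λ| < 1e−10/τ_f) are classified as such rather than
forced into stable/unstable.

## Feeding scalings (`scalings`)

`Pe = f₀/(8πDμ)`: the advective flux `j_a ~ uc ~ f₀c/8πμr` against the
diffusive flux `j_d ~ Dc/r`; the r and c dependences cancel, leaving
the force measured against the diffusive force `f_d = 8πDμ ≈ 25 pN`
for oxygen in water (D = 1e−5 cm²/s, μ = 1e−3 Pa·s). Swim-speed force
estimates use Stokes drag 6πμaU. For the ciliate the Stokes estimate
(58.9 pN at a = 12.5 µm, U = 250 µm/s) and the catalogued rounded force
(50 pN) are both reported; the Peclet number uses the catalogued value
when a preset is given.

## Synthetic data (`synthetic`)

The generators emulate the *statistical structure* of the experiments,
not their microphysics; every stochastic output is reproducible from an
explicit seed carried in its config/metadata.

**Stalk tracks.** Anchored cells drift from a random origin along a
random in-plane direction at a constant rate (0.65 µm/s bacterial
preset, 1.5 µm/s ciliate preset) with isotropic Gaussian localization
noise (0.3 µm default) on every sample; 10 tracks × 30 s at 1 Hz by
default. Real tracks would add slow direction wander and attachment
jitter; neither affects a per-track linear fit at these durations.

**Chamber.** A 1.5 cm square, 128×128 grid. Oxygen obeys explicit
finite-difference diffusion (D = 1e−5 cm²/s) with Dirichlet edges at
100% air saturation (gas-permeable walls) and starts uniform at 100%.
Each of 300 cells removes oxygen as a sink of strength 2e−5 %·cm²/s
smeared over σ = 2 px — a 250 µm/s swimmer sweeps that area between
field updates, and the smearing keeps a cell's self-generated oxygen
hole below a percent (a point sink of the same strength digs a hole of
order (q/2πD)·ln(R/r₀), which at 30× larger q was the dominant artifact
in early designs). Cells do drift–diffusion walks: diffusivity 1e−5
cm²/s, drift `−χ(c−c*)∇c/(|∇c|+ε)` with gain χ = 5e−4 cm/s per %
capped at 25 µm/s (~1% of swim speed, a realistic chemotactic bias);
above the preference they descend the gradient, below it they climb, so
they gather on the c = c* contour. Default duration 24000 s: with 300
desk-scale cells (vs ~10⁶ in a real chamber) depletion takes
proportionally longer than the ~1 h of the wet experiment. Each stored
frame carries the scattered-light cell image *and* the previous step's
image so sequential frame differencing can be exercised exactly as on
the microscope.

What the chamber does **not** model: self-generated fluid flow, cell
attachment/detachment kinetics, veil mechanics, cell division, or any
feedback of the veil on oxygen. Passing the recovery tests shows the
measurement stages are unbiased on a band formed by this mechanism; it
does not validate the chemotaxis strategy of real cells.

**Stern–Volmer imaging.** `I = I₀/(1+K_sv·c)` pointwise (defaults
I₀ = 1, K_sv = 0.05 per % atm — 6-fold quenching at saturation).

**Veil series.** Scattered intensity = rate × (trapezoid-rule running
time-integral of cell count) + Gaussian noise.

## Measurement pipeline (`measure`)

Pure functions; identical inputs give identical outputs.

* `fit_elongation_rate` — per-track OLS slope of displacement vs time,
  measured from each track's first point along the track's principal
  displacement axis (with point tracks, the principal axis stands in
  for the unknown stalk direction; isotropic noise then cannot bias the
  direction). Aggregate = unweighted mean of per-track slopes, matching
  the per-cell presentation of the wet measurement; uncertainty =
  standard error across tracks.
* `calibrate` / `oxygen_map` — two-point Stern–Volmer calibration and
  pointwise inversion after dividing by a saturated reference image,
  which cancels any multiplicative dye-gain field exactly; the forward
  model composed with the inversion is the identity to 1e−12.
* `cell_density_map` — |frame difference| then Gaussian smoothing
  (σ = 2 px): fast-moving cells dominate the time derivative of the
  image.
* `front_report` — front pixels are density above a quantile threshold
  (0.99 default: robust to cell-count changes, unlike an absolute
  threshold); the front concentration is the **median** oxygen over
  front pixels (robust to band-end outliers); the cross-front profile
  bins all pixels by distance to the nearest front pixel, signed by
  whether local oxygen is below or above the front value. The default
  front readout uses the last sequential frame pair only — averaging
  density over widely spaced stored frames smears the slowly migrating
  band and biases the concentration.
* `veil_production_fit` — OLS of intensity change (from the first
  sample) against integrated cell number; R² is the linearity
  diagnostic.

## Problem sizes and defaults

The shipped defaults are desk scale: 128×128 chamber with 300 cells
(seconds per run), 10 tracks × 31 samples, phase portraits on ~15×7
grids with sub-sampled basin integration. All are plain parameters;
larger runs only cost time.

## Known limitations

* The leading-image orientation model degrades when the cell height
  approaches the cell radius (no Faxén corrections, no lubrication);
  the spiral fixed points near the basin corners live in exactly that
  near-wall regime and their precise location should not be
  over-interpreted.
* The three stability-threshold routes (closed form, coupled numerical
  linearization, single-angle form) differ by O(1) factors, as
  expected from their different truncations; the package reports all
  three.
* The chamber walker model has a gradient "dead zone" where oxygen is
  fully depleted and flat; cells that start deep inside it reach the
  band only by slow diffusion. With default parameters this affects a
  small minority of cells and the median-based front readout is
  insensitive to them.
* Elongation tracks are 2-D projections; a stalk tilted out of plane
  would bias a real measurement low, which the generator does not
  emulate.
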