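# Methods

## Model

The package simulates the early regenerative outgrowth of the axolotl spinal
cord as a hybrid two-scale system on a flat strip representing the unrolled
apical surface of the ependymal tube.  The x axis is the anterior–posterior
(AP) axis; the y axis is arc length along the central-canal circumference and
is periodic.  Internally positions use shifted coordinates x ∈ [0, L(t)] with
a fixed wall at x = 0; reported positions are amputation-plane coordinates
z = x − L0.

**Cellular scale.**  Ependymal cells are hard discs of common radius R.  Each
cell carries a non-Markovian cycle clock: a total length T drawn from a
lognormal distribution parameterized by its mean and standard deviation
(slow program: 340 ± 32 h; fast program: 119 ± 10 h) and an age C ∈ [0, T).
A cell divides when C reaches T; one daughter keeps the mother's position,
the other lands at a uniform distance in (0, 2R) and a uniform angle in
(−π/8, π/8) off the posterior-pointing axis.  Both daughters draw fresh cycle
lengths from their program's distribution, and the residual age overshoot
C − T at the step end seeds the new cycle, so division timing carries no
systematic half-step delay.  Divisions create overlaps; non-overlap is
restored by explicit-Euler descent on the pairwise repulsion potential
Φ(r) = 2κR²(r − 1)² (r = distance/2R < 1) until the largest overlap is below
one tenth of a cell diameter.  Tissue length L(t) is the mean x of the front
cells — cells with no other cell posterior of them within a periodic ±R band
in y.

**Signalling scale.**  A regeneration-inducing signal of density ρs obeys

    ∂t ρs = D Δρs − k ρs

on the cell-occupied strip, with ρs = ρ0 on the moving posterior front,
ρs = 0 at the fixed anterior boundary, and periodic y.  It is solved with a
smoothed-particle scheme: the density is carried by equal-mass particles
moved along their regularized density gradient (diffusion velocity method,
v = −D ∇ρ/(ρ + ρ*)), with density and gradient estimated by SPH sums over
the 2D Poly6 kernel of support radius h.  Degradation removes each particle
with probability 1 − e^(−kΔt) per step.  The front condition is enforced
discretely by holding a calibrated particle count in the source strip
[L − 2R, L]; the anterior sink by deleting particles that cross x = 0,
supported by negative mirror images (below).

**Coupling.**  A cell is exposed to the signal only if at least two
particles lie within h of its center; an exposed, non-recruited cell whose
local SPH density exceeds the threshold ρsmin is recruited: irreversibly and
heritably switched to the fast program, shortening its cycle by partially
skipping G1 (age capped at the end of the shorter G1), proportionally
mapping progress through S, and preserving the remaining time to division in
G2/M.  One simulation step applies, in order: diffusion, degradation,
boundary enforcement at the current L, recruitment, division (clock-based or
the Poisson variant), overlap relaxation, observable updates.  Recruitment
precedes division so a newly recruited cell divides on the fast program from
the same step on.

**Poisson variant.**  For theory comparisons the clocks can be replaced by
memoryless division: each cell divides with probability 1 − e^(−νΔt), with
ν = νS (non-recruited) or νF (recruited), νF > νS.  Defaults ν = ln2/mean
cycle length give the same population doubling pace as the clock model.

## Fast reaction–diffusion theory

When signal relaxation is instantaneous relative to division, the profile is
the steady state ρ(x) = ρ0 sinh(x/λ)/sinh(L/λ) with λ = √(D/k), and the
threshold crossing sits at x*(L) = λ asinh((ρsmin/ρ0) sinh(L/λ)).  Cells
posterior of x*(L0) are recruited at once; if the initial condition
satisfies

    νF·LF(0) > νS·LS(0)·√((ρ0/ρsmin)² − 1)/cosh(L0/λ)

then x*(t) stays inside the recruited zone for all t, no further recruitment
occurs, and the two zones grow exponentially:
Ls(t) = (ξ(0)+L0)e^(νS t), Lf(t) = −ξ(0)e^(νF t), with
ξ(0) = x*(L0) − L0.  Outgrowth(t) = Ls + Lf − L0.

The theoretical *recruitment-limit curve* reported by the package is the
slow/fast interface ξ(t) = Ls(t) − L0.  The most anterior recruited cell
sits at that material interface, which pilot comparisons confirm the
simulation tracks within a fraction of a cell diameter, while the threshold
crossing x*(t) itself runs posterior of it in this regime (it equals the
interface only at t = 0).  x* remains available separately.  The growth ODE
integrator (fixed-step RK4, default dt = 0.01 day, on L′ = νS Ls + νF Lf
with instantaneous recruitment projected after each step) covers the general
case in which the inequality fails.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| D | config | μm²/s at the surface (×3600 internally) | free parameter of the signal |
| k | config | 1/day at the surface (÷24 internally) | degradation; half-life ln2/k |
| λ = √(D/k) | derived | μm | D = 0.08 μm²/s, k = 0.1/day give 262.9 μm |
| ρ0 | 60 | signal-density units | front (source) density |
| ρsmin | 3 | signal-density units | recruitment threshold; sensitivity 1/ρsmin |
| ρ* | ρ0/100 | signal-density units | diffusion-velocity regularization |
| h | 4R | μm | SPH kernel support |
| particle mass m | 1 | signal units | ρ0/m is the source number density |
| R | 7 | μm | cell radius (documented placeholder) |
| L0 | 1000 | μm | initial tissue length (placeholder) |
| ymax − ymin | 180 | μm | circumference (placeholder) |
| κ | 1 | — | repulsion intensity; only the fixed point matters |
| μS, σS | 340, 32 | h | slow cycle length (measured) |
| μF, σF | 119, 10 | h | fast cycle length (measured) |
| G1/S/G2M fractions | 0.45/0.40/0.15 slow, 0.20/0.60/0.20 fast | — | placeholders, configurable |
| νS, νF | ln2/340, ln2/119 | 1/h | Poisson-variant rates |
| θ* | π/8 | rad | daughter placement half-angle |

Geometry, source density and phase fractions marked "placeholder" are
configuration defaults, not measured values: the original parameter table
is not reproduced here, and every result in the test suite states the values
it uses.

Initial conditions: cells are thrown uniformly at 1.12× hexagonal packing,
relaxed, and cells pushed past L0 are removed, leaving [0, L0] at a
reproducible near-jammed packing (φ ≈ 0.90–0.96) so divisions translate into
tissue extension from the start.  Initial cycle lengths are slow-program
draws; initial ages follow the truncated exponential with density
∝ 2^(−2C/T) on [0, T).  The printed form of that density integrates to 3/4;
the package normalizes it (shape preserved) and samples by inverse CDF.

## Numerical choices

* **Time step.**  Δt = min(C(2R)²/D, 1/k) with C = 1/2 and the displacement
  bound ΔZ* = 2R, further capped so kΔt ≤ 0.1 and Δt ≤ 0.5 h (division
  events stay resolved when D is small).
* **Displacement limiter.**  The density discontinuity at the vacuum edge of
  the source strip produces occasional velocity spikes on particles the
  boundary step deletes and re-imposes anyway; displacements are clipped to
  2R (direction preserved).  If more than 5 % of particles would need
  clipping the step size is genuinely mis-chosen and the run aborts.
* **Source-strip calibration.**  A uniform strip of width 2R acts, seen from
  the interior, like a Dirichlet boundary at its anterior face.  The strip
  count is therefore scaled by sinh((L−2R)/λ)/sinh(L/λ) so the imposed value
  ρ0 sits at the front line; the factor tends to 1 for λ ≫ 2R.  Degradation
  is skipped inside the strip (its density is re-imposed each step);
  toggleable.
* **Absorbing wall.**  Deleting particles at x < 0 alone cannot sustain the
  continuum boundary flux and lets density pile up anteriorly.  Negative
  mirror images across x = 0 (method of images) restore ρ(0) ≈ 0 and the
  wall-directed gradient; density estimates are floored at 0 in the
  velocity denominator.
* **Relaxation.**  Euler step 0.1R/(4κR), shrunk so no cell moves more than
  0.25R per iteration; iteration cap 10⁵.  Dense random packings can stall
  in frustrated force-balance states; when no progress is made over 2000
  iterations a small seeded jitter (0.05R) breaks the symmetry.  The
  compiled fast path and the pure-python energy-audited path are verified
  to produce identical trajectories.
* **Stable sinh ratios.**  All sinh/cosh ratios and asinh are evaluated in
  log space above argument 30 (λ down to a few μm on mm-scale domains).
* **Units.**  Hours and μm internally; the configuration surface quotes D in
  μm²/s and k in 1/day.
* **Reproducibility.**  One seeded generator per run consumes all stochastic
  draws in a fixed documented order; identical seeds give bit-identical
  observable series.

## Curve error and fitting

The distance between two curves is the trapezoidal time integral of the
squared pointwise absolute difference; references are linearly interpolated
onto the simulation grid.  Recruitment-limit (switchpoint) fitting follows
the convention of expressing positions in millimetres and time in days, on
which the default acceptance tolerance ε = 0.5 mm²·day is a meaningful
scale for mm-amplitude experimental curves.  On μm-amplitude desk-scale
synthetic references that tolerance accepts everything, so the recovery
study in the test suite uses ε = 0.01 mm²·day, chosen a priori from the
theory sensitivity analysis: a 20 % error in λ moves the fast-limit ξ(t)
curve by ≈ 0.08 mm rms (E ≈ 0.05 mm²·day for curves spanning 8 days), while
the seed-noise floor is ≈ 0.001.  ε is exposed everywhere.

The per-animal phase-profile error normalizes each channel's curve error by
the error of that animal's profile against zero and takes the minimum over
channels and animals.

## Synthetic data

No public switchpoint or AxFUCCI dataset ships with the package, so the
calibration module generates stand-ins:

* `synth_switchpoint_curve` — daily samples (days 0–8) of the fast-limit
  theoretical ξ(t) for a chosen λ, in mm, plus i.i.d. Gaussian noise; the
  generating λ is recorded for recovery studies.
* `synth_fucci_profiles` — per-animal G0/G1 and S/G2 spatial fractions from
  a seeded simulation, with binomial finite-count sampling per AP bin; the
  two channels sum to one.

These stand-ins reproduce the *shape* of the experimental files, not their
biology: the switchpoint generator assumes the fast-limit Poisson regime
(the experimental curve is transient-dominated), and the phase generator
inherits the placeholder phase fractions.  Tests that pass against them
demonstrate the machinery (metrics, sweeps, recovery), not agreement with
axolotl measurements.

## Desk-scale study conditions

The validation suite runs on a reduced strip: width 56 μm (= 2h, the
narrowest strip on which single minimal-image kernel sums are exact),
L0 = 400 μm, source number density ρ0/m = 0.25 μm⁻², 5 seeds for the
fast-limit ladder (λ = 41.74 μm, k ∈ {1, 10, 100}/day), 3 seeds for the
threshold sweep ((D, k) = (1 μm²/s, 1/day), ρsmin ∈ {3, 10, 30}, day 6,
with ρ0 = 35 so that all three threshold crossings fall inside the resolved
part of the discrete profile) and
for the recovery sweep (2 × 3 grid in (D, k), λ_true = 107.3 μm).  The SPH
steady-state validation uses L = 500 μm, λ = 100 μm, h = 14 μm and a
1000 h run.  The theory-only checks use λ ∈ [20, 400] μm on L0 = 1000 μm.
Fast-limit comparisons start at t ≥ 3/k, after the signal-establishment
transient: the closed forms are the instantaneous-relaxation limit and do
not describe earlier times at finite k.

## Known limitations

* The deterministic diffusion-velocity scheme under-transports where the
  particle density is sparse relative to the kernel (isolated particles do
  not move) and wherever ρ ≲ 10ρ*; at the coarse particle masses used for
  engine runs this flattens steady profiles on short domains (L ≲ 1.5λ) by
  tens of percent.  The profile validation passes in its resolved regime;
  interface-tracking and monotonicity results are insensitive to the bias,
  but absolute recruitment extents at large λ/L inherit it.
* The 10 % overlap tolerance lets the packing fraction drift slightly over
  long runs, absorbing a few percent of division-driven growth.
* 2D strip geometry, symmetric divisions only, no quiescence kinetics or
  late negative-feedback shutdown of proliferation; the model addresses the
  first ~8 days after amputation.
* The Dirichlet source models a persistently secreting wound epidermis;
  signal identity, transport by tissue flow, and multi-species interactions
  are out of scope.
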