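# Methods

## Physical model and assumptions

The package treats beam-induced radiolysis damage as mediated by an
unspecified diffusing species whose areal density `φ(r, t)` (units u·nm⁻²,
"u" an arbitrary species unit) obeys Fick's second law with a constant,
concentration-independent diffusion tensor in an infinite, homogeneous,
infinitesimally thin 2-D medium.  No boundary conditions are imposed.  The
probe is modelled as a Gaussian source (a good proxy for an airy disc in
the absence of non-round aberrations); its spatial profile always
integrates to one, so changing the probe size redistributes but does not
change the number of species seeded per unit time — consistent with a fixed
beam current.  Probe moves are instantaneous and error-free: no scan-coil
dynamics, hysteresis or flyback are modelled, and no healing or secondary
damage mechanisms are included.

For the instantaneous point source the solution is the anisotropic heat
kernel `Q0 (4π(t−t0))^{−d/2} |D|^{−1/2} exp(−¼(t−t0)⁻¹ drᵀD⁻¹dr)`.  For
continuous sources the closed forms follow by superposition: E1 forms for
the point and Gaussian sources (log forms at the centre), a radial
I0-kernel double integral for the circular disc, and a separable
error-function form with a numerical time integral for the square disc.

A note on units: the rate `Q0` carries u·s⁻¹ for every continuous source.
For the *instantaneous* source dimensional consistency requires a total
amount, so there `Q0` is interpreted as u deposited at the activation
instant.

## Normalisation choices

Two normalisations are fixed by requiring (a) that the isotropic 2-D
instantaneous solution reduce to the standard heat kernel and (b) exact
conservation `Qtot(t) = Q0·min(t−t0, τ)`; both are test-enforced:

* instantaneous-kernel denominator `sqrt(|4πD| (t−t0)^d)`;
* Gaussian spatial profile as the unit-integral density with covariance
  `Ds`: `1/(2π√|Ds|)·exp(−½ rᵀDs⁻¹r)`, the only choice consistent with the
  effective-covariance form `De = Ds + 2(t−t′)D` of the time integral.

## Numerical choices

* **Quadrature.**  Disc/square sources and the anisotropic Gaussian use
  adaptive quadrature, relative target 1e-10 (callers may relax), with the
  modified Bessel factor computed in exponentially scaled form
  (`exp(−(ρ²+u²)/4s)·I0(uρ/2s) = exp(−(ρ−u)²/4s)·i0e(uρ/2s)`) so large
  arguments never overflow.  An absolute floor tied to the source density
  suppresses roundoff churn at far-field points of negligible value.
* **Singular branches.**  E1(0) = +∞; the centre branch of the point and
  Gaussian solutions is dispatched by *exact* coordinate match — probe
  positions sit on simulation-grid nodes by construction, so no epsilon
  comparison is needed.
* **Accumulation engine.**  On the simulation grid (default 10 pixels per
  scan step, field extended 5 scan steps beyond the probe array so boundary
  maxima are not clipped) every probe's field is radially symmetric, and on
  a constant-dwell timeline its elapsed on/off times take only as many
  distinct values as there are probe lags.  Each distinct elapsed-time pair
  therefore yields one 1-D kernel over the unique squared pixel distances
  (cached with nanosecond-resolution time keys) that is scattered into the
  field by index lookup.  This is exact — verified against direct per-point
  evaluation to machine precision.  The only approximation available is a
  conservative whole-event skip when an event's centre value (its maximal
  possible contribution) falls below `eps_rel` (default 1e-9) of the
  running field maximum; a test pins the skip against an exact pass.
* **Temporal sampling.**  `nt = 1` evaluates the CDD at dwell ends only,
  where each probe's own contribution peaks; this is the standard setting
  and a lower bound on the continuous-time maximum.  `nt > 1` subdivides
  each dwell.  The damage integral uses rectangles on the probe-slot grid
  (slot = activation to next activation, half-open to avoid double
  counting) sampled at sub-slot ends; it converges to an independent
  dense-time quadrature as `nt` grows.
* **Damage-map units.**  With the sign activation Λ is a duration (s); with
  ReLU it is u·nm⁻²·s.  The units are reported in the map metadata rather
  than normalised away, since no physical calibration of the species unit
  is attempted.

## Scan timing and hardware semantics

A full scan visits every grid node in trajectory order with slot spacing
`τ + τ̄` (dwell plus settling/blanking).  Subsampling hardware:

* **beam blanker** — the full raster timeline is kept; unselected slots
  elapse with the beam blanked (time passes, nothing is deposited);
* **scan generator** — only selected slots exist, consecutively spaced, so
  acquisition time shrinks from `N(τ+τ̄)` to `M(τ+τ̄)`.

A mask that carries its own visiting order — the linehop pattern is the
canonical case — *is* a trajectory: the probe path touches only selected
pixels, blanking never engages, and both hardware models coincide (tested).
Linehop lanes are scanned one after another, left to right; lane collisions
are resampled up to a retry cap and then shifted deterministically to the
nearest free row.  Both conventions are dialects: the original linehop
hardware reference does not pin them down, and all stated linehop
properties (one pixel per lane per column, hops of at most one row) hold.

The alternating scan of order κ interleaves κ² raster passes over a
κ-decimated lattice, pass offsets in row-major order; κ = 1 reduces to
raster.  Hilbert, Z-order and spiral orders are accepted through the
`custom` trajectory hook but not generated.

## Diffusion-controlled sampling

The designer walks the base trajectory and accepts a candidate only if the
cumulative field of the already accepted probes plus the candidate, at the
candidate's dwell end, stays below the threshold λ at *every* grid pixel.
Accepted dwell ends are exactly the discrete times at which the scheduled
scan's PM-CDD is evaluated, so the designer's running maximum equals the
designed scan's GM-CDD (tested), and by the threshold equivalence the scan
is damage-free.  Rejected candidates are skipped permanently; under blanker
hardware their slot still elapses, under generator hardware no time passes.
The greedy rule is deterministic; the solution is not unique, and candidate
ordering is the only heuristic.  An optional minimum-distance side
constraint can thin the accepted set further.

## Default study conditions

The default configuration is a 20×20 raster scan with 0.05 nm step, 10 µs
dwell, zero settling, `D = 10 nm²·s⁻¹`, `Ds = 0.01 nm²` (0.1 nm probe
radius) and `Q0 = 63.45×10⁶ u·s⁻¹` — a setting representative of imaging a
beam-sensitive zeolite, for which the single-probe maximum is ≈10⁴ u·nm⁻²
and the full-scan deposit ≈253.8 Ku.  Simulation grid: 10 pixels per scan
step, dwell-end sampling, 5-step margin.

Test problem sizes are chosen for speed without changing the physics: unit
and property tests run on 1×1 to 10×10 grids at 4–10 pixels per step; the
acceptance checks run the full 20×20 reference scan.  Where a qualitative
trajectory effect is asserted on a reduced grid, the dwell is lengthened
(100 µs) so the trajectory term dominates the comparison, mirroring the
observation that trajectory effects grow with dwell time.

## What the tests do and do not show

The synthetic scenes exercise the model under its own assumptions —
homogeneous infinite medium, Gaussian probe, perfect instantaneous scan.
Passing tests validate the mathematics and the numerics, not the physics of
any particular specimen: real samples have boundaries, thickness,
concentration-dependent transport, secondary damage channels and scan-coil
dynamics, none of which are modelled.  The damage threshold λ and the
species unit are abstract; mapping them to a measurable damage quantity
requires experimental calibration.

## Known limitations

* 2-D only; no three-dimensional diffusion.
* The online pupil can violate the damage-equivalence precondition at
  pixels never within `rp` of a future probe; the implementation warns
  rather than asserting the equivalence there.
* `nt = 1` underestimates the continuous-time PM-CDD between dwell ends
  (refinable via `nt`).
* The DCS designer is greedy, not optimal; fixed-budget damage-minimising
  design is out of scope.
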