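# Methods

## Model

Under the quasi-static approximation (`∂E/∂t = ∂B/∂t = 0`, `∇·J = 0` —
valid for the conductivities and the sub-100 Hz band relevant to
neural recordings), both **E** and **B** outside the source volume are
gradients of harmonic potentials.  The package represents them in one
shared expansion over vector spherical harmonics,

    F(r) = c [ Σ_lm a_lm ν_lm(Ω) r^-(l+2) + Σ_lm b_lm r^(l-1) ω_lm(Ω) ],

with `ν_lm = −(l+1)Y e_r + ∂θY e_θ + (imY/sinθ) e_φ` (the angular part of
`∇(Y/r^(l+1))`) and `ω_lm = lY e_r + ∂θY e_θ + (imY/sinθ) e_φ` (that of
`∇(r^l Y)`).  The `a_lm` terms converge away from the origin and describe
sources inside the sensor shell; the `b_lm` terms converge toward the
origin and describe distant (interference) sources.  The overall scales are
`c_e = −1/ε₀` and `c_b = −μ₀` (CODATA 2018 constants), applied at synthesis
time; moments themselves are stored scale-free.

Sign convention: the electric potential is synthesized as
`V = −c_e [Σ a Y r^-(l+1) + Σ b r^l Y]`, the unique choice for which
`E = −∇V` holds against the field expansion and a positive point charge
has a positive potential.  Exterior moments follow the same convention
(`b_lm = q Y*_lm(Ω₀)/((2l+1) d^(l+1))` for a point charge at distance `d`;
`b_lm = m·ν*_lm(Ω₀)/((2l+1) d^(l+2))` for a point magnetic dipole, derived
by expanding the dipole's scalar potential about the origin).

### Moments of discrete sources

Volume integrals reduce to sums over point sources:

* electrostatic: `a_lm = 1/(2l+1) Σ_k q_k r'^l_k Y*_lm(Ω'_k)`;
* magnetostatic: `a_lm = i/(2l+1) √(l/(l+1)) Σ_k r'^l_k X*_lm(Ω'_k)·Q_k`,
  with `X_lm = L Y_lm/√(l(l+1))` the unit-normalized tangential VSH.
  `a₀₀` is stored as an exact zero (`X₀₀ = 0`): there are no magnetic
  monopoles, for any current distribution.

The divergence-form magnetostatic integral (kernel `r^l Y* ∇·(r×J)`) is
implemented for closed polyline loops by integration by parts,
`a_lm = I/((2l+1)(l+1)) ∮ r^(l-1) ω*_lm · (r × dl)`, with per-segment
Gauss–Legendre quadrature — exact for the polynomial integrand, so the two
magnetostatic routes agree to rounding on closed loops.  Open polylines are
rejected (they violate charge continuity, and the boundary term would not
vanish).

### Harmonic conventions and pole safety

Orthonormal complex spherical harmonics with the Condon–Shortley phase
(`scipy.special.sph_harm_y`), `Y_{l,−m} = (−1)^m Y*_{lm}`.  The two
apparent `1/sinθ` singularities are evaluated through identities that are
analytically finite at the poles:

* `∂θY` by the same-degree ladder
  `2∂θY_lm = √((l−m)(l+m+1)) Y_{l,m+1}e^{−iφ} − √((l+m)(l−m+1)) Y_{l,m−1}e^{iφ}`;
* `mY/sinθ` by the degree-(l−1) associated-Legendre identity
  `m P_l^m/sinθ = −½[P_{l−1}^{m+1} + (l+m−1)(l+m) P_{l−1}^{m−1}]`
  in normalized form.

Sensors may therefore sit exactly on the z-axis.  Both identities are
verified in the tests against an independently coded Legendre recurrence
and against Cartesian finite differences of the solid harmonics.

## Forward models

**Sarvas field.**  The exterior magnetic field of a current dipole in a
spherically symmetric conductor depends only on the sphere center and the
dipole's tangential part; volume currents are silent.  Implemented in the
standard closed form; radial dipoles and dipoles at the center return an
exact zero.

**M-shell potential.**  The scalp potential of a dipole in concentric
shells is solved per Legendre degree `n`: in each shell
`V = (α u^n + β u^-(n+1)) h_n(r̂)` in normalized radius `u = r/R` (avoiding
under/overflow at `n = 200`), with continuity of `V` and `σ ∂V/∂r` at each
interface and an insulating exterior.  The per-degree 2×2 interface
transfer is solved in closed form from the outside in with a trial outer
coefficient, then rescaled to match the source term
`β₁ = (b/R)^(n-1)/(4πσ₁R²)`; the angular factor
`h_n = n(p·r̂₀)P_n + P_n'(cosγ)(p·r̂ − cosγ p·r̂₀)` is pole-safe and linear
in the dipole moment `p`, so free-orientation gain matrices come from one
pass.  Defaults: 200 degrees (converged to <1e−10 for sources at ≤0.9 of
the innermost radius; verified against 400), and the 4-shell head of radius
91 mm with relative radii (0.90, 0.92, 0.97, 1.00) and conductivities
(0.33, 1.0, 0.004, 0.33) S/m — brain, CSF, skull, scalp.  Electrode
positions are projected radially onto the outer surface, since digitized
positions rarely sit exactly on the model sphere.  The homogeneous-sphere
central-dipole closed form `V = 3p cosθ/(4πσR²)` and the equal-conductivity
reduction serve as oracles.

## Signal space

Basis columns are the per-channel responses to unit moments: field sensors
project the field onto their unit orientation (point projection — pickup
loop geometry is out of scope); electrodes sample `Y/r^(l+1)` (interior) or
`r^l Y` (exterior) scaled by `1/ε₀`, with the reference electrode's own
component subtracted (or the column mean, under average reference).
Magnetic bases omit `l = 0` in both blocks — the interior monopole vanishes
physically and `ω₀₀ ≡ 0` identically — giving `(L+1)²−1` columns per block.

Complex `(l, ±m)` pairs are recombined into real columns,
`(√2·Re, −√2·Im)`, so bases, data and coefficients stay real; recovered
complex moments are `a_lm = (x_c + i x_s)/√2`.  Columns are normalized to
unit Euclidean norm before pseudoinversion (the raw norms span many orders
of magnitude across `l`); the recorded scales convert coefficients back to
physical moments.  A column whose reference subtraction cancels more than
13 digits of its magnitude (the monopole on a single-radius referenced
montage) is treated as the analytic zero it is rather than normalized
rounding noise.  Pseudoinverses truncate the SVD at a relative
singular-value threshold of 1e−8 (configurable).  Sensor noise is not
whitened; a per-channel weighting can be emulated by scaling rows of data
and basis alike.

Default truncation orders: `L_in = 8`, `L_out = 3` for field arrays (80+15
components) and `L_in = 4`, `L_out = 0` for electrode arrays.  The default
origin is a least-squares sphere fit to the sensor positions; a warning is
issued if the origin falls outside the sensor convex hull.

`suppress_interference` refuses when the joint `[S_in S_out]` condition
number exceeds 1e6 (default): for scalar potentials sampled at a single
radius the interior and exterior columns of each `(l, m)` are proportional,
the subspace angle collapses, and the in/out split is not unique.  The
refusal message points to the safe alternative, interior-only low-rank
reconstruction.

`variance_explained` uses Frobenius norms, `100·‖S S⁺ G‖_F/‖G‖_F` —
consistent with summing variance over sources and orientations.

## Applications

**Standardization** is `x̂ = S_in⁺ d`: coefficients on the physical moment
scale, so different montages sampling one field agree (the referenced
monopole is unobservable and excluded from such comparisons).

**Interpolation** estimates moments from the trusted row subset of the same
basis and reapplies the full basis.  The full array's reference
specification is reused for the sub-basis (no re-referencing).  It is exact
when the generating field order is ≤ `L_in` and at least `(L+1)²` good
channels remain; an underdetermined request errors unless forced.

**Calibration** runs coordinate descent over the channels to adjust: for
one channel at a time, moments are estimated from the other N−1 channels
and the channel's assumed position is moved (Nelder–Mead within a ±3 cm
box, with inward/outward radial restarts, fixed sphere-fit origin) to
maximize the variance of its recorded signal explained by its
reconstruction.  The leave-one-out objective is what makes single-channel
position errors identifiable: a misplaced electrode's own row cannot
compensate during estimation, so the objective peaks at the true position.
Moves are kept only when the aggregate leave-one-out explained variance
improves (a non-decreasing trace); sweeps stop below a 1e−4 percent gain
or after 20 sweeps.  Radial errors cost more explained variance than equal
tangential ones — radius enters every interior column as `r^-(l+1)` while
tangential moves stay on the sampled sphere — which is why radial
digitization errors are both the most damaging and the easiest to detect.

**E-field estimation** from two potentials is `−(V₂−V₁)/|x₂−x₁|`, exactly
the path average of the true field component along the separation; it
converges O(Δ) to the pointwise field for one-sided electrode placement.

## Synthetic data

`generate_array` places sensors on a Fibonacci spiral over a spherical cap
(default 120° maximum polar angle, the coverage of a dense cap montage).
Electrode recipes default to 60 channels on an exact 91 mm sphere with the
reference at the cap vertex.  Magnetometer recipes default to a 120 mm
shell with 10% of sensors tilted to tangential orientation and 5 mm radial
scatter: a radial-only single-radius magnetometer array has a rank-deficient
joint basis, and these are the standard symmetry-breaking features that
make the interior/exterior split well conditioned.  All generators are pure
functions of recipe + seed.

`simulate_recording` superposes per-source patterns times waveforms
(10 Hz sinusoids or 1–40 Hz band-passed Gaussian noise at unit RMS by
default — the band where neural signals live), plus optional white sensor
noise.  Interior current dipoles propagate through the conductor model
(Sarvas / shell series) or, without a model, through an order-20 free-space
multipole synthesis.  Exterior interference is modeled as point magnetic
dipoles (for field arrays) or point charges (for electrode arrays) placed
at room scale, meters from the array — where environmental interference
actually resides, and far enough that an order-3 exterior basis captures
it to a fraction of a percent.  Quasi-statics makes moments linear in
source amplitude, so time courses factor out exactly; moments accept a
trailing sample axis when amplitudes genuinely vary.

What the generator does **not** emulate: realistic noise spectra (1/f,
line harmonics), conductor-geometry deviations from sphericity, pickup-coil
flux integration, head movement, or vendor file formats.  Passing tests
therefore demonstrate the linear-algebraic and field-theoretic claims on
ideal spherical geometry, not performance on any particular recording
system.

## Problem sizes and numerical notes

The test and acceptance experiments run at desk scale by choice: 60–150
channels, order ≤ 8 bases, a 7 mm source grid restricted to the 7.5–8.5 cm
shell (~1500 free-orientation dipoles) for the dimensionality experiment,
and 40–256-sample recordings.  The multipole-vs-Sarvas equivalence is
asserted where its own convergence law `(r'/r)^l` supports the tolerance:
0.1% at order 8 corresponds to `r'/r ≈ 1/3` (source at 4 cm, sensors at
12 cm); at `r'/r = 0.58` the same tolerance needs order ≈ 16, and the
implementation converges to the closed form to 1e−7 by order 32.
"Exact zero" claims (magnetic monopole, radial silence) are exact in IEEE
arithmetic for axis-aligned geometry; for arbitrary directions the stored
source vector is itself only parallel to its radius to rounding, and the
moments are bounded by ~1e−13 of an equal-magnitude tangential source.

## Known limitations

* Homogeneous arrays only (one sensor kind per array); combine arrays for
  mixed systems.
* The spherical conductor family only — no BEM/FEM, no anisotropy.
* No temporal-domain extension of the interference separation; purely
  spatial projections.
* Calibration assumes the data are well represented at the chosen order;
  gross truncation error biases the recovered positions.
* Bad-channel *detection* is the caller's job; interpolation repairs a
  given list.
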