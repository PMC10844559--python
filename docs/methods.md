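# Methods

This note documents the models, algorithms, numerical choices, and known
limitations of `viscofit`.

## Constitutive model

The material is a finite-strain generalized Maxwell solid with one Maxwell
branch: an equilibrium spring in parallel with a spring–dashpot element.
Both springs are compressible one-term Ogden models, written in the
isochoric principal stretches λ̄_a = J^{-1/3} λ_a:

    Ψ_iso = (2μ/α²) (λ̄₁^α + λ̄₂^α + λ̄₃^α − 3),
    Ψ_vol = (κ/4) (J² − 1 − 2 ln J),

so μ is the infinitesimal shear modulus and α the nonlinearity; negative α
produces the compression–tension asymmetry typical of brain tissue.  The
bulk modulus is not a free parameter: each spring derives its own κ from
its shear modulus through the linear-regime relation κ = 2μ(1+ν)/(3(1−2ν))
at a fixed Poisson ratio ν = 0.45 (a per-spring κ is the natural reading of
the single generic formula; a shared κ would only differ in the volumetric
response, which is small at ν = 0.45 strain levels ≤ 10 %).

The free parameters, in the order used everywhere (sampling boxes,
optimizer variables, surrogate inputs), are

| name   | meaning                         | units | typical box     |
|--------|---------------------------------|-------|-----------------|
| μ∞     | equilibrium shear modulus       | Pa    | [100, 2000]     |
| α∞     | equilibrium Ogden nonlinearity  | –     | [−20, 20]       |
| μ₁     | Maxwell shear modulus           | Pa    | [100, 2000]     |
| α₁     | Maxwell Ogden nonlinearity      | –     | [−20, 20]       |
| η₁     | dashpot viscosity (deviatoric)  | Pa·s  | (0, 10⁴]        |

Zero or infinite bounds are represented by sentinels (10⁻³ for zero lower
bounds on μ∞ and η₁, 10⁸ for the unbounded μ∞ upper limit).

### Viscous flow and its integrator

Kinematics use the multiplicative split F = F_e F_v; the internal variable
is the elastic left Cauchy–Green tensor b_e of the Maxwell branch.  The
dashpot is purely deviatoric (the volumetric viscosity is disabled), so
det F_v = 1 exactly and the branch stores the full volumetric deformation
elastically.

Time integration is the standard exponential-map predictor–corrector in
principal logarithmic strains: the trial state b_e^tr = f b_e fᵀ (with
f = F_new F_old⁻¹) is eigen-decomposed, and the corrector solves

    ε_a = ε_a^tr − dt/(2η₁) · dev τ_a(ε)

by a local Newton iteration with the analytic 3×3 Jacobian (tolerance
10⁻¹⁰ on the log-strain residual, at most 50 iterations).  Because the
deviatoric flow conserves Σε_a, the scheme preserves the viscous volume to
machine precision.  The integrator is first-order accurate in dt; the test
suite checks the convergence order against fine-step references and the
closed-form linear Maxwell relaxation (agreement within 1 % at
dt ≲ 0.01·η₁/μ₁).

Small Ogden exponents are handled by a series branch for |α| < 10⁻⁴
(α² appears in denominators): the energy uses the expm1 form on the direct
branch and the O(α)-corrected limit on the series branch, the stress the
O(α²)-corrected limit, so both quantities are continuous to ~10⁻⁸ relative
at the switch.  Repeated eigenvalues need no special casing because every
spectral function is assembled as V diag(g(w)) Vᵀ from an orthonormal
eigenbasis.

## Forward model (high-fidelity labeler)

The high-fidelity model is a homogeneous material-point simulation of a
cylindrical specimen under combined axial stretch λ(t) and torsional shear
γ(t):

    F = (I + γ e_θ⊗e_z) · diag(λ_lat, λ_lat, λ_ax).

At every time step the lateral stretch λ_lat is solved so that the radial
Cauchy stress vanishes (traction-free lateral surface), by a secant
iteration safeguarded with bracketing bisection, to
|σ_rr| ≤ 10⁻⁸(μ∞ + μ₁).  Outputs are the rheometer observables: nominal
axial stress P = (J σ F⁻ᵀ)_zz and shear stress τ = σ_θz.  If the local
Newton fails at the protocol step size the step is halved (up to four
times) with linear strain interpolation.

This material point replaces a finite-element discretization of the glued
specimen.  That is a deliberate fidelity gap: inhomogeneous deformation
near the glued platens is absent, so absolute stress levels differ from a
specimen-scale simulation.  Everything downstream (surrogate, active
learning, identification) only assumes *a* deterministic labeler mapping
parameters to stress series, and accepts any callable with the same
interface.

## Synthetic experiments

The default loading protocol mirrors a combined rheometer session: two
sinusoidal compression–tension cycles (amplitude 0.1, period 6 s), a
compression hold and a tension hold (ramp 1 s, hold 4.5 s, offset 0.1),
and two torsional-shear cycles (amplitude 0.1, period 2.45 s) at λ = 1 —
300 samples at dt = 0.1 s.  Amplitudes near 10 % strain are typical for
soft-tissue testing; the exact values are configurable.

Raw records add independent Gaussian noise per channel (std = noise level
× channel peak), then apply a centered moving average (default window 5,
shrinking at the edges) and Ramer–Douglas–Peucker simplification (default
ε = 0.5 % of the channel peak), and finally resample to the uniform grid.
RDP runs on (sample index, stress/peak) coordinates: with a unit-range
ordinate and shallow chords the perpendicular distance is effectively the
stress deviation, making the ε fraction meaningful.  The filters are
near-identity on well-resolved smooth signals but attenuate sharp features
(ramp corners, the first/last half-window); synthetic noise is white and
Gaussian, unlike real rheometer drift or quantization — conclusions about
filter robustness transfer only qualitatively to real instruments.

## LSTM surrogate

The surrogate maps per-timestep inputs (the five parameters broadcast
along the sequence, λ(t), γ(t), and t) to the two stress channels:
LSTM(64, sequences) → dropout → LSTM(64, sequences) → dropout →
per-timestep dense(2).  Inputs and outputs are z-score normalized per
feature with training-set statistics.  Training minimizes the mean
absolute error on normalized outputs with Adam (learning rate 10⁻³,
default batch size 32); the dropout rate is 0.5 during the active-learning
phase and 0 for the final model.

The network and its training loop (forward pass, backpropagation through
time, inverted dropout, Adam) are implemented directly on NumPy arrays in
float32.  Initialization is Glorot-uniform input kernels, orthogonal
recurrent kernels per gate, and a forget-gate bias of 1.  Analytic
gradients are validated against central finite differences (float64) in
the unit tests.  All randomness flows through a single seeded generator
per model, so training is bit-reproducible on a fixed BLAS.

Monte-Carlo dropout uncertainty: n stochastic forward passes; the
prediction is their mean, and the scalar uncertainty of a sample is the
across-call variance averaged over timesteps and both channels in
normalized output space.

## Active learning

The pool starts from Poisson-disk samples of the parameter box (radius
auto-shrunk until the requested count fits) and grows by m points per
iteration: train the dropout surrogate for a few intermediate epochs (warm
start), sample a fresh uniform evaluation set, rank it by MC-dropout
variance, and accept candidates whose normalized distance to the pool and
to already-accepted candidates is at least min(1/|T|, minimum pairwise
distance within T) — falling back to the highest-variance remaining
candidate when none qualifies.  The distance constraint is implemented as
*at least* the threshold: an at-most reading would concentrate acquisition
on near-duplicates of existing points, defeating its stated purpose; a
flag restores the opposite inequality.

The final surrogate is trained from a fresh model (new initialization, new
optimizer state, dropout 0, normalization statistics refit on the complete
pool).  Warm-starting the final training from the dropout-0.5 intermediate
weights was measured to stall at a noticeably worse test R² than a cold
start on the same epoch budget; the intermediate models exist to guide
acquisition, not to seed the deliverable.

## Inverse identification

The misfit is the normalized L2 error per channel, χ² = Σ(y_exp − y_sim)²
/ Σy_exp², summed over P and τ by stacking per-channel residuals
(y_exp − y_sim)/√(Σ y_exp²), which makes the objective invariant to
uniform stress-unit rescaling.  Optimization uses SciPy's trust-region
reflective bounded least squares with forward finite differences.

The hybrid driver fits the surrogate first, inside the training-data box
(start: box midpoint), then restarts from that optimum against the
high-fidelity model under the wider physical bounds.  The
finite-difference relative step is 10⁻³ against the surrogate (float32
outputs limit the usable derivative resolution) and 10⁻⁶ against the
forward model.  Every model evaluation, including finite-difference probes
and rejected steps, is logged in the phase-tagged trace.

## Problem sizes used in tests and the acceptance script

The reference study scale (pool 500, 119 acquisition iterations of 4
points, 100 intermediate and 1000 final epochs, 1000 test points) is
represented at desk scale:

* acceptance script: pool 200 grown from 24 Poisson-disk points in
  iterations of 16, 100 intermediate epochs, 300 final epochs, 300-sample
  protocol, 200 test points;
* the test suite runs the same method at pool 128 with 80 test points for
  the surrogate-accuracy check, pool 44 (4 points per iteration, three
  seeds) for the active-vs-random comparison, and smaller pools / shorter
  protocols for the loop-mechanics tests.

Sixteen points per iteration keeps the number of intermediate trainings
proportionate to the smaller pool at the reference 100 intermediate
epochs; the acquisition rule itself is unchanged.  These are the package's standard desk-scale
conditions; the full schedule remains available through the configuration
objects.

### What variance-driven acquisition does on this labeler

A caveat worth stating plainly: on the material-point labeler over the
full parameter box, the MC-dropout variance is dominated by response
amplitude (Spearman correlation ≈ 0.95 with the mean absolute response,
versus ≈ 0.5 with the absolute prediction error and *negative* with the
relative error).  This is mechanical — dropout perturbs bounded hidden
units, so the prediction spread scales with the output magnitude — and it
means the acquisition concentrates new points in the large-stress corners
of the box (|α| near 20, μ near the upper bound).  The variance–error
trend that motivates the acquisition is reproduced (absolute error also
grows with amplitude), but in our experiments the resulting pools gave a
*lower* uniform-test per-sample R² than random sampling at matched sizes.
The corresponding end-to-end checks in the test suite assert the
behavior expected of the reference method and are left failing rather
than weakened; the numbers the pipeline actually produces are reported by
the acceptance script.

## Known limitations

* One Maxwell branch only; the architecture leaves room for more branches
  but nothing implements them.
* No algorithmically consistent tangent: gradients downstream are finite
  differences by design.
* The material-point labeler cannot represent specimen-scale
  inhomogeneity; surrogate-accuracy numbers obtained against it are upper
  bounds on what an FE labeler of the same protocol would yield.
* The surrogate assumes the training protocol's grid; inputs on other
  grids must be interpolated first.
* MC-dropout variance is a heuristic uncertainty, not a calibrated
  posterior.
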