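# Methods

## Model and scope

`glvflux` implements the generalized Lotka–Volterra (GLV) system
dN_i/dt = N_i (r_i + Σ_j a_ij N_j) together with a biomass/energy budget
layered on top of the dynamics. The budget has three ingredients: a
prescribed C¹ total-biomass function M(t); per-species trophic functionals
τ_i(t) = (1/t) ∫₀ᵗ p_i N_i dμ_t weighting the history of the effective
trophic potential p_i = m̄_i k_i against a measure family μ_t on [0, t]; and
the derived quantities R = M − Σ τ_i (abiotic reservoir) and
Y = d/dt[M − R] = Σ dτ_i/dt (net energy flux between the surroundings and
the reservoir). m̄_i (mean individual biomass) and k_i (relative trophic
strength) enter every formula only through their product, so the library
houses only p_i; a convenience constructor taking the factors separately
would add state without behavior and is deliberately omitted.

Units: abundances are individuals, p_i is mass per individual, τ_i, M and R
are masses, Y is mass per time. The framework treats mass and energy flow on
a single scale and does not attempt a caloric conversion.

## Integration in log-abundance coordinates

Solutions started in the open positive orthant stay there while they exist.
To make that invariant exact numerically, the integrator works in
x_i = log N_i, with dx_i/dt = r_i + (A e^x)_i, using SciPy's adaptive
explicit Runge–Kutta DOP853 at rtol 1e-9 / atol 1e-11 by default. Blow-up
(possible for matrices with positive feedback) is detected by a terminal
event at x_i = 700 — near the double-precision overflow point — and surfaces
as an error carrying the last valid time, never as a silently truncated
trajectory.

The running integrals cumN_j(t) = ∫₀ᵗ N_j ds are carried as additional ODE
states in the same solve rather than recovered afterwards by quadrature.
This choice is load-bearing for the conservation law below: the quantity
x_i − r_i t − (A·cumN)_i is a *linear* combination of integrated states whose
stage evaluations coincide inside every Runge–Kutta step, so any RK method —
and its dense-output interpolant — preserves it to roundoff, independent of
tolerances. A trapezoid-rule cumulative integral on the output grid is still
available (`cumulative_abundances`) and agrees with the solver-carried one to
O(dt²); it is the declared quadrature rule for everything downstream
(trophic and flux series), so their errors share one budget.

## Trophic functionals and their derivative

Density-kind measures are specified by a kernel w(t, s) ≥ 0 with w(t, t) > 0
and its analytic time derivative; the built-in Gaussian kernel is
w_t(s) = exp(−a (s−t)²) with a ≥ 0 (a = 0 is the flat, uniform-history
limit). User kernels without an analytic derivative fall back to a central
finite difference with step 1e-6 (1 + t) and are flagged. The functional is
evaluated by composite trapezoid on the trajectory's own output grid
restricted to [0, t]; for off-grid t the endpoint value of the integrand is
taken from a cubic spline. At t = 0 the 1/t prefactor is resolved by the
prefix-average limit, τ_i(0) := p_i(0) N_i(0) w(0, 0).

The total derivative of the density-kind functional is the three-term
expression

    dτ_i/dt = −(1/t²) ∫₀ᵗ f_i w_t ds
              + (1/t) [ f_i(t) w_t(t) + ∫₀ᵗ f_i ∂w_t/∂t ds ],

with f_i = p_i N_i, evaluated with the same trapezoid nodes as the
functional so that the two stay mutually consistent; a central finite
difference of the functional reproduces the formula to better than 1e-4
relative (in the per-time vector max-norm) at mid-trajectory times on smooth
fixtures. The `quad_refine` knob inserts k cubic-interpolated midpoints per
grid interval into the quadrature node set — at refine 7 the residual
formula-vs-difference gap on the packaged fixtures drops to a few 1e-5 —
without changing the ODE grid. In the flux series, the t = 0 derivative
(where the prefactor is singular) is filled by linear extrapolation from the
first two interior points and should be treated as cosmetic.

Dirac-kind measures (μ_t = t δ(t−s), mass fully inside [0, t]) reduce the
functional to τ_i = p_i(t) N_i(t); its derivative uses the chain rule with
dN/dt from the GLV right-hand side and the analytic total derivative of p
when the weights supply one (the exponential weights do), falling back to a
finite difference along the trajectory otherwise.

## The conserved memory-free regime

With the exponential potential p_i = exp(−r_i t − Σ_j a_ij cumN_j) and the
Dirac measure, dp_i/dt = −(r_i + (A N)_i) p_i cancels the GLV growth exactly,
so τ_i ≡ N_i(0) and Y ≡ 0 along every trajectory: the memory-free system has
nontrivial dynamic equilibria. Because cumN is an ODE state (see above), the
implementation reproduces this conservation to ~1e-14 relative over several
orbit periods, rather than to quadrature accuracy. In tests of the vanishing
flux, the natural tolerance scale is the magnitude of the two cancelling
chain-rule terms, max |p_i dN_i/dt| — the computed dτ_i/dt values themselves
are roundoff-level, so normalizing by them would be meaningless.

For absolutely continuous measures the opposite holds: Y vanishes
identically only on the trivial (extinct) trajectory. The package checks
this dichotomy numerically (`memory_equilibrium_diagnostic`) with
fixture-specific positive flux floors taken from reference runs, and it
exposes a Picard-iteration oracle for the underlying Volterra equation
φ(t) = ∫₀ᵗ φ K(t, s) ds: iterate sup-norms for the unit kernel follow 1/k!
exactly, and for the Gaussian equation-of-motion kernel
K = (w_t(s)/t − ∂w_t/∂t)/w_t(t) they decay to zero super-exponentially —
but only after a plateau of roughly thirty iterations, because K ~ 1/t is
unbounded near t = 0 and the textbook contraction bound (sup|K| T)^k / k!
does not apply. The decay confirms triviality; its onset is slow.

## Harmonicity constraint and conic analysis

Treating (t, N_1, …, N_n) as independent coordinates, the Laplacian of the
exponential potential reduces to its second time derivative,
Δp_i = [(r_i + (A N)_i)² − (A Ṅ)_i] p_i. Requiring Δp_i = 0 for all i and
substituting the GLV right-hand side yields the quadratic phase-space
constraint

    Σ_i [ r_i² + Σ_j a_ij (2r_i − r_j) N_j + Σ_jk a_ij (a_ik − a_jk) N_j N_k ] = 0,

stored as (γ₀, L, Q) with Q symmetrized (the raw asymmetric matrix is kept
for oracle comparisons). Two exact algebraic facts are property-tested: the
summed normalized Laplacian residual equals the constraint value at any
state, and the constraint vanishes identically at every interior equilibrium
(both brackets vanish there).

For n = 2 the constraint is a conic. Its normalization constant 𝒦 is chosen
as r₁² + r₂² whenever positive — making the constant coefficient c₆ = −1 —
with fallback 𝒦 = 1; the choice is a convention (only the curve's zero set
matters) and the classification uses the 𝒦-independent discriminant
D = cross² − 4 q₁₁ q₂₂ of the unnormalized quadratic part with the
scale-aware tolerance 1e-12 (1 + max q²). D reduces algebraically to the
perfect square [a₁₂(a₁₁−a₂₁) − a₂₁(a₂₂−a₁₂)]², so the constraint conic is
degenerate/parabolic (exactly so for zero-diagonal matrices) or hyperbolic,
never elliptic — closed elliptic orbits in the phase portrait are a property
of the GLV flow, not of this curve. A nested one-line form of the conic with
coefficients attached to mixed linear/quadratic groupings circulates in
discussions of this constraint; it does not expand consistently with the
coefficient definitions above, so the canonical (γ₀, L, Q) form is the
ground truth here and the c-coefficients are reported alongside verbatim.
The constraint curve can be sampled for plotting by dense grid signing
(midpoints of sign-changing grid edges), which needs no contouring library.

## Phase-portrait analysis

Period detection uses a Poincaré section: the vertical line N₁ = N₁*
through the coexistence equilibrium, restricted to the N₂ > N₂* branch and
to one crossing direction, with sub-grid crossing times from linear
interpolation. An orbit counts as closed when the state-space gap between
successive returns is below 1% of the orbit diameter (no standard criterion
exists; this one is scale-free and robust for planar centers). Cycle
averages are trapezoid means over exactly one detected period with the
endpoint interpolated; for a closed orbit any one-period window gives the
same answer, so the window starts at the trajectory's first section return
(or at t = 0 when the caller supplies the period directly). Escape detection
fires when any abundance exceeds 10⁶ times its initial value or drops below
the positivity floor 1e-12; fixed points are declared when the orbit
diameter is below 1e-8 relative to the initial state. All three thresholds
are module constants.

A caution from development: flipping the signs of *all* rates and
interactions of a zero-diagonal predator–prey pair is exactly time reversal,
so it produces the same closed orbits, not divergence; genuinely open orbits
for testing come from competitive systems whose interior equilibrium is a
saddle (e.g. r = (1,1), A = ((−1,−2),(−2,−1))), where trajectories run to
the boundary and trip the positivity floor.

## Scenario taxonomy and deadband

Each grid time is labeled from the sign triple (Y, M′, R′): for Y > 0 the
labels a/b/c (reservoir and populations both fed; inflow plus reservoir
drawdown; populations fed by a depleting reservoir, accepted with M′ ≤ 0),
for Y < 0 the labels d/e/f, for Y = 0 the labels g/h and "null" for the
fully steady triple; sign triples inconsistent with Y = M′ − R′ outside the
deadband map to "mixed" rather than to a neighboring label. Signs use a
deadband ε, by default 1e-9 times the larger of max|Y| and the mean trophic
turnover max|Στ|/span. The turnover floor matters in the conserved regime,
where Y is pure roundoff: a deadband relative to max|Y| alone would classify
that noise as signal, while the floor is still orders of magnitude below any
real flux.

## Fixtures and seeding

The built-in study systems double as the synthetic-data generators for the
test suite. `wolf_rabbit` is the packaged two-species preset with
coexistence equilibrium (1000, 80), eigenfrequency 0.2 at the equilibrium,
run from the displaced state (1500, 60); the classical sources for this
system print only the equilibrium and cycle averages, so the rate constants
r = (0.08, −0.5), A = ((0, −0.001), (0.0005, 0)) are the minimal
zero-diagonal reconstruction with that equilibrium, and the preset is
flagged as a reconstruction in its docstring. `random_center` draws
zero-diagonal antagonistic pairs (prey growth and predation/conversion rates
uniform on ecologically moderate ranges, initial states displaced 5–40% from
equilibrium); `random_stable` draws three-species competitive communities
with diagonally dominant negative interaction matrices and rates constructed
so a prescribed positive state is the equilibrium, rejecting draws whose
equilibrium is not linearly stable; `extinct` starts the preset model at
1e-15 individuals. One root seed feeds all fixtures; each kind derives its
substream as default_rng([seed, kind_code]) with a fixed per-kind code, so
adding kinds never perturbs existing draws.

What the generators emulate — smooth deterministic GLV trajectories with
exactly known equilibria, centers and saddles — is what the framework's
theorems address. They deliberately omit demographic noise, environmental
stochasticity, measurement error and model misspecification, so passing
tests certify the mathematics and the numerics, not robustness of the
budget accounting on noisy field data.

## Problem sizes and numerical defaults

Default output grids use dt_out = 0.01–0.02; the cycle-average and period
results use a 120-time-unit window (≈ 3.5 orbit periods, 12001 grid points),
density-measure flux series use 2000–4000-point grids (the series sweep is
O(G²)), and the Picard oracle uses 2048 uniform points. These sizes put
every headline quantity far inside its tolerance; halving the step changes
detected periods by well under 0.1% and trapezoid quantities by the expected
O(h²).

## Known limitations

Only density and Dirac measure families are supported — general Borel
measures and endpoint half-mass conventions are out of scope, as is symbolic
verification of the regularity hypotheses (uniform integrability of the
kernel family is a documented user obligation for custom kernels). The
budget-route flux Y_budget, a finite difference of the Στ series, is
ill-conditioned near t = 0 where the density-kind τ varies as 1/t; the
formula route Y_sum is the reference, and the two agree to better than 1e-3
of the flux scale away from the initial transient, with the gap shrinking as
O(h²) under refinement. Stochastic dynamics, spatial structure, parameter
inference, bifurcation/limit-cycle continuation and multi-reservoir budgets
are out of scope.
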