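# Methods

## Forward model

The specimen is modelled as a biphasic mixture: an intrinsically
incompressible porous elastic solid saturated by an incompressible
fluid. Transient load response arises from fluid flow through the
matrix. The solid is the Holmes–Mow exponential hyperelastic law
(parameters: modulus E in kPa, Poisson ratio ν, nonlinearity β), the
permeability is the Holmes–Mow strain-dependent form (strain-free
permeability k₀ in mm⁴ (N s)⁻¹, exponential coefficient M, power-law
exponent α, strain-free porosity φ₀ʷ), and the matrix carries fixed
negative charges producing a Donnan equilibrium osmotic pressure
(strain-free fixed charge density FCD₀ in mM, osmotic coefficient Φ)
against a bath of osmolarity c* = 300 mOsm at T = 294 K. Anisotropy is
deliberately excluded: lateral confinement prevents transverse tensile
strain, which minimizes its influence in this protocol.

The volumetric term of the Holmes–Mow exponent is implemented as
−ln(J²) = −2 ln J, the canonical form, under which the energy grows in
compression. A `log_squared` switch evaluates the −(ln J)² variant for
sensitivity checking; it softens rather than stiffens the volumetric
response and is not the default.

In-situ osmotic prestrain is parametrized by the initial swelling
fraction f₀ ∈ [0, 1]: given the free-swelling equilibrium strain ε_fs
(solved from zero total axial stress under isotropic stretch, bracketed
root find with residual below 10⁻⁶ kPa), the test starts from the
isotropic stretch λ₀ = 1 + f₀ ε_fs. The reference mesh height is
pre-scaled by (1 + f₀ ε_fs)⁻¹ so the swollen initial height always
equals the nominal 1.1 mm.

## Confined-compression simulator

Confined compression with a free-draining bottom face is one-dimensional
through the thickness: F = diag(λ₀, λ₀, λ_z(Z, t)) with λ₀ fixed.
Quasi-static momentum balance makes the total axial stress
σ(t) = σ_e(λ_z) − p_f spatially uniform, where σ_e is the solid stress
(elastic minus osmotic) and p_f the excess fluid pressure. Substituting
p_f = σ_e − σ into the referential fluid mass balance yields a single
nonlinear diffusion equation in λ_z, closed by the prescribed platen
displacement through the constraint ∫λ_z dZ = h(t). Discretization is
vertex-centred finite volumes (default 21 nodes; the three-level
factorial ensemble uses 11 nodes after a grid-convergence check) with
arithmetic-mean interface mobilities, backward-Euler time stepping, and
Newton iteration on nodal λ_z plus the scalar σ. The Jacobian is the
analytic tridiagonal stress-stiffness with lagged mobilities, solved by
a bordered Thomas algorithm; steps are damped to keep the pore space
open (J > 1 − φ₀ʷ) and halved adaptively on divergence (up to 14
halvings). Convergence demands a scaled residual below 10⁻¹⁰ (stress
rows scaled by the aggregate modulus, the constraint row by the
reference height), which realizes the prescribed displacement to well
below the 10⁻⁶ mm adherence tolerance. Every protocol output time is an
enforced solver step. The kernels are numba-compiled; a simulation costs
about a millisecond, which is what makes the 59 049-run factorial study
routine. Identical inputs give bit-identical outputs.

Units are kPa–mm–s; concentrations in mM (numerically mol m⁻³) with
R T c evaluated in Pa and converted to kPa; because the permeability
carries mm⁴ (N s)⁻¹, a factor of 10⁻³ accompanies every product of k
with a kPa stress gradient. The reported force is F_z = −σA (A = π·2²
mm²), compressive reaction positive, in N.

Verification: (i) work conjugacy — the closed-form Cauchy stress matches
central differences of the strain energy to 10⁻⁵ relative over random
admissible states; (ii) linear limit — for small β, constant
permeability and no charge, simulated F_z matches the classical linear
biphasic consolidation series solution within 1 % of the peak force at
all 72 output points (0.25 % increments keep kinematics linear; 101
nodes, 8 substeps per output interval); (iii) long-hold equilibrium
matches a 0-D root find on the uniform stretch to 0.5 %; (iv) grid
refinement differences decrease monotonically.

## Protocol and study conditions

Geometry and loading follow the standard incremental stress-relaxation
experiment: initial height 1.1 mm, diameter 4 mm, three increments of
5 % compression relative to initial height, 9 equally spaced output
points per ramp (excluding the ramp start) and 15 log-spaced points per
hold, the first at hold/1000 past the ramp end. Ramp and hold durations
are protocol choices, not physical constants; the defaults are 60 s and
2700 s, the hold chosen near the characteristic diffusion time
h²/(H_A k₀) at the range midpoints so relaxation is well developed.
Absolute force levels and peak/equilibrium ratios depend on these
timings, and so, weakly, do the identifiability statistics (we measured
the constrained-direction counts to be stable over ramps of 10–300 s and
holds of 900–10 000 s).

Default parameter ranges (the sampled space Θ): E ∈ [130, 470] kPa,
ν ∈ [0, 0.3], β ∈ [0.04, 0.5], k₀ ∈ [1, 20]×10⁻⁴ mm⁴ (N s)⁻¹,
M ∈ [1.7, 5.8], α ∈ [1, 2], φ₀ʷ ∈ [0.6, 0.87], FCD₀ ∈ [120, 315] mM,
Φ ∈ [0.9, 1.0], f₀ ∈ [0, 0.5] — plausible ranges for cartilaginous
tissue (endplate-like), consumed as given. Scaling to [0, 1] is affine
per coordinate (0 = min, 1 = max).

## Global analysis

Full factorial sampling with three equally spaced levels per parameter
(59 049 samples) spans Θ including parameter interactions. Each
simulation passes automatic protocol-adherence checks (all output times
present, displacement realized to 10⁻⁶ mm, all solves converged,
invariants respected); failures are excluded from all downstream
statistics and logged with reasons — under the default conditions a few
hundredths of a percent of samples, concentrated at extreme corners of
Θ. Per time point, the Pearson correlation between each parameter and
F_z forms that parameter's correlation vector. On a balanced factorial
with no exclusions the correlations are computed from integer level
codes (an exact affine relabelling) with level-by-level accumulation, so
a parameter without influence gets exactly zero correlation; zero
variance yields ρ := 0 by convention. Vectors are clustered by UPGMA on
unsigned cosine distance d = 1 − |cos| (a sign-flipped effect is the
same effect for identifiability purposes); leaves are sorted
lexicographically before linkage so ties break deterministically.
Linear combinations of effects are assessed by SVD of the P×T
correlation matrix: eigenvalues are the squared singular values
(variance associated with each left-singular direction in parameter
space), normalized to percent of their sum, with directions above 1 %
counted as constrained. Because it is genuinely ambiguous whether such
spectra should be read as singular values or their squares, both are
computed (`use_squares`); the squared reading is sharper (small
directions become quadratically smaller) and is the default. The two
readings differ in how many directions clear a fixed 1 % threshold —
the squared reading roughly halves the count — which is a reminder that
the threshold is an interpretive device, not physics; both readings
agree that well under half of the ten directions are constrained.
First-order and total sensitivity indices come from the exact factorial
ANOVA decomposition (equal-weight level means); if exclusions break the
balance the indices are still computed and flagged as biased.

## Local analysis

The cost j(θ; θ*) = Σᵢ (f(θ)ᵢ − f(θ*)ᵢ)² is evaluated in scaled
coordinates with exactly rounded compensated summation (`math.fsum`,
Shewchuk's algorithm). Its Hessian at θ* uses central differences with
fixed step h = 0.01 scaled units: diagonal from {θ*, θ* ± h eᵢ},
off-diagonal from the four-point cross stencil, 1 + 2P + 2P(P−1)
distinct evaluations (201 at P = 10), cached so shared points are
computed once; coordinates within h of a bound fall back to flagged
one-sided stencils. A step-size sweep over 10⁻⁸–10⁻² exposes the
condition-error (∝ h⁻²) and truncation-error regimes via a
neighbouring-step deviation metric and recommends the step minimizing
it. The eigen-spectrum of the symmetrized Hessian is read against a
noise floor (default 10⁻², configurable): by the Bauer–Fike theorem a
Hessian error of magnitude ε can move eigenvalues by a comparable
amount, so smaller eigenvalues — including the spurious negative ones
that make the stationary point look like a saddle — are
indistinguishable from zero curvature. Because the bundled solver is
deterministic with tight tolerances, its effective noise floor is far
below 10⁻²; the default floor is kept as a conservative, transferable
setting for noisier forward models (a production finite-element solver
will sit near it), and the report always prints the full spectrum
against the floor rather than hiding sub-floor values. Consequence: the
local analysis typically resolves a few more directions than the global
1 %-threshold count here, so the two should be compared as orders of
magnitude, not matched direction for direction.

## Optimizer diagnostics

Ten ground truths are drawn uniformly from Θ (seeded; truths whose
simulations fail adherence are resampled and logged), noise-free F_z
data are simulated, and each data set is fitted in scaled coordinates
with box bounds [0, 1]^P by (a) Nelder–Mead and (b) a bound-constrained
trust-region method, started from an independent uniform draw. Both use
`scipy.optimize.minimize`; Nelder–Mead runs with scipy's stock options
(xatol = fatol = 10⁻⁴, non-adaptive, 200 evaluations per parameter) and
projects out-of-bounds vertices onto the box, the trust-region method
uses forward-difference gradients with absolute step 10⁻⁴; all
tolerances and budgets are configurable. Every accepted iterate and its
cost are recorded (costs are looked up from the evaluation cache, so
recomputing the cost at a recorded iterate reproduces the recorded
value), and traces persist as .npz + JSON. The error report gives each
parameter's median |θ̂ − θ*| across runs against two baselines: 10 % of
the range, and the expected error of a uniform random guess,
E|U − V| = 1/3. The characteristic non-identifiability signature — SSE
driven several orders below the data scale while some parameter errors
remain at tens of percent of range — is robust across seeds; the
sharper statistic "minimum over parameters of the median error" sits
near the 10 %-of-range line and fluctuates with the random truth set,
with the strongly correlated permeability k₀ usually the best-recovered
parameter.

## Synthetic data and what the tests show

All test data are generated by the bundled simulator; there is no
external data. The generator reproduces the structure of a real
experiment (prestrain, ramp/hold transients, osmotic offsets) but not
its imperfections: no measurement noise, no specimen-to-specimen
geometry variation, no model discrepancy — the fits are inverse crimes
by construction, which is exactly the point: identifiability failures
demonstrated here are intrinsic to the model/protocol pair and can only
be worse with real data. Passing tests therefore certify the numerics
and the analysis machinery, not that any real specimen follows the
model.

## Degenerate inputs and tie-breaks

FCD₀ = 0 gives identically zero osmotic pressure and ε_fs = 0; α = M = 0
gives constant permeability (α below the sampled range is allowed solely
for linear-limit verification); zero-variance parameters get ρ = 0 and
distance 1 to all others in clustering, flagged "no direct effect";
UPGMA ties break lexicographically; SVD of an all-zero correlation
matrix yields all-zero normalized percentages. The strain energy uses
`expm1` so the small-β limit does not cancel catastrophically.

## Limitations

The simulator is strictly 1-D: it cannot represent lateral compliance of
the confinement chamber, friction, imperfect drainage or indentation
protocols. Counts of "constrained directions" are threshold- and
convention-dependent (see the global analysis section) and depend on
protocol timing through the degree of relaxation per hold; they should
be read as "about this many of ten", not as sharp integers. The
trust-region method's finite-difference gradients make it expensive and,
on this cost landscape, no more informative than the simplex method.
Marquardt-type least-squares optimizers are not included.
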