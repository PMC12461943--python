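# Methods

This note documents the model implemented by `mcgw`, its assumptions, the
numerical choices that are not forced by the equations, and what the test
fixtures do and do not probe.

## Scope and assumptions

The package treats gapped, closed-shell, spin-restricted references with
real orbitals; occupation is exactly 2 per occupied spatial orbital.  All
internal quantities are in Hartree; eV appears only in reporting (factor
27.211386245988).  Unrestricted or complex references, periodic systems,
finite-temperature (Matsubara) formulations, and Bethe–Salpeter extensions
are out of scope.  The reference bundle carries the exchange and
exchange-correlation potential matrices so that the static self-energy
Σ∞ = K[D] − V_xc is well defined; for a canonical Hartree–Fock reference
both vanish and Σ∞ = 0.

## Screening models

The particle-hole response is characterized entirely by the moment
intermediates η̃^(n) (auxiliary × particle-hole).  The restricted-spin
factor of 2 lives inside the equation-of-motion blocks A = D + 2VᵀV and
B = 2VᵀV, never inside the interaction tensor itself, so one convention
source feeds both the recursive pipeline and the dense oracles.

* **TDA** (B = 0): η̃^(0) = V and η̃^(n) = η̃^(n−1) A.  Purely algebraic.
* **RPA**: η̃^(1) = V·D exactly and η̃^(n) = η̃^(n−2)(D² + 4VᵀV·D); the
  zeroth moment requires one frequency integral, split into a rational
  part G_main and an exponential part G_offset, closed by a Woodbury-style
  solve of (I + 4VD⁻¹Vᵀ) in the auxiliary space.  That matrix is positive
  definite for any gapped reference; loss of definiteness is reported as
  "non-physical screening" rather than silently regularized.

### Quadrature

G_main is integrated with an open (Fejér-1) Clenshaw–Curtis rule mapped to
(0, ∞) through z = L·t/(1−t²).  The scale L is chosen once per call by
minimizing the rule's error on the diagonal surrogate
∫ z²/(z²+d²)⁻² dz = π/(4d) summed over the particle-hole gaps d — a
closed form that isolates the z-dependence of the true integrand — using a
bounded scalar minimization in log L.  G_offset uses Gauss–Laguerre with
the same point count, with the substitution z = s/(2 min D) matching the
e^(−2z·min D) decay of the integrand.  Convergence is exponential: on the
test fixtures the 8→16→32-point errors fall from ~1e−5 to ~1e−14.  The
default of 32 points is far inside machine precision at these sizes; the
difference against the half-resolution grid is attached to the result as a
diagnostic and is never fatal.

## Self-energy moments

Screened moments are contracted with x (the Green's-function index)
outermost and the particle-hole pair reduced, with the auxiliary-space
kernel S^(n) = η̃^(n) V_phᵀ formed once per order; this mirrors a
distributable layout without changing results.  The binomial contraction
into Σ^(n,</>) uses the screened moment of order t (not n) inside the sum
over t — the only reading that reproduces the pole model
Σ^(n,<) = Σ c (ε_k − Ω)ⁿ c exactly, which the oracle tests verify.

## Upfolding by block Lanczos

Lanczos block vectors are represented by their coefficients on the Krylov
generators Eⁿq₀, so every inner product is a contraction of normalized
moments S₀^(−1/2) Σ^(n) S₀^(−1/2); the pole space is never materialized
and moments up to order 2L−1 suffice for L blocks (hence the requirement
that n_max be odd).  Numerical choices:

* Block inverse square roots use symmetric eigendecomposition with an
  eigenvalue floor of 1e−12 relative to the sequence's energy-squared
  scale (estimated from the normalized second moment); directions below
  the floor are deflated and the external dimension shrinks.  This makes
  the rank decisions deterministic and lets an exhausted Krylov space
  (e.g. a single-pole moment sequence) terminate exactly.
* Residuals are fully reorthogonalized (twice) against all previous
  blocks, which keeps the round-trip error of conserved moments at
  ~1e−14 relative through order 13.
* Lesser and greater sequences are tridiagonalized independently and
  their external spaces concatenated without cross-coupling; the sector
  membership is stored so downfolded moments can be split without
  reference to a chemical potential.

Poles whose quasiparticle weight falls below 1e−8 are treated as having
zero Lehmann residue when identifying the frontier (IP/EA): finite
precision can leave external states that are exactly decoupled from the
physical space at arbitrary energies, and a pole that carries no spectral
weight does not appear in the Green's function.  They still participate in
completeness sums (their weight is numerically zero).

## Solvers

All variants share the moment → upfold → diagonalize primitive.  Defaults:
energy threshold 5 meV (1.8375e−4 Ha), moment threshold 1e−4, DIIS space
12, 32 quadrature points, NAF threshold 1e−5, at most 50 outer iterations.
Non-convergence is flagged on the result, never raised.

* **Chemical potential.** Occupations are assigned by Aufbau filling of
  the correlated poles: ascending in energy (stable tie-break by pole
  index), each pole contributing twice its quasiparticle weight, stopping
  at the prefix that best matches the electron count; μ is the midpoint of
  the frontier pole energies.  Moment splitting in iteration k+1 uses the
  μ of iteration k.
* **evGW/evGW0.** Quasiparticle energies are assigned per MO by largest
  squared residue (ties to the lowest pole index; collisions resolved
  greedily by descending weight, each logged), DIIS-extrapolated, and fed
  back into the Green's-function energies (and the screening, for evGW).
* **qsGW.** The static potential is built from the decoupled external
  poles, either Lorentzian-regularized (δ = 1e−3 Ha by default) or with
  the SRG form (s = 100 by default); both parameters are exposed since no
  canonical value exists.  The Fock matrix is rebuilt from the current
  density through the density-fitted J/K builder, whose effective core is
  extracted so that F[P_ref] = f + Σ∞ exactly.  The returned Green's
  function is the converged effective mean-field one (unit weights).
* **scGW/GW0/G0W.** The poles of the previous iteration (quasi-molecular
  orbitals) define the propagator spaces; the rotated interaction tensors
  carry the physical-space eigenvector components so that low-weight poles
  enter with suppressed couplings — the only weighting under which a
  zero-interaction reference is a fixed point.  DIIS acts on the stacked
  moment/static arrays; if an extrapolation breaks positive semidefiniteness
  of a zeroth moment the un-mixed moments are used for that iteration.
  Electron-number drift is reported each iteration and never corrected.
  The external-space size is bounded by construction
  (poles ≤ M·(n_max+2)) and asserted.
* **fsGW.** Outer loop over self-energy rebuilds; inner alternation of
  (a) a scalar search for the shift ζ applied to the external-block
  diagonal until the Aufbau electron count of the correlated Green's
  function matches 2o within 1e−6 (geometric bracket expansion, at most
  60 doublings, then bisection; the count varies continuously with ζ
  through the pole weights, so the tolerance is achievable on the
  fixtures), and (b) a DIIS-accelerated Fock SCF on the correlated
  (non-idempotent) density.  fsGW is the only variant that accepts a
  non-canonical (rotated-orbital) bundle, since its first step
  diagonalizes the Fock matrix; this is what makes the
  reference-independence checks possible.

## NAF compression

The Gram matrix of the interaction is built either over all orbital pairs
except the virtual–virtual block (`ph_only`, the one-shot default) or the
full product space (`full_product`, used whenever any self-consistency is
requested, because the NAF basis is built once and never rebuilt inside
the loop while self-consistency mixes virtual–virtual channels into the
screening).  The truncation threshold applies to the raw eigenvalues by
default (a relative mode exists but is off).  The Frobenius reconstruction
error is bounded by the square root of the dropped-eigenvalue sum, which
the tests check, and the default 1e−5 threshold moves the one-shot IP by
well under 1e−4 Ha on the fixtures.

## Synthetic fixtures: what they show

The generator draws occupied energies uniformly in
[−energy_scale − gap, −gap/2] and virtual energies in [gap/2, energy_scale]
with gap = 0.5 Ha, energy_scale = 2 Ha, and Gaussian interaction factors
scaled by 0.1 — magnitudes typical of small-molecule valence problems, and
a coupling weak enough that the screening problem is guaranteed stable
(A − B = D > 0 makes instabilities impossible for real couplings, and this
is checked per draw).  One pseudorandom stream exists per seed, consumed
in documented field order with sub-streams keyed per field, so fixtures
are bit-reproducible and extensible.  Problem sizes throughout the suite
and the acceptance script are o·v ≤ 12 with a handful of auxiliary
functions: large enough to exercise every code path against dense oracles
at ~1e−9 tolerances, deliberately small enough that brute-force
full-frequency references are exact.

What passing on fixtures does **not** show: basis-set or density-fitting
errors of real chemistry, strong-correlation regimes (fixture gaps are
large), RPA instabilities, near-degenerate quasiparticle assignment in
dense spectra, or the accuracy of any screening model against experiment —
fixtures validate the *implementation*, not the physics of a particular
molecule.  Chemically meaningful inputs enter through the container format
or the optional `pyscf` adapter.

## Known limitations

* Single-process, dense linear algebra; the oracle module is hard-capped
  at a particle-hole dimension of 400 and everything is sized for desk-
  scale validation rather than production chemistry.
* qsGW convergence is not guaranteed at high moment orders; failures are
  flagged, not repaired.
* The ζ-search reports failure if the electron count never crosses the
  target within the bracket; no self-energy reshaping is attempted.
* The moment-order metric for convergence studies is the per-MO
  quasiparticle energy (largest-residue assignment); satellite positions
  converge more slowly than this metric reflects.
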