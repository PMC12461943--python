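# mcgw — moment-conserving GW for molecular charged excitations

`mcgw` computes quasiparticle (charged-excitation) spectra of gapped,
closed-shell molecular systems with the *GW* approximation, reformulated
around **spectral moments of the self-energy** instead of frequency grids,
analytic continuation, or plasmon-pole models.  It is aimed at method
developers and practitioners who want full-frequency molecular *GW* —
ionization potentials, electron affinities, satellite structure, Dyson
orbitals and spectral functions — from a single dense diagonalization, with
a controlled, systematically improvable truncation parameter.

## The method

Starting from a restricted mean-field reference (orbital energies ε,
Fock matrix **f**, and a density-fitted Coulomb interaction
(pq|rs) = Σ_P V_{P,pq} V_{P,rs}), the hole/particle self-energy moments

    Σ^(n,<)_pq = -1/π ∫^μ ω^n Im Σ_pq(ω) dω,
    Σ^(n,>)_pq = +1/π ∫_μ ω^n Im Σ_pq(ω) dω

are computed **exactly** for n = 0 … n_mom from moments of the screened
interaction, W^(n) = V η̃^(n) V, where η̃^(n) are moments of the reducible
density response at either the Tamm–Dancoff (TDA) or random-phase (RPA)
level.  TDA screening is a simple recursion η̃^(n) = η̃^(n−1)(D + 2VᵀV);
RPA needs one numerical frequency integral for η̃^(0) (Clenshaw–Curtis +
Gauss–Laguerre, exponentially convergent) and a two-step recursion above
it.  A block Lanczos recursion then inverts the moment sequence into a
compact block-tridiagonal "upfolded" Hamiltonian

    H̃ = [ f + Σ∞   W̃ ]
         [ W̃ᵀ      d̃ ]

whose external block conserves the input moments exactly
(Σ^(n) = W̃ d̃ⁿ W̃ᵀ for all n ≤ n_mom) and grows only linearly with system
size and moment order.  One dense diagonalization of H̃ yields every pole
and residue of the correlated Green's function at once — IP and EA, reduced
quasiparticle weights, low-weighted satellites, the full spectral function,
and Dyson orbitals — with the odd moment order n_mom the single convergence
knob.

On top of this one-shot (G0W0) primitive the package implements the
self-consistent family: eigenvalue self-consistency (evGW, evGW0),
quasiparticle self-consistency with Lorentzian or SRG regularization
(qsGW, qsGW-SRG), fully dynamical self-consistency over quasi-molecular
orbitals (scGW, GW0, G0W), and Fock-matrix self-consistency (fsGW), which
couples a relative chemical-potential shift — enforcing the physical
electron number of the correlated Green's function exactly — to an SCF over
the correlated density matrix.  Natural-auxiliary-function (NAF)
compression of the density-fitting index is available throughout.

A synthetic-fixture generator produces physically valid random reference
bundles (gapped spectra, symmetric stable interactions), so the entire
pipeline is testable with no quantum-chemistry engine; an optional adapter
builds real bundles through `pyscf` when it is installed.

## Worked example

```python
from mcgw import MomentGW

model = MomentGW.from_synthetic(o=2, v=2, n_aux=4, seed=7,
                                variant="g0w0", screening="tda", n_max=7)
results = model.fit()
print(results.summary())
```

prints

```
Moment-conserving GW results
==============================================
variant                 g0w0
screening               TDA
moment order n_max      7
orbitals (occ/vir)      2/2
auxiliary dimension     4
iterations              1
converged               True
----------------------------------------------
IP [eV]                 13.087365
EA [eV]                 -17.522671
gap [eV]                30.610036
QP weight at IP         0.999569
QP weight at EA         0.999177
poles                   20
==============================================
```

The IP/EA are the negatives of the frontier pole energies of the correlated
Green's function (here for a random gapped fixture, so the numbers are
statistical, not chemical); the quasiparticle weights just below 1 show the
correlation-induced transfer of spectral weight into the 16 satellite poles
that accompany the 4 orbital-like excitations.  The same calculation is
available from the shell:

```sh
mcgw fixture --o 2 --v 2 --naux 4 --seed 7 -o ref.h5
mcgw run ref.h5 --screening tda --variant g0w0 --nmom 7 -o run
mcgw spectrum run.result.h5 -o spectrum.tsv
```

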