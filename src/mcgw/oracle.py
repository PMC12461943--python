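"""Brute-force full-frequency references for testing the moment pipeline.

These dense O(N^6)-like routes exist only for validation on tiny systems:
they diagonalize the particle-hole problem explicitly, reconstruct response
moments from the excitation amplitudes, and build the exact (untruncated)
upfolded GW Hamiltonian with one external state per (orbital, excitation)
pair.  A hard cap on the particle-hole dimension keeps them out of any
production path.

Conventions are shared with the recursive pipeline: amplitudes ``t`` are
normalized so that ``eta^(n) = t Omega^n t^T`` with the restricted-spin
factor of 2 inside the equation-of-motion blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ExcitationSpectrum",
    "exact_tda_excitations",
    "exact_rpa_excitations",
    "oracle_response_moments",
    "oracle_sigma_moments",
    "exact_gw_poles",
    "DENSE_CAP",
]

DENSE_CAP = 400


@dataclass
class ExcitationSpectrum:
    """Neutral excitation energies and moment-generating amplitudes.

    ``amplitudes`` has shape ``(o*v, n_exc)`` and satisfies
    ``eta^(n) = amplitudes @ diag(energies**n) @ amplitudes.T``; for TDA the
    columns are the orthonormal eigenvectors ``X`` of ``A``, for RPA the
    scaled combinations ``X + Y``.
    """

    energies: np.ndarray
    amplitudes: np.ndarray
    kind: str

    def response_moment(self, n: int) -> np.ndarray:
        return (self.amplitudes * self.energies[None, :] ** n) @ self.amplitudes.T


def _check_cap(v_ph: np.ndarray, cap: int) -> None:
    if v_ph.shape[1] > cap:
        raise ValueError(
            f"particle-hole dimension {v_ph.shape[1]} exceeds the dense "
            f"oracle cap ({cap}); the oracle is for tiny test systems only"
        )


def exact_tda_excitations(v_ph, d, cap: int = DENSE_CAP) -> ExcitationSpectrum:
    """Dense diagonalization of the Tamm-Dancoff matrix ``A = D + 2 V^T V``."""
    v_ph = np.asarray(v_ph, dtype=float)
    d = np.asarray(d, dtype=float)
    _check_cap(v_ph, cap)
    a = np.diag(d) + 2.0 * v_ph.T @ v_ph
    omega, x = np.linalg.eigh(a)
    return ExcitationSpectrum(energies=omega, amplitudes=x, kind="TDA")


def exact_rpa_excitations(v_ph, d, cap: int = DENSE_CAP) -> ExcitationSpectrum:
    """RPA spectrum via the symmetric form ``D^1/2 (A + B) D^1/2``.

    With ``A - B = D`` positive definite the squared excitation energies are
    the eigenvalues of ``D^1/2 (D + 4 V^T V) D^1/2``; amplitudes are scaled
    to ``X + Y = D^1/2 Z Omega^-1/2`` so the moment identity holds.
    """
    v_ph = np.asarray(v_ph, dtype=float)
    d = np.asarray(d, dtype=float)
    _check_cap(v_ph, cap)
    if np.any(d <= 0):
        raise ValueError("A - B = D must be positive definite")
    sqd = np.sqrt(d)
    m = sqd[:, None] * (np.diag(d) + 4.0 * v_ph.T @ v_ph) * sqd[None, :]
    omega2, z = np.linalg.eigh(0.5 * (m + m.T))
    if np.any(omega2 <= 0):
        raise ValueError("RPA instability: imaginary excitation energy")
    omega = np.sqrt(omega2)
    xpy = sqd[:, None] * z / np.sqrt(omega)[None, :]
    return ExcitationSpectrum(energies=omega, amplitudes=xpy, kind="RPA")


def oracle_response_moments(v_ph, spectrum: ExcitationSpectrum, n_max: int):
    """Explicit pole-sum intermediates ``eta~^(n) = V (t Omega^n t^T)``."""
    v_ph = np.asarray(v_ph, dtype=float)
    u = v_ph @ spectrum.amplitudes  # (N_aux, n_exc)
    return [
        (u * spectrum.energies[None, :] ** n) @ spectrum.amplitudes.T
        for n in range(n_max + 1)
    ]


def _couplings(ref, spectrum: ExcitationSpectrum) -> np.ndarray:
    """Couplings ``c[p, x, nu] = sum_P V[P, p, x] (V_ph t)[P, nu]``."""
    u = ref.interaction_ph @ spectrum.amplitudes  # (N_aux, n_exc)
    return np.einsum("Ppx,Pn->pxn", ref.interaction_full, u, optimize=True)


def oracle_sigma_moments(ref, spectrum: ExcitationSpectrum, n_max: int):
    """Self-energy moments as explicit sums over poles.

    Hole poles sit at ``eps_k - Omega_nu`` and particle poles at
    ``eps_c + Omega_nu`` with residues from the shared coupling convention;
    this is the independent cross-check for the recursive pipeline.
    """
    from .refstate import static_self_energy
    from .selfenergy import SelfEnergyMoments

    o = ref.n_occupied
    eps = ref.orbital_energies
    c = _couplings(ref, spectrum)
    m = ref.n_orbitals
    lesser = np.zeros((n_max + 1, m, m))
    greater = np.zeros((n_max + 1, m, m))
    for n in range(n_max + 1):
        e_hole = (eps[:o, None] - spectrum.energies[None, :]) ** n
        e_part = (eps[o:, None] + spectrum.energies[None, :]) ** n
        lesser[n] = np.einsum("pkn,kn,qkn->pq", c[:, :o, :], e_hole,
                              c[:, :o, :], optimize=True)
        greater[n] = np.einsum("pcn,cn,qcn->pq", c[:, o:, :], e_part,
                               c[:, o:, :], optimize=True)
    return SelfEnergyMoments(lesser=lesser, greater=greater,
                             static=static_self_energy(ref), n_max=n_max)


def exact_gw_poles(ref, spectrum: ExcitationSpectrum):
    """Exact full-frequency one-shot GW poles from the untruncated upfolding.

    Builds the supermatrix with the physical block ``f + Sigma_inf``, one
    external hole state per (k, nu) at ``eps_k - Omega_nu`` and one external
    particle state per (c, nu) at ``eps_c + Omega_nu``, with couplings from
    the interaction and excitation amplitudes, then diagonalizes densely.
    Moment-truncated solutions converge to this pole set as the conserved
    order grows.
    """
    from .refstate import static_self_energy
    from .solvers import aufbau_fill
    from .upfold import PoleSet

    o = ref.n_occupied
    v = ref.n_virtual
    m = ref.n_orbitals
    eps = ref.orbital_energies
    nexc = spectrum.energies.shape[0]
    _check_cap(np.empty((1, o * v)), DENSE_CAP)

    c = _couplings(ref, spectrum)
    hole_e = (eps[:o, None] - spectrum.energies[None, :]).ravel()
    part_e = (eps[o:, None] + spectrum.energies[None, :]).ravel()
    coupling = np.concatenate(
        [c[:, :o, :].reshape(m, o * nexc), c[:, o:, :].reshape(m, v * nexc)],
        axis=1,
    )
    external = np.concatenate([hole_e, part_e])
    k = external.shape[0]
    h = np.zeros((m + k, m + k))
    h[:m, :m] = ref.fock_mo + static_self_energy(ref)
    h[:m, m:] = coupling
    h[m:, :m] = coupling.T
    h[m:, m:] = np.diag(external)
    energies, vectors = np.linalg.eigh(h)
    chi = vectors[:m, :]
    mu, occupied, _ = aufbau_fill(energies, (chi**2).sum(axis=0),
                                  ref.n_electrons)
    return PoleSet(energies=energies, residues=chi, chemical_potential=mu,
                   occupied=occupied)
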