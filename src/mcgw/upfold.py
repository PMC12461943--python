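"""Upfolding self-energy moments into a block-tridiagonal Hamiltonian.

A finite sequence of Hermitian self-energy moments ``Sigma^(0..2L-1)`` per
sector defines, through the block Lanczos three-term recurrence run on the
(implicit) pole representation of the self-energy, an "external" space of
dimension at most ``L * M`` whose block-tridiagonal Hamiltonian reproduces
the input moments exactly:

    Sigma^(n) = W~  d~^n  W~^T     for n = 0 .. 2L-1.

The physical block ``f + Sigma_inf`` coupled to the two sector spaces forms
the moment-conserving effective Hamiltonian; its dense eigendecomposition
yields the correlated Green's function in Lehmann form, the spectral
function, quasiparticle weights and Dyson orbitals, while tracing the
external space back out gives the downfolded dynamical self-energy
``Sigma(w) = W~^T (w 1 - d~)^-1 W~``.

All inner products in the recursion are evaluated directly from the moment
sequence (the pole space is never materialized); block inverse square roots
are regularized by a deterministic eigenvalue-floor deflation, shrinking the
external dimension when a moment sequence is numerically rank deficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .refstate import HARTREE_TO_EV
from .selfenergy import SelfEnergyMoments

__all__ = [
    "UpfoldedHamiltonian",
    "PoleSet",
    "block_lanczos",
    "recover_moments",
    "diagonalize",
    "downfold_sigma",
    "spectral_function",
    "dyson_orbitals",
    "write_pole_table",
    "write_spectrum",
]

#: relative eigenvalue floor below which block directions are deflated
DEFLATION_FLOOR = 1e-12

#: quasiparticle weight below which a pole is treated as fully decoupled
#: from the physical space (zero Lehmann residue) for frontier searches
WEIGHT_FLOOR = 1e-8


@dataclass
class UpfoldedHamiltonian:
    """Moment-conserving effective Hamiltonian in block form."""

    physical: np.ndarray
    coupling: np.ndarray
    external: np.ndarray
    sector_slices: dict = field(default_factory=dict)

    @property
    def n_physical(self) -> int:
        return self.physical.shape[0]

    @property
    def n_external(self) -> int:
        return self.external.shape[0]

    @property
    def matrix(self) -> np.ndarray:
        """The assembled symmetric ``(M + K) x (M + K)`` matrix."""
        m, k = self.n_physical, self.n_external
        h = np.zeros((m + k, m + k))
        h[:m, :m] = self.physical
        h[:m, m:] = self.coupling
        h[m:, :m] = self.coupling.T
        h[m:, m:] = self.external
        return h


@dataclass
class PoleSet:
    """Lehmann representation of a correlated Green's function.

    ``residues[p, alpha]`` are the physical-space components of the
    unit-norm eigenvectors; the quasiparticle weight of pole ``alpha`` is
    ``sum_p residues[p, alpha]**2`` and lies in [0, 1].
    """

    energies: np.ndarray
    residues: np.ndarray
    chemical_potential: float
    occupied: np.ndarray

    @property
    def n_poles(self) -> int:
        return self.energies.shape[0]

    @property
    def n_physical(self) -> int:
        return self.residues.shape[0]

    @property
    def weights(self) -> np.ndarray:
        return (self.residues**2).sum(axis=0)

    @property
    def homo_index(self) -> int:
        """Highest occupied pole carrying physical spectral weight.

        Poles whose quasiparticle weight falls below :data:`WEIGHT_FLOOR`
        have (numerically) zero Lehmann residue -- they are external states
        decoupled from the physical space by round-off -- and do not appear
        in the Green's function, so they cannot define a frontier.
        """
        occ = np.flatnonzero(self.occupied & (self.weights > WEIGHT_FLOOR))
        if occ.size == 0:
            raise ValueError("no occupied poles with physical weight")
        return int(occ[np.argmax(self.energies[occ])])

    @property
    def lumo_index(self) -> int:
        vir = np.flatnonzero(~self.occupied
                             & (self.weights > WEIGHT_FLOOR))
        if vir.size == 0:
            raise ValueError("no unoccupied poles with physical weight")
        return int(vir[np.argmin(self.energies[vir])])

    def quasiparticle_energies(self) -> np.ndarray:
        """Per-MO quasiparticle energies: the pole of largest weight on each
        physical index (ties broken by lowest pole index)."""
        assignment = np.argmax(self.residues**2, axis=1)
        return self.energies[assignment]


# -- block Lanczos from moments ---------------------------------------------

def _floored_sqrt_factors(mat: np.ndarray, floor: float,
                          scale: float | None = None):
    """Eigenvalue-filtered square-root factors of a PSD matrix.

    Returns ``(basis, sqrt_vals)`` with ``mat ~= basis diag(vals) basis^T``
    restricted to eigenvalues above ``floor * scale``; directions below the
    floor are deflated.  ``scale`` defaults to the largest eigenvalue of
    ``mat`` itself, but the Lanczos recursion passes a global scale so that
    an exhausted Krylov space (residual Gram matrix of pure round-off) is
    deflated entirely rather than renormalized into noise.
    """
    mat = 0.5 * (mat + mat.T)
    vals, vecs = np.linalg.eigh(mat)
    top = max(vals.max(initial=0.0), 0.0)
    if scale is None:
        scale = top
    keep = vals > max(floor * scale, 0.0)
    if top <= 0.0:
        keep = np.zeros_like(keep)
    return vecs[:, keep], np.sqrt(vals[keep])


def _tridiagonalize_sector(moments: np.ndarray, n_blocks: int,
                           floor: float = DEFLATION_FLOOR):
    """Block Lanczos driven purely by a sector's moment sequence.

    ``moments`` holds orders ``0 .. 2 n_blocks - 1``.  Returns the sector
    coupling ``(M x m0)`` and external block-tridiagonal matrix.  The
    Lanczos vectors are represented by their coefficients on the Krylov
    generators ``E^n q_0``, so every inner product reduces to a contraction
    of normalized moments; full reorthogonalization keeps the recursion
    stable at high orders.
    """
    m = moments.shape[1]
    basis, sq = _floored_sqrt_factors(moments[0], floor)
    m0 = basis.shape[1]
    if m0 == 0:
        return np.zeros((m, 0)), np.zeros((0, 0))
    # normalized moments T_n = S0^(-1/2) Sigma^(n) S0^(-1/2), projected
    inv_half = basis / sq[None, :]
    t = np.einsum("pi,npq,qj->nij", inv_half, moments, inv_half,
                  optimize=True)
    t = 0.5 * (t + t.transpose(0, 2, 1))
    # energy-squared scale of the normalized sequence, for deflation
    gram_scale = max(1.0, float(np.abs(t[2]).max())) if t.shape[0] > 2 \
        else max(1.0, float(np.abs(t[1]).max()) ** 2)

    def inner(ci, cj, shift):
        out = np.zeros((ci[0].shape[1], cj[0].shape[1]))
        for n, a in enumerate(ci):
            for np_, b in enumerate(cj):
                out += a.T @ t[n + shift + np_] @ b
        return out

    coeffs = [[np.eye(m0)]]  # q_0
    a_blocks = []
    b_blocks = []
    for j in range(n_blocks):
        cj = coeffs[j]
        a_j = inner(cj, cj, 1)
        a_j = 0.5 * (a_j + a_j.T)
        a_blocks.append(a_j)
        if j == n_blocks - 1:
            break
        # residual r = E q_j - q_j a_j - q_{j-1} b_j^T, in coefficient form
        width = cj[0].shape[1]
        res = [np.zeros((m0, width)) for _ in range(j + 2)]
        for n, c in enumerate(cj):
            res[n + 1] += c
            res[n] -= c @ a_j
        if j > 0:
            for n, c in enumerate(coeffs[j - 1]):
                res[n] -= c @ b_blocks[-1].T
        # full reorthogonalization (twice) against all previous blocks
        for _ in range(2):
            for ci in coeffs:
                ov = inner(ci, res, 0)
                for n, c in enumerate(ci):
                    res[n] -= c @ ov
        gram = inner(res, res, 0)
        vecs, sqv = _floored_sqrt_factors(gram, floor, scale=gram_scale)
        if vecs.shape[1] == 0:
            break  # Krylov space exhausted; moments already conserved
        b_next = (vecs * sqv[None, :]).T  # (m_{j+1} x m_j)
        q_next = [r @ (vecs / sqv[None, :]) for r in res]
        b_blocks.append(b_next)
        coeffs.append(q_next)

    sizes = [c[0].shape[1] for c in coeffs]
    k = sum(sizes)
    ext = np.zeros((k, k))
    offs = np.concatenate([[0], np.cumsum(sizes)])
    for j, a_j in enumerate(a_blocks[: len(sizes)]):
        ext[offs[j]:offs[j + 1], offs[j]:offs[j + 1]] = a_j
    for j, b_j in enumerate(b_blocks[: len(sizes) - 1]):
        ext[offs[j + 1]:offs[j + 2], offs[j]:offs[j + 1]] = b_j
        ext[offs[j]:offs[j + 1], offs[j + 1]:offs[j + 2]] = b_j.T
    coupling = np.zeros((m, k))
    coupling[:, :m0] = basis * sq[None, :]
    return coupling, ext


def block_lanczos(
    moments: SelfEnergyMoments, physical: np.ndarray
) -> UpfoldedHamiltonian:
    """Build the moment-conserving effective Hamiltonian.

    ``n_max`` must be odd (``n_max = 2L - 1`` conserves ``L`` block
    iterations per sector); the lesser and greater sequences are
    tridiagonalized independently and their external spaces concatenated.
    """
    if moments.n_max % 2 == 0:
        raise ValueError(
            f"moment order must be odd (got n_max = {moments.n_max}); "
            "n_max = 2L - 1 conserves L block-Lanczos iterations"
        )
    for name, seq in (("lesser", moments.lesser),
                      ("greater", moments.greater)):
        scale = max(np.abs(seq[0]).max(), 1e-300)
        if np.linalg.eigvalsh(0.5 * (seq[0] + seq[0].T))[0] < -1e-8 * scale:
            raise ValueError(
                f"invalid moment sequence: zeroth {name} moment is not PSD"
            )
    n_blocks = (moments.n_max + 1) // 2
    w_less, d_less = _tridiagonalize_sector(moments.lesser, n_blocks)
    w_grtr, d_grtr = _tridiagonalize_sector(moments.greater, n_blocks)
    k_less = d_less.shape[0]
    k_grtr = d_grtr.shape[0]
    coupling = np.concatenate([w_less, w_grtr], axis=1)
    external = np.zeros((k_less + k_grtr, k_less + k_grtr))
    external[:k_less, :k_less] = d_less
    external[k_less:, k_less:] = d_grtr
    return UpfoldedHamiltonian(
        physical=0.5 * (physical + physical.T),
        coupling=coupling,
        external=external,
        sector_slices={"hole": slice(0, k_less),
                       "particle": slice(k_less, k_less + k_grtr)},
    )


def recover_moments(
    h: UpfoldedHamiltonian, n_max: int, mu: float | None = None
) -> SelfEnergyMoments:
    """Downfolded moments ``Sigma^(n) = W~ d~^n W~^T`` split by sector.

    Uses the construction-time sector slices when available; otherwise the
    external eigenvalues are split about the chemical potential ``mu``.
    """
    m = h.n_physical

    def power_moments(w, d):
        out = np.empty((n_max + 1, m, m))
        cur = w.copy()
        for n in range(n_max + 1):
            out[n] = 0.5 * (cur @ w.T + w @ cur.T)
            cur = cur @ d
        return out

    if h.sector_slices:
        hole = h.sector_slices["hole"]
        part = h.sector_slices["particle"]
        lesser = power_moments(h.coupling[:, hole], h.external[hole, hole])
        greater = power_moments(h.coupling[:, part], h.external[part, part])
    else:
        if mu is None:
            raise ValueError("mu required without stored sector slices")
        vals, vecs = np.linalg.eigh(h.external)
        rot = h.coupling @ vecs
        below = vals < mu
        lesser = power_moments(rot[:, below], np.diag(vals[below]))
        greater = power_moments(rot[:, ~below], np.diag(vals[~below]))
    return SelfEnergyMoments(lesser=lesser, greater=greater,
                             static=np.zeros((m, m)), n_max=n_max)


def diagonalize(h: UpfoldedHamiltonian, n_electrons: int) -> PoleSet:
    """Complete eigendecomposition into the correlated pole set."""
    from .solvers import aufbau_fill

    energies, vectors = np.linalg.eigh(h.matrix)
    chi = vectors[: h.n_physical, :]
    mu, occupied, _ = aufbau_fill(energies, (chi**2).sum(axis=0),
                                  n_electrons)
    return PoleSet(energies=energies, residues=chi,
                   chemical_potential=mu, occupied=occupied)


def downfold_sigma(
    h: UpfoldedHamiltonian, omega_grid, delta: float = 0.0
) -> np.ndarray:
    """Dynamical self-energy samples ``Sigma(w) = W~ (w1 - d~)^-1 W~^T``.

    Evaluated through the decoupled-pole representation (diagonalize the
    external block once); ``delta`` enters as a uniform retarded ``+i delta``.
    With ``delta = 0`` a grid point at an external eigenvalue is singular.
    """
    omega_grid = np.atleast_1d(np.asarray(omega_grid, dtype=float))
    vals, vecs = np.linalg.eigh(h.external)
    v = h.coupling @ vecs  # (M, K)
    if delta == 0.0 and np.any(
        np.isclose(omega_grid[:, None], vals[None, :], atol=1e-12)
    ):
        raise ValueError("singular evaluation: omega hits an external pole "
                         "with delta = 0")
    denom = omega_grid[:, None] - vals[None, :] + 1j * delta
    return np.einsum("pk,wk,qk->wpq", v, 1.0 / denom, v, optimize=True)


def spectral_function(
    poles: PoleSet, omega_grid, delta: float = 0.01
) -> np.ndarray:
    """Lorentzian-broadened spectral function ``A(w) >= 0``.

    ``A(w) = (1/pi) sum_{p,alpha} chi_{p alpha}^2 delta /
    ((w - E_alpha)^2 + delta^2)``; integrates to the number of physical
    orbitals over the real line (completeness sum rule).
    """
    if delta <= 0:
        raise ValueError("broadening delta must be > 0")
    omega_grid = np.atleast_1d(np.asarray(omega_grid, dtype=float))
    w = poles.weights
    lor = delta / ((omega_grid[:, None] - poles.energies[None, :]) ** 2
                   + delta**2)
    return (lor @ w) / np.pi


def dyson_orbitals(poles: PoleSet, mo_coefficients: np.ndarray, selection):
    """AO-space Dyson orbitals ``C chi_alpha`` with their weights."""
    selection = np.atleast_1d(np.asarray(selection, dtype=int))
    vectors = mo_coefficients @ poles.residues[:, selection]
    weights = poles.weights[selection]
    return vectors, weights


# -- text writers -----------------------------------------------------------

def write_pole_table(path, poles: PoleSet) -> None:
    """TSV pole table: index, energy (Ha, eV), weight, occupation flag."""
    with open(path, "w") as fh:
        fh.write("index\tenergy_Ha\tenergy_eV\tweight\toccupied_flag\n")
        for i, (e, w, occ) in enumerate(
            zip(poles.energies, poles.weights, poles.occupied)
        ):
            fh.write(f"{i}\t{e:.12e}\t{e * HARTREE_TO_EV:.12e}"
                     f"\t{w:.12e}\t{int(occ)}\n")


def write_spectrum(path, omega_grid, values) -> None:
    """TSV spectrum: frequency in eV against A(w)."""
    with open(path, "w") as fh:
        fh.write("omega_eV\tA\n")
        for w, a in zip(np.atleast_1d(omega_grid), np.atleast_1d(values)):
            fh.write(f"{w * HARTREE_TO_EV:.12e}\t{a:.12e}\n")
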