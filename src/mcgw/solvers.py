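"""One-shot and self-consistent GW drivers over the moment pipeline.

Every variant shares the same primitive chain -- screening moments,
screened-interaction moments, self-energy moments, block Lanczos upfolding,
dense diagonalization -- and differs only in which ingredients are updated
between iterations:

========  ===========================================================
variant   what is iterated
========  ===========================================================
g0w0      nothing (single shot)
evgw0     quasiparticle energies in G only (screening frozen)
evgw      quasiparticle energies in G and in the screening
qsgw      static Hermitian potential from the self-energy (Lorentzian
          regularization); qsgw_srg uses the similarity-renormalization-
          group regularizer instead
gw0       correlated Green's function (quasi-molecular orbitals), with
          the screened-interaction moments frozen at iteration zero
g0w       screening from the correlated Green's function, with the
          G-side spaces frozen at the reference
scgw      everything dynamical: both G and W from the previous
          iteration's correlated Green's function
fsgw      Fock matrix and a relative chemical-potential shift zeta,
          enforcing electron number and density consistency with the
          correlated Green's function at fixed self-energy
========  ===========================================================

Chemical potentials for moment splitting are midpoints of the HOMO/LUMO
pole energies of the previous iteration (reference HOMO/LUMO at the start).
Iterative solvers flag non-convergence in the result; they never raise.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.optimize

from ._diis import DIIS
from .naf import build_naf, project_interaction
from .refstate import HARTREE_TO_EV, ReferenceState, static_self_energy
from .screening import rpa_moments, tda_moments
from .selfenergy import (
    ScreenedMoments,
    SelfEnergyMoments,
    sigma_moments,
    w_moments_core,
)
from .upfold import PoleSet, UpfoldedHamiltonian, block_lanczos, diagonalize

__all__ = [
    "SolverConfig",
    "GWResult",
    "aufbau_fill",
    "electron_number",
    "run",
    "run_g0w0",
    "run_evgw",
    "run_qsgw",
    "run_scgw",
    "run_fsgw",
    "VARIANTS",
]

logger = logging.getLogger(__name__)

VARIANTS = ("g0w0", "evgw0", "evgw", "gw0", "g0w", "scgw", "fsgw",
            "qsgw", "qsgw_srg")
_SCREENINGS = ("tda", "rpa")

#: electron-number tolerance of the fsGW zeta search
ZETA_TOL = 1e-6


@dataclass
class SolverConfig:
    """Knobs shared by all solver variants.

    Defaults follow common practice for moment-conserving GW: a 5 meV
    energy threshold, 1e-4 moment threshold, DIIS space of 12, 32-point
    screening quadrature and an NAF truncation of 1e-5.
    """

    screening: str = "tda"
    variant: str = "g0w0"
    n_max: int = 7
    e_tol: float = 5e-3 / HARTREE_TO_EV
    moment_tol: float = 1e-4
    diis_size: int = 12
    use_diis: bool = True
    max_iter: int = 50
    quad_points: int = 32
    delta: float = 0.01
    qs_delta: float = 1e-3
    srg_s: float = 100.0
    naf_threshold: float = 1e-5
    seed: int = 0

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.screening not in _SCREENINGS:
            raise ValueError(f"unknown screening {self.screening!r}")
        if self.n_max % 2 == 0 or self.n_max < 1:
            raise ValueError(
                f"moment order must be odd (got n_max = {self.n_max})"
            )
        if min(self.e_tol, self.moment_tol) <= 0:
            raise ValueError("tolerances must be > 0")
        if self.quad_points < 4:
            raise ValueError("quad_points must be >= 4")


@dataclass
class GWResult:
    """Poles, frontier excitations and convergence record of one run."""

    variant: str
    screening: str
    poles: PoleSet
    moments: SelfEnergyMoments | None
    ip: float
    ea: float
    gap: float
    qp_weight_ip: float
    qp_weight_ea: float
    iterations: int
    converged: bool
    diagnostics: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)


# -- occupation machinery ---------------------------------------------------

def aufbau_fill(energies, weights=None, n_electrons=None):
    """Aufbau filling of correlated poles.

    Accepts either ``(PoleSet, n_electrons)`` or
    ``(energies, weights, n_electrons)``.  Poles are filled ascending by
    energy (stable tie-break by pole index), each contributing twice its
    quasiparticle weight, stopping at the prefix that best matches the
    target electron count.  Returns ``(mu, occupied_flags, achieved_N)``
    with ``mu`` the midpoint between the frontier pole energies.
    """
    if hasattr(energies, "residues"):
        poles = energies
        n_electrons = weights if n_electrons is None else n_electrons
        weights = poles.weights
        energies = poles.energies
    energies = np.asarray(energies, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if energies.size == 0:
        raise ValueError("empty pole set")
    if int(n_electrons) % 2:
        raise ValueError("n_electrons must be even (closed shell)")
    order = np.argsort(energies, kind="stable")
    cum = np.concatenate([[0.0], np.cumsum(2.0 * weights[order])])
    k = int(np.argmin(np.abs(cum - n_electrons)))
    occupied = np.zeros(energies.size, dtype=bool)
    occupied[order[:k]] = True
    sorted_e = energies[order]
    if k == 0:
        mu = float(sorted_e[0] - 1.0)
    elif k == energies.size:
        mu = float(sorted_e[-1] + 1.0)
    else:
        mu = float(0.5 * (sorted_e[k - 1] + sorted_e[k]))
    return mu, occupied, float(cum[k])


def electron_number(poles: PoleSet, mu: float) -> float:
    """``N = 2 sum_{alpha: E_alpha < mu} sum_p chi_{p alpha}^2``."""
    below = poles.energies < mu
    return float(2.0 * poles.weights[below].sum())


# -- shared internals -------------------------------------------------------

def _prepare(ref: ReferenceState, config: SolverConfig) -> ReferenceState:
    """Validate and NAF-compress the bundle for the requested variant.

    One-shot runs compress over the particle-hole-dominated block; any
    self-consistency uses the full product space since the NAF basis is
    never rebuilt inside the loop.
    """
    config.validate()
    ref.validate()
    if config.variant != "fsgw" and not ref.is_canonical:
        raise ValueError(
            f"variant {config.variant!r} requires a canonical (diagonal "
            "Fock) reference; only fsgw rediagonalizes the Fock matrix"
        )
    if config.naf_threshold and config.naf_threshold > 0:
        block = "ph_only" if config.variant == "g0w0" else "full_product"
        naf = build_naf(ref, threshold=config.naf_threshold,
                        block_choice=block)
        ref = project_interaction(ref, naf)
    return ref


def _eta(v_ph, d, config: SolverConfig):
    if config.screening == "tda":
        return tda_moments(v_ph, d, config.n_max)
    return rpa_moments(v_ph, d, config.n_max, n_points=config.quad_points)


def _eta_fingerprint(eta) -> str:
    h = hashlib.sha256()
    for m in eta.moments:
        h.update(np.ascontiguousarray(m).tobytes())
    return h.hexdigest()


def _rotate_interaction(vfull: np.ndarray, left: np.ndarray,
                        right: np.ndarray) -> np.ndarray:
    return np.einsum("Qpq,pi,qj->Qij", vfull, left, right, optimize=True)


def _frontier(poles: PoleSet):
    hi, li = poles.homo_index, poles.lumo_index
    ip = -float(poles.energies[hi])
    ea = -float(poles.energies[li])
    return ip, ea, float(poles.weights[hi]), float(poles.weights[li])


def _result(variant, screening, poles, moments, iterations, converged,
            diagnostics, extras=None) -> GWResult:
    ip, ea, w_ip, w_ea = _frontier(poles)
    return GWResult(
        variant=variant, screening=screening, poles=poles, moments=moments,
        ip=ip, ea=ea, gap=ip - ea, qp_weight_ip=w_ip, qp_weight_ea=w_ea,
        iterations=iterations, converged=converged,
        diagnostics=diagnostics, extras=extras or {},
    )


def _build_moments_mo(work: ReferenceState, eps: np.ndarray,
                      config: SolverConfig, eta=None):
    """Self-energy moments in a fixed MO space with energies ``eps``.

    ``eta`` may be passed in to freeze the screening (evGW0); otherwise it
    is built from the supplied energies.
    """
    o = work.n_occupied
    d = (eps[None, o:] - eps[:o, None]).ravel()
    if eta is None:
        eta = _eta(work.interaction_ph, d, config)
    wh = w_moments_core(eta, work.interaction_ph,
                        work.interaction_full[:, :, :o], eps[:o], "hole")
    wp = w_moments_core(eta, work.interaction_ph,
                        work.interaction_full[:, :, o:], eps[o:], "particle")
    out = sigma_moments(wh, wp, config.n_max,
                        static=static_self_energy(work))
    return out, eta


def _fock_builder(work: ReferenceState):
    """Restricted Fock matrix as a function of the (per-spin) density.

    ``F[P] = h_eff + 2 J[P] - K[P]`` in the reference MO basis, with the
    effective core extracted so that ``F[P_ref] = f + Sigma_inf`` -- the
    static potential of the reference, exact for a Hartree-Fock bundle.
    """
    vfull = work.interaction_full
    o = work.n_occupied
    m = work.n_orbitals

    def jk(p):
        j = np.einsum("Qpq,Q->pq", vfull,
                      np.einsum("Qrs,rs->Q", vfull, p, optimize=True),
                      optimize=True)
        k = np.einsum("Qpr,rs,Qsq->pq", vfull, p, vfull, optimize=True)
        return 2.0 * j - k

    p_ref = np.zeros((m, m))
    p_ref[:o, :o] = np.eye(o)
    core = work.fock_mo + static_self_energy(work) - jk(p_ref)

    def fock(p):
        f = core + jk(p)
        return 0.5 * (f + f.T)

    return fock


def _qp_energies(poles: PoleSet) -> np.ndarray:
    """Per-MO quasiparticle energies with greedy collision resolution.

    Each MO takes the pole of largest squared residue on its index (ties to
    the lowest pole index); if two MOs claim one pole, MOs are served in
    descending best-weight order and take their best still-free pole, with
    a logged warning.
    """
    chi2 = poles.residues**2
    m = chi2.shape[0]
    assignment = np.argmax(chi2, axis=1)
    if np.unique(assignment).size < m:
        logger.warning("quasiparticle assignment collision; resolving "
                       "greedily by descending weight")
        best = chi2.max(axis=1)
        taken: set[int] = set()
        assignment = np.empty(m, dtype=int)
        for p in np.argsort(-best, kind="stable"):
            row = chi2[p].copy()
            if taken:
                row[list(taken)] = -1.0
            alpha = int(np.argmax(row))
            assignment[p] = alpha
            taken.add(alpha)
    return poles.energies[assignment]


# -- one-shot ---------------------------------------------------------------

def run_g0w0(ref: ReferenceState, config: SolverConfig) -> GWResult:
    """Single-shot moment-conserving GW on the reference state."""
    work = _prepare(ref, config)
    moments, _ = _build_moments_mo(work, work.orbital_energies, config)
    h = block_lanczos(moments, work.fock_mo + moments.static)
    poles = diagonalize(h, work.n_electrons)
    mu0 = poles.chemical_potential
    diag = [{
        "iteration": 0,
        "n_elec": electron_number(poles, mu0),
        "n_poles": poles.n_poles,
    }]
    return _result(config.variant, config.screening, poles, moments,
                   1, True, diag, extras={"upfolded": h})


# -- eigenvalue self-consistency --------------------------------------------

def run_evgw(ref: ReferenceState, config: SolverConfig) -> GWResult:
    """Eigenvalue self-consistent GW (evGW / evGW0).

    Orbital energies are updated between iterations without touching the
    orbital coefficients: each MO is assigned the pole with the largest
    quasiparticle weight on its index, and the new energies re-enter the
    Green's-function side of the moments (and the screening too for the
    full evGW flavor).
    """
    if config.variant not in ("evgw", "evgw0"):
        raise ValueError("run_evgw drives variants 'evgw' and 'evgw0'")
    work = _prepare(ref, config)
    eps0 = work.orbital_energies
    frozen_eta = None
    if config.variant == "evgw0":
        o = work.n_occupied
        d0 = (eps0[None, o:] - eps0[:o, None]).ravel()
        frozen_eta = _eta(work.interaction_ph, d0, config)
    eps = eps0.copy()
    diis = DIIS(config.diis_size, enabled=config.use_diis)
    diagnostics = []
    converged = False
    poles = None
    moments = None
    for it in range(config.max_iter):
        moments, eta = _build_moments_mo(work, eps, config, eta=frozen_eta)
        h = block_lanczos(moments, work.fock_mo + moments.static)
        poles = diagonalize(h, work.n_electrons)
        eps_qp = _qp_energies(poles)
        delta = float(np.abs(eps_qp - eps).max())
        ip, ea, _, _ = _frontier(poles)
        diagnostics.append({
            "iteration": it, "ip": ip, "ea": ea, "delta_eps": delta,
            "n_elec": electron_number(poles, poles.chemical_potential),
            "eta_fingerprint": _eta_fingerprint(eta),
        })
        if delta < config.e_tol:
            converged = True
            break
        eps = diis.update(eps_qp).reshape(eps.shape)
    return _result(config.variant, config.screening, poles, moments,
                   len(diagnostics), converged, diagnostics)


# -- quasiparticle self-consistency -----------------------------------------

def _static_potential_lorentzian(eps, ext_e, couplings, delta):
    """Eq.-style symmetrized static potential with Lorentzian broadening.

    ``V^S_pq = Re[Sigma_pq(eps_p) + Sigma_pq(eps_q)] / 2`` with the
    self-energy evaluated from the decoupled external poles.
    """
    dpl = eps[:, None] - ext_e[None, :]  # (M, K)
    kernel = dpl / (dpl**2 + delta**2)
    sig = np.einsum("pk,pk,qk->pq", couplings, kernel, couplings,
                    optimize=True)
    return 0.5 * (sig + sig.T)


def _static_potential_srg(eps, ext_e, couplings, s):
    """SRG-regularized static potential.

    ``V^S_pq = sum_k (D_pk + D_qk)/(D_pk^2 + D_qk^2) v_pk v_qk
    (1 - exp(-(D_pk^2 + D_qk^2) s))`` with ``D_pk = eps_p - e_k``; the
    s -> 0 limit vanishes and s -> inf recovers the unregularized
    symmetrized potential.
    """
    d = eps[:, None] - ext_e[None, :]  # (M, K)
    d2 = d**2
    denom = d2[:, None, :] + d2[None, :, :]  # (M, M, K)
    num = d[:, None, :] + d[None, :, :]
    factor = np.where(denom > 0,
                      num / np.where(denom > 0, denom, 1.0)
                      * (1.0 - np.exp(-denom * s)),
                      0.0)
    vs = np.einsum("pk,qk,pqk->pq", couplings, couplings, factor,
                   optimize=True)
    return 0.5 * (vs + vs.T)


def run_qsgw(ref: ReferenceState, config: SolverConfig) -> GWResult:
    """Quasiparticle self-consistent GW (Lorentzian or SRG regularized).

    Each iteration casts the upfolded self-energy to a Hermitian static
    potential evaluated at the current quasiparticle energies, adds it to
    the Fock matrix rebuilt from the current density, and rediagonalizes.
    The returned Green's function is the converged effective mean-field
    one: unit quasiparticle weights, no satellites.
    """
    if config.variant not in ("qsgw", "qsgw_srg"):
        raise ValueError("run_qsgw drives variants 'qsgw' and 'qsgw_srg'")
    work = _prepare(ref, config)
    o, m = work.n_occupied, work.n_orbitals
    fock = _fock_builder(work)
    eps = work.orbital_energies.copy()
    coeff = np.eye(m)
    diis = DIIS(config.diis_size, enabled=config.use_diis)
    diagnostics = []
    converged = False
    moments = None
    for it in range(config.max_iter):
        vfull_cur = _rotate_interaction(work.interaction_full, coeff, coeff)
        rotated = replace(work, interaction_full=vfull_cur,
                          orbital_energies=eps, fock_mo=np.diag(eps))
        moments, _ = _build_moments_mo(rotated, eps, config)
        h = block_lanczos(moments, np.diag(eps))
        ext_e, ext_vec = np.linalg.eigh(h.external)
        coup = h.coupling @ ext_vec  # couplings in the current basis
        if config.variant == "qsgw":
            vs = _static_potential_lorentzian(eps, ext_e, coup,
                                              config.qs_delta)
        else:
            vs = _static_potential_srg(eps, ext_e, coup, config.srg_s)
        vs_ref = coeff @ vs @ coeff.T  # back to the reference MO basis
        p_cur = coeff[:, :o] @ coeff[:, :o].T
        heff = fock(p_cur) + vs_ref
        heff = diis.update(heff).reshape(m, m)
        heff = 0.5 * (heff + heff.T)
        eps_new, coeff_new = np.linalg.eigh(heff)
        delta = float(np.abs(eps_new - eps).max())
        diagnostics.append({"iteration": it, "ip": -eps_new[o - 1],
                            "ea": -eps_new[o], "delta_eps": delta})
        eps, coeff = eps_new, coeff_new
        if delta < config.e_tol:
            converged = True
            break
    occupied = np.zeros(m, dtype=bool)
    occupied[:o] = True
    poles = PoleSet(energies=eps, residues=coeff,
                    chemical_potential=0.5 * (eps[o - 1] + eps[o]),
                    occupied=occupied)
    return _result(config.variant, config.screening, poles, moments,
                   len(diagnostics), converged, diagnostics)


# -- full dynamical self-consistency ----------------------------------------

def run_scgw(ref: ReferenceState, config: SolverConfig,
             initial_energies: np.ndarray | None = None) -> GWResult:
    """Self-consistent GW over quasi-molecular orbitals (scGW/GW0/G0W).

    The correlated Green's function of the previous iteration supplies the
    propagator spaces: its poles (QMOs) replace the molecular orbitals on
    the G side (and in the particle-hole screening channel unless frozen),
    with the physical-space eigenvector components carried inside the
    rotated interaction tensors so that low-weight poles couple weakly.
    Electron-number drift is monitored and reported, never corrected.

    ``initial_energies`` optionally replaces the reference orbital energies
    in the iteration-zero propagator spaces only (the physical Hamiltonian
    is untouched); a converged fixed point should not depend on it.
    """
    if config.variant not in ("scgw", "gw0", "g0w"):
        raise ValueError("run_scgw drives variants 'scgw', 'gw0', 'g0w'")
    work = _prepare(ref, config)
    o, m = work.n_occupied, work.n_orbitals
    eps0 = work.orbital_energies
    vfull = work.interaction_full
    fock = _fock_builder(work)
    p_ref = np.zeros((m, m))
    p_ref[:o, :o] = np.eye(o)

    # iteration-zero spaces: the molecular orbitals themselves
    start = eps0 if initial_energies is None \
        else np.asarray(initial_energies, dtype=float)
    hole_e, hole_vec = start[:o].copy(), np.eye(m)[:, :o]
    part_e, part_vec = start[o:].copy(), np.eye(m)[:, o:]
    dens = p_ref.copy()
    frozen = None  # (eta, v_ph) for GW0
    diis = DIIS(config.diis_size, enabled=config.use_diis)
    diagnostics = []
    converged = False
    prev_moments = None
    prev_ip = None
    poles = None
    moments = None
    for it in range(config.max_iter):
        if config.variant == "gw0" and frozen is not None:
            eta, v_ph = frozen
        else:
            # particle-hole channel over the current (QMO) spaces
            d = (part_e[None, :] - hole_e[:, None]).ravel()
            if np.any(d <= 0):
                d = np.clip(d, 1e-8, None)
            v_ph = np.einsum("Qpq,pi,qa->Qia", vfull, hole_vec, part_vec,
                             optimize=True).reshape(vfull.shape[0], -1)
            eta = _eta(v_ph, d, config)
            if config.variant == "gw0" and frozen is None:
                frozen = (eta, v_ph)
        if config.variant == "g0w":
            g_hole = (vfull[:, :, :o], eps0[:o])
            g_part = (vfull[:, :, o:], eps0[o:])
        else:
            g_hole = (np.einsum("Qpq,qx->Qpx", vfull, hole_vec,
                                optimize=True), hole_e)
            g_part = (np.einsum("Qpq,qx->Qpx", vfull, part_vec,
                                optimize=True), part_e)
        wh = w_moments_core(eta, v_ph, g_hole[0], g_hole[1], "hole")
        wp = w_moments_core(eta, v_ph, g_part[0], g_part[1], "particle")
        moments = sigma_moments(wh, wp, config.n_max,
                                static=static_self_energy(work))
        physical = fock(dens)
        stacked = np.concatenate([moments.lesser.ravel(),
                                  moments.greater.ravel(),
                                  physical.ravel()])
        mixed = diis.update(stacked)
        n_mom = moments.lesser.size
        mix_moments = SelfEnergyMoments(
            lesser=mixed[:n_mom].reshape(moments.lesser.shape),
            greater=mixed[n_mom:2 * n_mom].reshape(moments.greater.shape),
            static=moments.static, n_max=config.n_max,
        )
        mix_physical = mixed[2 * n_mom:].reshape(m, m)
        try:
            h = block_lanczos(mix_moments, mix_physical)
            used_moments = mix_moments
        except ValueError:
            # DIIS extrapolation broke PSD of a zeroth moment; fall back
            h = block_lanczos(moments, physical)
            used_moments = moments
        poles = diagonalize(h, work.n_electrons)
        assert poles.n_poles <= m * (config.n_max + 2), \
            "external space exceeded the moment-truncation bound"
        mu = poles.chemical_potential
        nelec = electron_number(poles, mu)
        ip, ea, _, _ = _frontier(poles)
        mom_change = (
            float(max(np.abs(used_moments.lesser - prev_moments.lesser).max(),
                      np.abs(used_moments.greater - prev_moments.greater).max()))
            if prev_moments is not None else np.inf
        )
        diagnostics.append({
            "iteration": it, "ip": ip, "ea": ea, "n_elec": nelec,
            "electron_number_error": abs(nelec - work.n_electrons),
            "moment_change": mom_change, "n_poles": poles.n_poles,
            "eta_fingerprint": _eta_fingerprint(eta),
        })
        if (prev_ip is not None and abs(ip - prev_ip) < config.e_tol
                and mom_change < config.moment_tol):
            converged = True
            break
        prev_ip = ip
        prev_moments = used_moments
        occ = poles.occupied
        hole_e, hole_vec = poles.energies[occ], poles.residues[:, occ]
        part_e, part_vec = poles.energies[~occ], poles.residues[:, ~occ]
        dens = poles.residues[:, occ] @ poles.residues[:, occ].T
    return _result(config.variant, config.screening, poles, moments,
                   len(diagnostics), converged, diagnostics)


# -- Fock-matrix self-consistency -------------------------------------------

def _assemble_shifted(physical, coupling, external, zeta):
    return UpfoldedHamiltonian(
        physical=physical, coupling=coupling,
        external=external + zeta * np.eye(external.shape[0]),
    )


def _zeta_search(physical, coupling, external, n_electrons, zeta0=0.0):
    """Relative chemical-potential shift enforcing the electron number.

    Shifts the diagonal of the external block by ``zeta`` until the Aufbau
    electron count of the resulting correlated Green's function matches the
    target within :data:`ZETA_TOL`.  Brackets a sign change geometrically
    (at most 60 doublings) and bisects; if the count never crosses the
    target the best achievable shift is returned with ``ok=False``.
    """

    def count(z):
        h = _assemble_shifted(physical, coupling, external, z)
        poles = diagonalize(h, n_electrons)
        return electron_number(poles, poles.chemical_potential) - n_electrons

    f0 = count(zeta0)
    if abs(f0) < ZETA_TOL:
        return zeta0, True
    step = 1e-3
    lo = hi = zeta0
    flo = fhi = f0
    for _ in range(60):
        lo, hi = zeta0 - step, zeta0 + step
        flo, fhi = count(lo), count(hi)
        if abs(flo) < ZETA_TOL:
            return lo, True
        if abs(fhi) < ZETA_TOL:
            return hi, True
        if flo * f0 < 0 or fhi * f0 < 0:
            break
        step *= 2.0
    else:
        return zeta0, False
    a, b = (lo, zeta0) if flo * f0 < 0 else (zeta0, hi)
    try:
        zeta = scipy.optimize.brentq(count, a, b, xtol=1e-13)
    except ValueError:  # pragma: no cover - bracket checked above
        return zeta0, False
    return zeta, abs(count(zeta)) < ZETA_TOL


def run_fsgw(ref: ReferenceState, config: SolverConfig) -> GWResult:
    """Fock-matrix self-consistent GW.

    The outer loop rebuilds the self-energy moments from the orbitals and
    energies of the current Fock matrix.  With the self-energy fixed, two
    nested loops are alternated until jointly satisfied: a scalar search
    for the relative chemical-potential offset ``zeta`` on the external
    block enforcing the physical electron number, and a DIIS-accelerated
    SCF in which the Fock matrix is rebuilt from the correlated
    (non-idempotent) density of the occupied poles.  At convergence the
    correlated density equals the density implied by the converged Fock
    matrix and the electron number is exact to the search tolerance.
    """
    if config.variant != "fsgw":
        raise ValueError("run_fsgw drives variant 'fsgw'")
    work = _prepare(ref, config)
    o, m = work.n_occupied, work.n_orbitals
    fock = _fock_builder(work)
    f_cur = work.fock_mo + static_self_energy(work)
    zeta = 0.0
    diagnostics = []
    converged = False
    prev_ip = None
    poles = None
    moments = None
    for outer in range(config.max_iter):
        eps_cur, c_cur = np.linalg.eigh(f_cur)
        vfull_cur = _rotate_interaction(work.interaction_full, c_cur, c_cur)
        basis_ref = replace(
            work, interaction_full=vfull_cur, orbital_energies=eps_cur,
            fock_mo=np.diag(eps_cur),
        )
        moments, _ = _build_moments_mo(basis_ref, eps_cur, config)
        # rotate the moment matrices back to the fixed reference MO basis
        back = SelfEnergyMoments(
            lesser=np.einsum("pi,nij,qj->npq", c_cur, moments.lesser,
                             c_cur, optimize=True),
            greater=np.einsum("pi,nij,qj->npq", c_cur, moments.greater,
                              c_cur, optimize=True),
            static=moments.static, n_max=config.n_max,
        )
        h0 = block_lanczos(back, f_cur)
        coupling, external = h0.coupling, h0.external
        # inner: alternate zeta search and the Fock loop at fixed self-energy
        zeta_ok = density_ok = False
        dens_prev = None
        for _cycle in range(config.max_iter):
            zeta, zeta_ok = _zeta_search(f_cur, coupling, external,
                                         work.n_electrons, zeta0=zeta)
            diis = DIIS(config.diis_size, enabled=config.use_diis)
            density_ok = False
            for _scf in range(config.max_iter):
                h = _assemble_shifted(f_cur, coupling, external, zeta)
                poles = diagonalize(h, work.n_electrons)
                occ = poles.occupied
                dens = poles.residues[:, occ] @ poles.residues[:, occ].T
                d_dens = (np.abs(dens - dens_prev).max()
                          if dens_prev is not None else np.inf)
                dens_prev = dens
                if d_dens < config.moment_tol:
                    density_ok = True
                    break
                f_cur = diis.update(fock(dens)).reshape(m, m)
                f_cur = 0.5 * (f_cur + f_cur.T)
            h = _assemble_shifted(f_cur, coupling, external, zeta)
            poles = diagonalize(h, work.n_electrons)
            nelec = electron_number(poles, poles.chemical_potential)
            if density_ok and abs(nelec - work.n_electrons) < ZETA_TOL:
                zeta_ok = True
                break
        ip, ea, _, _ = _frontier(poles)
        nelec = electron_number(poles, poles.chemical_potential)
        diagnostics.append({
            "iteration": outer, "ip": ip, "ea": ea, "n_elec": nelec,
            "electron_number_error": abs(nelec - work.n_electrons),
            "zeta": zeta, "zeta_ok": zeta_ok, "density_ok": density_ok,
        })
        if prev_ip is not None and abs(ip - prev_ip) < config.e_tol:
            converged = zeta_ok and density_ok
            break
        prev_ip = ip
    return _result(config.variant, config.screening, poles, moments,
                   len(diagnostics), converged, diagnostics,
                   extras={"zeta": zeta})


_DISPATCH = {
    "g0w0": run_g0w0,
    "evgw": run_evgw,
    "evgw0": run_evgw,
    "qsgw": run_qsgw,
    "qsgw_srg": run_qsgw,
    "scgw": run_scgw,
    "gw0": run_scgw,
    "g0w": run_scgw,
    "fsgw": run_fsgw,
}


def run(ref: ReferenceState, config: SolverConfig) -> GWResult:
    """Dispatch to the driver for ``config.variant``."""
    config.validate()
    return _DISPATCH[config.variant](ref, config)
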