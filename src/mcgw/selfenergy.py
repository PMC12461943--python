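"""Screened-interaction and self-energy spectral moments.

Given response moments ``eta~^(n)`` the screened-interaction moments are

    W^(n)[p x, q x] = sum_PQ V[P, p, x] S^(n)[P, Q] V[Q, q, x],
    S^(n) = eta~^(n) V_ph^T,

with ``x`` running over the hole (occupied) or particle (virtual) states of
the Green's function for the lesser and greater sectors respectively.  The
auxiliary-space kernel ``S^(n)`` is independent of ``x`` and is formed once
per order; the contraction is laid out with ``x`` outermost and the
particle-hole pair reduced, so a distributed variant could partition ``x``
without changing results.

Hole and particle self-energy moments then follow from the binomial
contraction with the Green's-function energies,

    Sigma^(n,<)_pq = sum_{t<=n} sum_k C(n,t) (-1)^t eps_k^(n-t) W^(t)[pk,qk]
    Sigma^(n,>)_pq = sum_{t<=n} sum_c C(n,t)        eps_c^(n-t) W^(t)[pc,qc]

which is the moment expansion of poles at ``eps_k - Omega`` (holes) and
``eps_c + Omega`` (particles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import comb

from .naf import build_naf, project_interaction
from .refstate import ReferenceState, static_self_energy
from .screening import ResponseMoments, rpa_moments, tda_moments

__all__ = [
    "ScreenedMoments",
    "SelfEnergyMoments",
    "w_moments",
    "sigma_moments",
    "assemble",
]

_SECTORS = ("hole", "particle")


@dataclass
class ScreenedMoments:
    """Screened-interaction moments for one sector.

    ``w`` has shape ``(n_max + 1, n_x, M, M)``; each ``w[n, x]`` is symmetric
    in the physical orbital pair.  ``x_energies`` are the Green's-function
    energies attached to the contracted index (occupied orbital energies for
    the hole sector, virtual for the particle sector; quasi-molecular-orbital
    energies in fully self-consistent iterations).
    """

    w: np.ndarray
    x_energies: np.ndarray
    sector: str

    @property
    def n_max(self) -> int:
        return self.w.shape[0] - 1


@dataclass
class SelfEnergyMoments:
    """Hermitian hole/particle moment matrices plus the static piece."""

    lesser: np.ndarray
    greater: np.ndarray
    static: np.ndarray
    n_max: int
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lesser = np.asarray(self.lesser, dtype=float)
        self.greater = np.asarray(self.greater, dtype=float)
        self.static = np.asarray(self.static, dtype=float)

    @property
    def n_orbitals(self) -> int:
        return self.static.shape[0]

    def validate(self) -> None:
        for name, seq in (("lesser", self.lesser), ("greater", self.greater)):
            if seq.shape[0] != self.n_max + 1:
                raise ValueError(f"{name} moments missing orders")
            for n in range(self.n_max + 1):
                if not np.allclose(seq[n], seq[n].T, atol=1e-10):
                    raise ValueError(f"{name} moment {n} not symmetric")
            scale = max(np.abs(seq[0]).max(), 1e-300)
            if np.linalg.eigvalsh(seq[0])[0] < -1e-10 * scale:
                raise ValueError(f"{name} zeroth moment not PSD")


def w_moments_core(
    eta: ResponseMoments, v_ph: np.ndarray, v_gside: np.ndarray,
    x_energies: np.ndarray, sector: str,
) -> ScreenedMoments:
    """Contract response moments into screened moments for one sector.

    ``v_gside`` has shape ``(N_aux, M, n_x)``: the interaction with one
    index in the physical space and one in the Green's-function (``x``)
    space -- an orbital slice of the full tensor in one-shot calculations,
    a quasi-molecular-orbital rotation in self-consistent ones.
    """
    if v_gside.shape[0] != v_ph.shape[0] or eta[0].shape[0] != v_ph.shape[0]:
        raise ValueError(
            "auxiliary dimension mismatch between response moments and "
            "interaction tensors (axis 0)"
        )
    n_max = eta.n_max
    nx = v_gside.shape[2]
    m = v_gside.shape[1]
    w = np.empty((n_max + 1, nx, m, m))
    for n in range(n_max + 1):
        s = eta[n] @ v_ph.T
        s = 0.5 * (s + s.T)
        w[n] = np.einsum("Ppx,PQ,Qqx->xpq", v_gside, s, v_gside,
                         optimize=True)
        w[n] = 0.5 * (w[n] + w[n].transpose(0, 2, 1))
    return ScreenedMoments(w=w, x_energies=np.asarray(x_energies, float),
                           sector=sector)


def w_moments(
    eta: ResponseMoments, ref: ReferenceState, sector: str
) -> ScreenedMoments:
    """Screened moments for the hole or particle sector of a reference."""
    if sector not in _SECTORS:
        raise ValueError(f"sector must be one of {_SECTORS}")
    o = ref.n_occupied
    sl = slice(None, o) if sector == "hole" else slice(o, None)
    return w_moments_core(
        eta,
        ref.interaction_ph,
        ref.interaction_full[:, :, sl],
        ref.orbital_energies[sl],
        sector,
    )


def sigma_moments(
    w_hole: ScreenedMoments, w_particle: ScreenedMoments,
    n_max: int, static: np.ndarray | None = None,
) -> SelfEnergyMoments:
    """Binomial contraction of screened moments into self-energy moments."""
    for w in (w_hole, w_particle):
        if w.n_max < n_max:
            raise ValueError(
                f"screened moments carry orders up to {w.n_max}, "
                f"but n_max = {n_max} was requested"
            )
    m = w_hole.w.shape[2]
    lesser = np.zeros((n_max + 1, m, m))
    greater = np.zeros((n_max + 1, m, m))
    for n in range(n_max + 1):
        for t in range(n + 1):
            cnt = comb(n, t, exact=True)
            ek = w_hole.x_energies ** (n - t)
            ec = w_particle.x_energies ** (n - t)
            lesser[n] += cnt * (-1) ** t * np.einsum(
                "x,xpq->pq", ek, w_hole.w[t], optimize=True)
            greater[n] += cnt * np.einsum(
                "x,xpq->pq", ec, w_particle.w[t], optimize=True)
        lesser[n] = 0.5 * (lesser[n] + lesser[n].T)
        greater[n] = 0.5 * (greater[n] + greater[n].T)
    if static is None:
        static = np.zeros((m, m))
    return SelfEnergyMoments(lesser=lesser, greater=greater, static=static,
                             n_max=n_max)


def assemble(
    ref: ReferenceState,
    screening_kind: str = "TDA",
    n_max: int = 7,
    *,
    n_points: int = 32,
    naf_threshold: float | None = None,
    naf_block: str = "ph_only",
) -> SelfEnergyMoments:
    """Full one-shot moment chain for a reference bundle.

    Optional NAF compression, then screening moments, screened-interaction
    moments for both sectors, and the binomial contraction; the static
    self-energy ``K[D] - V_xc`` rides along.  Stage failures propagate with
    the stage named.
    """
    kind = screening_kind.upper()
    if kind not in ("TDA", "RPA"):
        raise ValueError("screening_kind must be 'TDA' or 'RPA'")
    work = ref
    if naf_threshold is not None and naf_threshold > 0:
        try:
            naf = build_naf(ref, threshold=naf_threshold,
                            block_choice=naf_block)
            work = project_interaction(ref, naf)
        except Exception as exc:
            raise RuntimeError(f"NAF stage failed: {exc}") from exc
    d = work.orbital_energy_differences
    v_ph = work.interaction_ph
    try:
        if kind == "TDA":
            eta = tda_moments(v_ph, d, n_max)
        else:
            eta = rpa_moments(v_ph, d, n_max, n_points=n_points)
    except Exception as exc:
        raise RuntimeError(f"screening stage failed: {exc}") from exc
    try:
        wh = w_moments(eta, work, "hole")
        wp = w_moments(eta, work, "particle")
        out = sigma_moments(wh, wp, n_max, static=static_self_energy(work))
    except Exception as exc:
        raise RuntimeError(f"self-energy stage failed: {exc}") from exc
    out.diagnostics.update(eta.diagnostics)
    return out
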