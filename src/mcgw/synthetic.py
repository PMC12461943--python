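"""Deterministic synthetic reference states and pole models.

The generator produces physically valid closed-shell bundles -- gapped
spectra, symmetric factorized interactions, stable screening -- so the whole
moment pipeline and every solver can be exercised without a quantum-chemistry
engine.  Fixtures are statistical stand-ins, not chemistry: orbital energies
are drawn uniformly inside occupied/virtual windows separated by a gap, and
interaction factors are i.i.d. Gaussian.  Defaults put the gap, spread and
coupling strength at magnitudes typical of small-molecule valence spectra
(a few tenths of a Hartree).

One pseudorandom stream exists per seed and is consumed in a documented
field order (energies, then interaction); any field added later must draw
from a sub-stream keyed by its own tag so existing fixtures never shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .refstate import ReferenceState

__all__ = [
    "FixtureSpec",
    "random_reference",
    "pole_model_moments",
    "rotate_reference",
]

# Sub-stream tags, in documented draw order.
_STREAM_ENERGIES = 0
_STREAM_INTERACTION = 1
_STREAM_ROTATION = 2


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and scales of a synthetic reference bundle.

    ``gap`` separates the occupied window ``[-energy_scale - gap, -gap/2]``
    from the virtual window ``[gap/2, energy_scale]`` (Hartree);
    ``coupling_scale`` multiplies the Gaussian interaction factors and is
    kept small enough that the screening problem stays positive definite.
    """

    o: int
    v: int
    n_aux: int
    gap: float = 0.5
    energy_scale: float = 2.0
    coupling_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.o, self.v, self.n_aux) < 1:
            raise ValueError("o, v and n_aux must be positive")
        if self.gap <= 0 or self.energy_scale <= 0 or self.coupling_scale < 0:
            raise ValueError("gap, energy_scale must be > 0, coupling >= 0")


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(spec.seed), stream])


def random_reference(spec: FixtureSpec) -> ReferenceState:
    """Generate a gapped, screening-stable, HF-like reference bundle.

    The same spec (including seed) always returns bitwise-identical arrays.
    The Tamm-Dancoff matrix ``D + 2 V^T V`` is positive definite by
    construction (``D > 0`` and the coupling term is PSD); the draw is
    nevertheless checked and redrawn with halved coupling if degenerate.
    """
    o, v, naux = spec.o, spec.v, spec.n_aux
    m = o + v

    rng_e = _rng(spec, _STREAM_ENERGIES)
    occ = np.sort(rng_e.uniform(-spec.energy_scale - spec.gap,
                                -spec.gap / 2.0, size=o))
    vir = np.sort(rng_e.uniform(spec.gap / 2.0, spec.energy_scale, size=v))
    energies = np.concatenate([occ, vir])

    rng_v = _rng(spec, _STREAM_INTERACTION)
    scale = spec.coupling_scale
    for _ in range(8):
        vfull = rng_v.normal(size=(naux, m, m)) * scale
        vfull = 0.5 * (vfull + vfull.transpose(0, 2, 1))
        d = (energies[None, o:] - energies[:o, None]).ravel()
        vph = vfull[:, :o, o:].reshape(naux, o * v)
        tda = np.diag(d) + 2.0 * vph.T @ vph
        if np.linalg.eigvalsh(tda)[0] > 1e-10:
            break
        scale *= 0.5  # pragma: no cover - D > 0 makes this unreachable
    zero = np.zeros((m, m))
    ref = ReferenceState(
        orbital_energies=energies,
        n_occupied=o,
        mo_coefficients=np.eye(m),
        fock_mo=np.diag(energies),
        exchange_mo=zero.copy(),
        vxc_mo=zero.copy(),
        interaction_full=vfull,
        metadata={"basis": "synthetic", "reference": "HF",
                  "n_elec": 2 * o, "seed": spec.seed},
    )
    ref.validate()
    return ref


def pole_model_moments(poles, n_max: int, mu: float = 0.0):
    """Spectral moments of an explicit pole model.

    ``poles`` is a sequence of ``(energy, coupling_vector)`` pairs; the
    moments are ``Sigma^(n) = sum_j w_j e_j^n w_j^T`` split into lesser and
    greater sequences by the sign of ``e_j - mu``.  Zeroth moments are PSD
    by construction.  This is the generator used to test the block Lanczos
    upfolding: pole energies are exactly identifiable whenever the per-sector
    pole count does not exceed ``(n_max + 1) / 2``.
    """
    from .selfenergy import SelfEnergyMoments

    poles = [(float(e), np.asarray(w, dtype=float)) for e, w in poles]
    if not poles:
        raise ValueError("pole model requires at least one pole")
    m = poles[0][1].shape[0]
    lesser = np.zeros((n_max + 1, m, m))
    greater = np.zeros((n_max + 1, m, m))
    for e, w in poles:
        outer = np.outer(w, w)
        target = lesser if e < mu else greater
        for n in range(n_max + 1):
            target[n] += (e ** n) * outer
    return SelfEnergyMoments(lesser=lesser, greater=greater,
                             static=np.zeros((m, m)), n_max=n_max)


def rotate_reference(ref: ReferenceState, seed: int = 0) -> ReferenceState:
    """An equivalent, non-canonical bundle: same state, rotated orbitals.

    Applies an orthogonal rotation mixing occupied orbitals among themselves
    and virtual orbitals among themselves.  The mean-field state (density,
    Fock spectrum, interaction) is physically unchanged, but the Fock matrix
    is no longer diagonal -- useful for reference-independence checks of
    self-consistent solvers that rediagonalize the Fock matrix.
    """
    from scipy.stats import ortho_group

    o, v = ref.n_occupied, ref.n_virtual
    rng = np.random.default_rng([int(seed), _STREAM_ROTATION])
    q = np.zeros((o + v, o + v))
    q[:o, :o] = ortho_group.rvs(o, random_state=rng) if o > 1 else 1.0
    q[o:, o:] = ortho_group.rvs(v, random_state=rng) if v > 1 else 1.0
    rotated = ReferenceState(
        orbital_energies=ref.orbital_energies.copy(),
        n_occupied=o,
        mo_coefficients=ref.mo_coefficients @ q,
        fock_mo=q.T @ ref.fock_mo @ q,
        exchange_mo=q.T @ ref.exchange_mo @ q,
        vxc_mo=q.T @ ref.vxc_mo @ q,
        interaction_full=np.einsum(
            "Ppq,pi,qj->Pij", ref.interaction_full, q, q, optimize=True
        ),
        metadata={**ref.metadata, "rotated": True},
    )
    rotated.validate()
    return rotated
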