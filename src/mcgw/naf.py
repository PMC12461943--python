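"""Natural auxiliary function (NAF) compression of the Coulomb factors.

The auxiliary index of the factorized interaction ``V[P, p, q]`` carries
redundancy; diagonalizing the positive semidefinite Gram matrix

    M_PQ = sum_{vw} V[P, v, w] V[Q, v, w]

over a chosen orbital-pair block yields an eigenbasis (the NAFs) in which
the interaction can be truncated with a controllable threshold on the
eigenvalues.  The particle-hole-dominated block (everything except
virtual-virtual) suffices for one-shot calculations; self-consistent
solvers, which mix virtual-virtual channels into the screening as the
propagators update, use the full orbital-product space.  The NAF basis is
built once from the initial reference and never rebuilt inside a
self-consistency loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .refstate import ReferenceShapeError, ReferenceState

__all__ = ["NAFBasis", "build_naf", "project_interaction"]

_BLOCK_CHOICES = ("ph_only", "full_product")


@dataclass
class NAFBasis:
    """Orthonormal NAF transform and the spectrum it was truncated from.

    ``transform`` has shape ``(N_aux, N_NAF)`` with orthonormal columns;
    ``eigenvalues`` is the full nonincreasing spectrum of the Gram matrix
    (length ``N_aux``), of which the first ``N_NAF`` are retained.
    """

    transform: np.ndarray
    eigenvalues: np.ndarray
    threshold: float
    block_choice: str

    @property
    def n_naf(self) -> int:
        return self.transform.shape[1]

    @property
    def dropped_eigenvalue_sum(self) -> float:
        return float(self.eigenvalues[self.n_naf:].sum())


def build_naf(
    ref: ReferenceState,
    threshold: float = 1e-5,
    block_choice: str = "ph_only",
    relative: bool = False,
) -> NAFBasis:
    """Build the NAF basis from a reference bundle.

    The threshold is applied to the raw (absolute) eigenvalues of the Gram
    matrix by default, matching the conventional single-number report of
    the truncation level; ``relative=True`` rescales it by the largest
    eigenvalue.  ``threshold = 0`` keeps all ``N_aux`` vectors.
    """
    if threshold < 0:
        raise ValueError("NAF threshold must be >= 0")
    if block_choice not in _BLOCK_CHOICES:
        raise ValueError(f"block_choice must be one of {_BLOCK_CHOICES}")
    v = ref.interaction_full
    if block_choice == "ph_only":
        v = v.copy()
        o = ref.n_occupied
        v[:, o:, o:] = 0.0  # exclude the virtual-virtual block
    naux = v.shape[0]
    gram = v.reshape(naux, -1) @ v.reshape(naux, -1).T
    gram = 0.5 * (gram + gram.T)
    eigval, eigvec = np.linalg.eigh(gram)
    eigval, eigvec = eigval[::-1].copy(), eigvec[:, ::-1].copy()
    cut = threshold * (eigval[0] if relative and eigval[0] > 0 else 1.0)
    keep = eigval > cut
    if threshold == 0.0:
        keep = np.ones_like(keep)
    return NAFBasis(
        transform=eigvec[:, keep],
        eigenvalues=np.clip(eigval, 0.0, None),
        threshold=threshold,
        block_choice=block_choice,
    )


def project_interaction(ref: ReferenceState, naf: NAFBasis) -> ReferenceState:
    """Contract the auxiliary index of the interaction into the NAF basis.

    Returns a new bundle whose interaction tensor has auxiliary dimension
    ``N_NAF``; all other fields are unchanged.  The Frobenius error of
    reconstructing the (block-restricted) interaction is bounded by the
    square root of the sum of dropped eigenvalues.
    """
    if naf.transform.shape[0] != ref.n_aux:
        raise ReferenceShapeError(
            f"NAF transform has {naf.transform.shape[0]} auxiliary rows, "
            f"bundle has N_aux = {ref.n_aux}"
        )
    projected = np.tensordot(naf.transform.T, ref.interaction_full, axes=1)
    return ReferenceState(
        orbital_energies=ref.orbital_energies.copy(),
        n_occupied=ref.n_occupied,
        mo_coefficients=ref.mo_coefficients.copy(),
        fock_mo=ref.fock_mo.copy(),
        exchange_mo=ref.exchange_mo.copy(),
        vxc_mo=ref.vxc_mo.copy(),
        interaction_full=projected,
        metadata={**ref.metadata, "naf_threshold": naf.threshold,
                  "naf_block": naf.block_choice},
    )
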