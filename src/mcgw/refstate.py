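"""Mean-field reference states for moment-conserving GW calculations.

Every GW calculation in this package is seeded by a converged, closed-shell,
spin-restricted mean-field state: molecular-orbital (MO) energies and
coefficients, the Fock matrix, exchange and exchange-correlation potential
matrices, and a three-index factorized Coulomb interaction

    (pq|rs) = sum_P V[P, p, q] V[P, r, s]

obtained from density fitting or a Cholesky decomposition.  The internal unit
is Hartree throughout; conversion to eV happens only at reporting time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReferenceState",
    "ReferenceValidationError",
    "ReferenceFormatError",
    "ReferenceShapeError",
    "OptionalDependencyError",
    "load_reference",
    "save_reference",
    "static_self_energy",
    "adapter_build",
    "HARTREE_TO_EV",
]

HARTREE_TO_EV = 27.211386245988


class ReferenceValidationError(ValueError):
    """A reference-state invariant is violated; the message names it."""


class ReferenceFormatError(IOError):
    """The on-disk container does not conform to the documented layout."""


class ReferenceShapeError(ReferenceValidationError):
    """Array dimensions are inconsistent with the stated o, v, N_aux."""


class OptionalDependencyError(ImportError):
    """An optional external quantum-chemistry engine is not installed."""


@dataclass
class ReferenceState:
    """A closed-shell mean-field reference bundle.

    Parameters
    ----------
    orbital_energies
        Canonical MO energies ``eps_p`` in Hartree, ascending, length ``M``.
        For a non-canonical bundle these are the eigenvalues of ``fock_mo``.
    n_occupied
        Number of doubly occupied spatial orbitals ``o``; ``N_elec = 2 o``.
    mo_coefficients
        AO-to-MO transformation ``C`` (``n_ao x M``).
    fock_mo, exchange_mo, vxc_mo
        Fock matrix, exchange matrix ``K[D]`` and exchange-correlation
        potential ``V_xc`` in the MO basis (``M x M``, real symmetric).
        Both potential matrices are zero for a Hartree-Fock reference.
    interaction_full
        Three-index Coulomb factor ``V[P, p, q]`` (``N_aux x M x M``),
        symmetric in the two orbital indices (real orbitals).
    metadata
        Free-form provenance: basis name, reference kind, electron count.
    """

    orbital_energies: np.ndarray
    n_occupied: int
    mo_coefficients: np.ndarray
    fock_mo: np.ndarray
    exchange_mo: np.ndarray
    vxc_mo: np.ndarray
    interaction_full: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.orbital_energies = np.asarray(self.orbital_energies, dtype=float)
        self.mo_coefficients = np.asarray(self.mo_coefficients, dtype=float)
        self.fock_mo = np.asarray(self.fock_mo, dtype=float)
        self.exchange_mo = np.asarray(self.exchange_mo, dtype=float)
        self.vxc_mo = np.asarray(self.vxc_mo, dtype=float)
        self.interaction_full = np.asarray(self.interaction_full, dtype=float)

    # -- derived dimensions -------------------------------------------------

    @property
    def n_orbitals(self) -> int:
        return self.orbital_energies.shape[0]

    @property
    def n_virtual(self) -> int:
        return self.n_orbitals - self.n_occupied

    @property
    def n_aux(self) -> int:
        return self.interaction_full.shape[0]

    @property
    def n_electrons(self) -> int:
        return 2 * self.n_occupied

    @property
    def interaction_ph(self) -> np.ndarray:
        """Particle-hole slice ``V[P, i, a]`` flattened to ``(N_aux, o*v)``.

        The compound index runs over occupied-major ``(i, a)`` pairs.  This
        is derived from :attr:`interaction_full`, never stored separately.
        """
        o = self.n_occupied
        block = self.interaction_full[:, :o, o:]
        return block.reshape(self.n_aux, o * self.n_virtual)

    @property
    def orbital_energy_differences(self) -> np.ndarray:
        """Diagonal ``d_{ia} = eps_a - eps_i`` over the same (i, a) order."""
        o = self.n_occupied
        eps = self.orbital_energies
        return (eps[None, o:] - eps[:o, None]).ravel()

    @property
    def is_canonical(self) -> bool:
        """Whether the Fock matrix is diagonal with the orbital energies."""
        return bool(
            np.allclose(self.fock_mo, np.diag(self.orbital_energies),
                        atol=1e-10)
        )

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Check every invariant; raise naming the first violation."""
        m = self.n_orbitals
        o = self.n_occupied
        v = self.n_virtual
        if o <= 0 or v <= 0:
            raise ReferenceValidationError(
                "closed-shell reference requires o >= 1 and v >= 1"
            )
        if self.fock_mo.shape != (m, m):
            raise ReferenceShapeError(
                f"fock_mo shape {self.fock_mo.shape} != ({m}, {m})"
            )
        for name in ("exchange_mo", "vxc_mo"):
            mat = getattr(self, name)
            if mat.shape != (m, m):
                raise ReferenceShapeError(
                    f"{name} shape {mat.shape} != ({m}, {m})"
                )
            if not np.allclose(mat, mat.T, atol=1e-10):
                raise ReferenceValidationError(f"{name} is not symmetric")
        if self.interaction_full.ndim != 3 or self.interaction_full.shape[1:] != (m, m):
            raise ReferenceShapeError(
                f"interaction_full shape {self.interaction_full.shape} "
                f"!= (N_aux, {m}, {m})"
            )
        if self.mo_coefficients.ndim != 2 or self.mo_coefficients.shape[1] != m:
            raise ReferenceShapeError(
                f"mo_coefficients shape {self.mo_coefficients.shape} "
                f"incompatible with M = {m}"
            )
        eps = self.orbital_energies
        if np.any(np.diff(eps) < -1e-12):
            raise ReferenceValidationError(
                "orbital_energies are not sorted ascending"
            )
        if not eps[o - 1] < eps[o]:
            raise ReferenceValidationError(
                "gapless reference: eps_HOMO >= eps_LUMO"
            )
        if not np.allclose(
            self.interaction_full, self.interaction_full.transpose(0, 2, 1),
            atol=1e-10,
        ):
            raise ReferenceValidationError(
                "interaction_full is not symmetric in its orbital indices"
            )
        if not np.allclose(self.fock_mo, self.fock_mo.T, atol=1e-10):
            raise ReferenceValidationError("fock_mo is not symmetric")
        fock_eigs = np.linalg.eigvalsh(self.fock_mo)
        if not np.allclose(fock_eigs, eps, atol=1e-7):
            raise ReferenceValidationError(
                "orbital_energies do not match the Fock-matrix spectrum"
            )


def static_self_energy(ref: ReferenceState) -> np.ndarray:
    """Static self-energy ``Sigma_inf = K[D] - V_xc``.

    Removes the explicit exchange-correlation contribution of the reference
    so that the perturbative expansion is well defined; identically zero for
    a canonical Hartree-Fock reference.
    """
    sigma = ref.exchange_mo - ref.vxc_mo
    return 0.5 * (sigma + sigma.T)


# -- HDF5 container ---------------------------------------------------------

_LAYOUT = {
    "/reference/energies": "orbital_energies",
    "/reference/coeffs": "mo_coefficients",
    "/reference/fock": "fock_mo",
    "/reference/exchange": "exchange_mo",
    "/reference/vxc": "vxc_mo",
    "/interaction/full": "interaction_full",
}


def save_reference(ref: ReferenceState, path) -> None:
    """Write a bundle to the hierarchical (HDF5) container layout."""
    import h5py

    ref.validate()
    with h5py.File(path, "w") as fh:
        for dset, attr in _LAYOUT.items():
            fh.create_dataset(dset, data=np.asarray(getattr(ref, attr),
                                                    dtype=np.float64))
        fh.create_dataset("/interaction/aux_dim", data=ref.n_aux)
        meta = fh.create_group("/reference/meta")
        meta.attrs["basis"] = str(ref.metadata.get("basis", "synthetic"))
        meta.attrs["reference"] = str(ref.metadata.get("reference", "HF"))
        meta.attrs["n_elec"] = int(ref.metadata.get("n_elec",
                                                    ref.n_electrons))
        fh.attrs["o"] = ref.n_occupied
        fh.attrs["v"] = ref.n_virtual
        fh.attrs["M"] = ref.n_orbitals
        fh.attrs["N_aux"] = ref.n_aux


def load_reference(path) -> ReferenceState:
    """Read a bundle from the container and validate every invariant."""
    import h5py

    arrays = {}
    with h5py.File(path, "r") as fh:
        for dset, attr in _LAYOUT.items():
            if dset not in fh:
                raise ReferenceFormatError(f"missing dataset {dset!r}")
            arrays[attr] = fh[dset][()]
        if "o" not in fh.attrs:
            raise ReferenceFormatError("missing dimension attribute 'o'")
        o = int(fh.attrs["o"])
        meta_grp = fh.get("/reference/meta")
        metadata = dict(meta_grp.attrs) if meta_grp is not None else {}
        metadata = {k: (v.item() if hasattr(v, "item") else v)
                    for k, v in metadata.items()}
    m = arrays["orbital_energies"].shape[0]
    if int(o) >= m or o < 1:
        raise ReferenceShapeError(
            f"o = {o} inconsistent with M = {m} orbitals"
        )
    ref = ReferenceState(n_occupied=o, metadata=metadata, **arrays)
    ref.validate()
    return ref


# -- optional quantum-chemistry adapter -------------------------------------

def adapter_build(geometry, basis: str, reference: str = "HF") -> ReferenceState:
    """Build a bundle from a quantum-chemistry engine (optional path).

    Requires ``pyscf``; runs a restricted mean-field calculation with density
    fitting on the molecule in the XYZ file ``geometry`` and packs the result
    into a :class:`ReferenceState`.  Effective core potentials and grids are
    the engine's concern; the GW core never sees them.
    """
    try:
        from pyscf import gto, scf, df  # noqa: F401
    except ImportError as exc:  # pragma: no cover - engine not installed
        raise OptionalDependencyError(
            "adapter_build requires the optional quantum-chemistry engine "
            "'pyscf'; install it or supply a reference-state container"
        ) from exc

    mol = gto.M(atom=str(geometry), basis=basis)  # pragma: no cover
    if mol.nelectron % 2:  # pragma: no cover
        raise ReferenceValidationError("closed-shell only")
    if reference.upper() != "HF":  # pragma: no cover
        raise NotImplementedError("only HF references in the adapter")
    mf = scf.RHF(mol).density_fit().run()  # pragma: no cover
    if not mf.converged:  # pragma: no cover
        raise RuntimeError("SCF non-convergence in the engine")
    c = mf.mo_coeff  # pragma: no cover
    nmo = c.shape[1]  # pragma: no cover
    lpq = df.incore.aux_e2(mol, mf.with_df.auxmol)  # pragma: no cover
    j2c = mf.with_df.auxmol.intor("int2c2e")  # pragma: no cover
    import scipy.linalg as sla  # pragma: no cover
    low = sla.cholesky(j2c, lower=True)  # pragma: no cover
    v_ao = sla.solve_triangular(  # pragma: no cover
        low, lpq.reshape(-1, mol.nao**2).T.reshape(mol.nao**2, -1).T,
        lower=True,
    ).reshape(-1, mol.nao, mol.nao)
    v_mo = np.einsum("Puv,ui,vj->Pij", v_ao, c, c)  # pragma: no cover
    fock = np.diag(mf.mo_energy)  # pragma: no cover
    zero = np.zeros((nmo, nmo))  # pragma: no cover
    return ReferenceState(  # pragma: no cover
        orbital_energies=mf.mo_energy,
        n_occupied=mol.nelectron // 2,
        mo_coefficients=c,
        fock_mo=fock,
        exchange_mo=zero,
        vxc_mo=zero,
        interaction_full=v_mo,
        metadata={"basis": basis, "reference": "HF",
                  "n_elec": mol.nelectron},
    )
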