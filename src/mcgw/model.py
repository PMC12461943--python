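"""Model/results front end for moment-conserving GW calculations.

A :class:`MomentGW` instance binds a mean-field reference state to a solver
configuration; :meth:`MomentGW.fit` executes the chosen variant and returns
a :class:`MomentGWResults` carrying the correlated pole set, the frontier
excitations, quasiparticle weights, convergence diagnostics and a
``summary()`` table, with spectral functions and Dyson orbitals available
as methods of the results object.

Example
-------
>>> from mcgw import MomentGW
>>> model = MomentGW.from_synthetic(o=2, v=2, n_aux=4, seed=7,
...                                 variant="g0w0", screening="tda", n_max=7)
>>> results = model.fit()
>>> print(results.summary())          # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np

from . import solvers
from .refstate import HARTREE_TO_EV, ReferenceState, load_reference
from .solvers import GWResult, SolverConfig
from .upfold import spectral_function as _spectral_function
from .upfold import dyson_orbitals as _dyson_orbitals

__all__ = ["MomentGW", "MomentGWResults"]


class MomentGW:
    """A moment-conserving GW model over a mean-field reference state.

    Parameters mirror :class:`~mcgw.solvers.SolverConfig`; any keyword it
    accepts can be passed here.
    """

    def __init__(self, ref: ReferenceState, **config) -> None:
        ref.validate()
        self.ref = ref
        self.config = SolverConfig(**config)
        self.config.validate()

    @classmethod
    def from_file(cls, path, **config) -> "MomentGW":
        """Build the model from a reference-state container on disk."""
        return cls(load_reference(path), **config)

    @classmethod
    def from_synthetic(cls, o: int, v: int, n_aux: int, seed: int = 0,
                       **config) -> "MomentGW":
        """Build the model over a deterministic synthetic fixture."""
        from .synthetic import FixtureSpec, random_reference

        fixture_keys = {"gap", "energy_scale", "coupling_scale"}
        fx = {k: config.pop(k) for k in list(config) if k in fixture_keys}
        ref = random_reference(FixtureSpec(o=o, v=v, n_aux=n_aux, seed=seed,
                                           **fx))
        return cls(ref, **config)

    def fit(self) -> "MomentGWResults":
        """Run the configured GW variant and wrap its result."""
        raw = solvers.run(self.ref, self.config)
        return MomentGWResults(self, raw)


class MomentGWResults:
    """Estimates and diagnostics from a fitted moment-conserving GW model."""

    def __init__(self, model: MomentGW, raw: GWResult) -> None:
        self.model = model
        self.raw = raw

    # -- primary estimates --------------------------------------------------

    @property
    def poles(self):
        return self.raw.poles

    @property
    def ip(self) -> float:
        """First ionization potential in Hartree."""
        return self.raw.ip

    @property
    def ea(self) -> float:
        """First electron affinity in Hartree."""
        return self.raw.ea

    @property
    def gap(self) -> float:
        """Fundamental gap ``IP - EA`` in Hartree."""
        return self.raw.gap

    @property
    def ip_ev(self) -> float:
        return self.raw.ip * HARTREE_TO_EV

    @property
    def ea_ev(self) -> float:
        return self.raw.ea * HARTREE_TO_EV

    @property
    def gap_ev(self) -> float:
        return self.raw.gap * HARTREE_TO_EV

    @property
    def converged(self) -> bool:
        return self.raw.converged

    @property
    def iterations(self) -> int:
        return self.raw.iterations

    def quasiparticle_energies(self) -> np.ndarray:
        return self.poles.quasiparticle_energies()

    # -- derived spectra ----------------------------------------------------

    def spectral_function(self, omega_grid, delta: float | None = None):
        """Broadened spectral function ``A(w)`` on a frequency grid (Ha)."""
        delta = self.model.config.delta if delta is None else delta
        return _spectral_function(self.poles, omega_grid, delta)

    def dyson_orbitals(self, selection=None):
        """AO-space Dyson orbitals for selected poles (default: HOMO, LUMO)."""
        if selection is None:
            selection = [self.poles.homo_index, self.poles.lumo_index]
        return _dyson_orbitals(self.poles, self.model.ref.mo_coefficients,
                               selection)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        cfg = self.model.config
        ref = self.model.ref
        lines = [
            "Moment-conserving GW results",
            "=" * 46,
            f"{'variant':<24}{cfg.variant}",
            f"{'screening':<24}{cfg.screening.upper()}",
            f"{'moment order n_max':<24}{cfg.n_max}",
            f"{'orbitals (occ/vir)':<24}{ref.n_occupied}/{ref.n_virtual}",
            f"{'auxiliary dimension':<24}{ref.n_aux}",
            f"{'iterations':<24}{self.iterations}",
            f"{'converged':<24}{self.converged}",
            "-" * 46,
            f"{'IP [eV]':<24}{self.ip_ev:.6f}",
            f"{'EA [eV]':<24}{self.ea_ev:.6f}",
            f"{'gap [eV]':<24}{self.gap_ev:.6f}",
            f"{'QP weight at IP':<24}{self.raw.qp_weight_ip:.6f}",
            f"{'QP weight at EA':<24}{self.raw.qp_weight_ea:.6f}",
            f"{'poles':<24}{self.poles.n_poles}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<MomentGWResults {self.raw.variant}@"
                f"{self.raw.screening.upper()} IP={self.ip_ev:.4f} eV "
                f"converged={self.converged}>")
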