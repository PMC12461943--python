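import numpy as np
import pytest
from hypothesis import given, strategies as st

from mcgw.oracle import exact_tda_excitations, exact_gw_poles
from mcgw.solvers import (
    SolverConfig,
    aufbau_fill,
    electron_number,
    run,
    run_evgw,
    run_fsgw,
    run_g0w0,
    run_qsgw,
    run_scgw,
    _static_potential_lorentzian,
    _static_potential_srg,
)
from mcgw.synthetic import FixtureSpec, random_reference, rotate_reference
from mcgw.upfold import PoleSet


def _cfg(**kw):
    kw.setdefault("naf_threshold", 0.0)
    kw.setdefault("n_max", 3)
    return SolverConfig(**kw)


class TestAufbauFill:
    def test_unit_weights_fill_exactly(self):
        e = np.array([-2.0, -1.0, 0.5, 1.5])
        w = np.ones(4)
        mu, occ, n = aufbau_fill(e, w, 4)
        assert n == 4.0
        assert occ.tolist() == [True, True, False, False]
        assert mu == pytest.approx(-0.25)

    @given(st.integers(0, 40))
    def test_matches_brute_force_prefix_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 8))
        e = np.sort(rng.uniform(-2, 2, k))
        w = rng.uniform(0, 1, k)
        target = 2 * int(rng.integers(1, k))
        _, occ, n = aufbau_fill(e, w, target)
        cums = [2 * w[:j].sum() for j in range(k + 1)]
        best = min(cums, key=lambda c: abs(c - target))
        assert n == pytest.approx(best)
        assert occ.sum() == int(np.argmin(np.abs(np.array(cums) - target)))

    def test_fractional_weights_pick_the_best_prefix(self):
        e = np.array([-2.0, -1.0, -0.5, 1.0])
        w = np.array([1.0, 0.9, 0.1, 1.0])
        _, occ, n = aufbau_fill(e, w, 4)
        # prefixes give 0, 2, 3.8, 4.0, 6.0 -> three poles, N = 4.0
        assert occ.tolist() == [True, True, True, False]
        assert n == pytest.approx(4.0)

    def test_degenerate_energies_break_ties_by_index(self):
        e = np.array([-1.0, -1.0, -1.0])
        w = np.ones(3)
        _, occ, _ = aufbau_fill(e, w, 2)
        assert occ.tolist() == [True, False, False]

    def test_empty_pole_set_raises(self):
        with pytest.raises(ValueError, match="empty"):
            aufbau_fill(np.array([]), np.array([]), 2)

    def test_odd_electron_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            aufbau_fill(np.array([0.0]), np.array([1.0]), 3)


class TestElectronNumber:
    def _poles(self, seed=0, n=6, m=3):
        rng = np.random.default_rng(seed)
        chi = rng.normal(size=(m, n))
        chi /= np.linalg.norm(chi, axis=0, keepdims=True) * np.sqrt(n / m)
        e = np.sort(rng.uniform(-2, 2, n))
        return PoleSet(energies=e, residues=chi, chemical_potential=0.0,
                       occupied=e < 0.0)

    def test_mu_below_all_poles_counts_zero(self):
        p = self._poles()
        assert electron_number(p, p.energies.min() - 1) == 0.0

    def test_mu_above_all_poles_counts_all_weight(self):
        p = self._poles()
        total = 2.0 * p.weights.sum()
        assert electron_number(p, p.energies.max() + 1) == pytest.approx(total)

    def test_matches_direct_density_trace(self):
        p = self._poles(seed=4)
        mu = 0.3
        below = p.energies < mu
        rho = 2.0 * p.residues[:, below] @ p.residues[:, below].T
        assert electron_number(p, mu) == pytest.approx(np.trace(rho))


class TestG0W0:
    def test_zero_interaction_recovers_mean_field_frontier(self, free_ref):
        res = run_g0w0(free_ref, _cfg())
        o = free_ref.n_occupied
        assert res.ip == pytest.approx(-free_ref.orbital_energies[o - 1],
                                       abs=1e-12)
        assert res.ea == pytest.approx(-free_ref.orbital_energies[o],
                                       abs=1e-12)
        assert res.gap == pytest.approx(res.ip - res.ea)

    def test_high_order_ip_matches_the_oracle(self, small_ref):
        spec = exact_tda_excitations(small_ref.interaction_ph,
                                     small_ref.orbital_energy_differences)
        exact = exact_gw_poles(small_ref, spec)
        exact_ip = -exact.energies[exact.homo_index]
        res = run_g0w0(small_ref, _cfg(n_max=13))
        assert abs(res.ip - exact_ip) < 1e-6

    def test_ip_sequence_is_cauchy_in_moment_order(self, small_ref):
        cfg = _cfg()
        ips = [run_g0w0(small_ref, _cfg(n_max=n)).ip
               for n in (1, 3, 5, 7, 9, 11, 13)]
        assert abs(ips[-1] - ips[-2]) < cfg.e_tol


class TestEvGW:
    def test_zero_self_energy_converges_immediately(self, free_ref):
        res = run_evgw(free_ref, _cfg(variant="evgw"))
        assert res.converged and res.iterations == 1
        np.testing.assert_allclose(
            np.sort(res.poles.quasiparticle_energies()),
            free_ref.orbital_energies, atol=1e-10)

    def test_evgw0_keeps_the_screening_bit_identical(self, small_ref):
        res = run_evgw(small_ref, _cfg(variant="evgw0", e_tol=1e-10))
        prints = {d["eta_fingerprint"] for d in res.diagnostics}
        assert len(prints) == 1
        assert res.iterations >= 2

    def test_converged_energies_are_a_fixed_point(self, small_ref):
        cfg = _cfg(variant="evgw", e_tol=1e-9)
        res = run_evgw(small_ref, cfg)
        assert res.converged
        assert res.diagnostics[-1]["delta_eps"] < cfg.e_tol

    def test_variant_guard(self, small_ref):
        with pytest.raises(ValueError):
            run_evgw(small_ref, _cfg(variant="g0w0"))


class TestQsGW:
    def test_static_potentials_are_hermitian(self):
        rng = np.random.default_rng(0)
        eps = np.array([-1.0, 0.8])
        ext = np.array([-1.5, 1.2, 2.0])
        coup = rng.normal(size=(2, 3))
        for vs in (_static_potential_lorentzian(eps, ext, coup, 1e-3),
                   _static_potential_srg(eps, ext, coup, 100.0)):
            np.testing.assert_allclose(vs, vs.T, atol=1e-14)

    def test_srg_s_to_zero_vanishes(self):
        eps = np.array([-1.0])
        ext = np.array([0.5])
        coup = np.array([[0.3]])
        vs = _static_potential_srg(eps, ext, coup, 0.0)
        assert np.abs(vs).max() == 0.0

    def test_srg_s_to_infinity_matches_unregularized_one_pole(self):
        # single pole, single orbital: limit is v^2 / Delta
        eps = np.array([-1.0])
        ext = np.array([0.5])
        coup = np.array([[0.3]])
        vs = _static_potential_srg(eps, ext, coup, 1e8)
        delta0 = _static_potential_lorentzian(eps, ext, coup, 0.0)
        assert vs[0, 0] == pytest.approx(0.3**2 / (-1.0 - 0.5), abs=1e-12)
        assert vs[0, 0] == pytest.approx(delta0[0, 0], abs=1e-12)

    @pytest.mark.parametrize("variant", ["qsgw", "qsgw_srg"])
    def test_qsgw_converges_with_unit_weights(self, small_ref, variant):
        res = run_qsgw(small_ref, _cfg(variant=variant))
        assert res.converged
        np.testing.assert_allclose(res.poles.weights,
                                   np.ones(small_ref.n_orbitals),
                                   atol=1e-12)


class TestScGW:
    def test_first_iteration_equals_g0w0(self, small_ref):
        one_shot = run_g0w0(small_ref, _cfg())
        sc = run_scgw(small_ref, _cfg(variant="scgw"))
        assert sc.diagnostics[0]["ip"] == pytest.approx(one_shot.ip,
                                                        abs=1e-12)

    def test_gw0_keeps_the_screening_bit_identical(self, small_ref):
        res = run_scgw(small_ref, _cfg(variant="gw0", e_tol=1e-9,
                                       moment_tol=1e-8))
        prints = {d["eta_fingerprint"] for d in res.diagnostics}
        assert len(prints) == 1
        assert res.iterations >= 2

    def test_zero_interaction_is_a_one_iteration_fixed_point(self, free_ref):
        res = run_scgw(free_ref, _cfg(variant="scgw"))
        assert res.converged
        o = free_ref.n_occupied
        assert res.ip == pytest.approx(-free_ref.orbital_energies[o - 1],
                                       abs=1e-10)
        assert res.diagnostics[-1]["electron_number_error"] < 1e-12

    def test_fixed_point_is_independent_of_a_perturbed_start(self, tiny_ref):
        cfg = _cfg(variant="scgw", e_tol=1e-8, moment_tol=1e-7)
        base = run_scgw(tiny_ref, cfg)
        shaken = run_scgw(tiny_ref, cfg,
                          initial_energies=tiny_ref.orbital_energies
                          + np.array([-0.05, 0.07]))
        assert base.converged and shaken.converged
        assert abs(base.ip - shaken.ip) < 10 * cfg.e_tol

    def test_electron_number_drift_is_reported(self, small_ref):
        res = run_scgw(small_ref, _cfg(variant="scgw"))
        assert "electron_number_error" in res.diagnostics[-1]


class TestFsGW:
    def test_zero_self_energy_reduces_to_the_reference(self, free_ref):
        res = run_fsgw(free_ref, _cfg(variant="fsgw"))
        assert res.converged
        assert res.extras["zeta"] == pytest.approx(0.0, abs=1e-12)
        o = free_ref.n_occupied
        assert res.ip == pytest.approx(-free_ref.orbital_energies[o - 1],
                                       abs=1e-10)

    def test_electron_number_is_enforced_at_convergence(self, small_ref):
        res = run_fsgw(small_ref, _cfg(variant="fsgw"))
        assert res.converged
        assert res.diagnostics[-1]["electron_number_error"] < 1e-6

    def test_equivalent_rotated_reference_gives_the_same_ip(self, small_ref):
        cfg = _cfg(variant="fsgw")
        base = run_fsgw(small_ref, cfg)
        rotated = rotate_reference(small_ref, seed=11)
        other = run_fsgw(rotated, cfg)
        assert abs(base.ip - other.ip) < 10 * cfg.e_tol


class TestCrossVariantContracts:
    def test_evgw_variants_coincide_at_zero_coupling(self, free_ref):
        a = run_evgw(free_ref, _cfg(variant="evgw0"))
        b = run_evgw(free_ref, _cfg(variant="evgw"))
        assert a.ip == pytest.approx(b.ip, abs=1e-12)

    @pytest.mark.parametrize("variant", ["evgw", "scgw", "fsgw"])
    def test_diis_on_and_off_reach_the_same_fixed_point(self, small_ref,
                                                        variant):
        cfg_on = _cfg(variant=variant, use_diis=True)
        cfg_off = _cfg(variant=variant, use_diis=False)
        r_on = run(small_ref, cfg_on)
        r_off = run(small_ref, cfg_off)
        assert abs(r_on.ip - r_off.ip) < 10 * cfg_on.e_tol

    def test_canonical_reference_required_outside_fsgw(self, small_ref):
        rotated = rotate_reference(small_ref, seed=2)
        with pytest.raises(ValueError, match="canonical"):
            run(rotated, _cfg(variant="g0w0"))

    def test_config_validation(self):
        with pytest.raises(ValueError, match="odd"):
            SolverConfig(n_max=4).validate()
        with pytest.raises(ValueError, match="variant"):
            SolverConfig(variant="g3w2").validate()
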