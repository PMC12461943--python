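import numpy as np
import pytest

from mcgw.oracle import exact_tda_excitations, exact_gw_poles
from mcgw.selfenergy import SelfEnergyMoments, assemble
from mcgw.solvers import SolverConfig, run_g0w0
from mcgw.synthetic import pole_model_moments
from mcgw.upfold import (
    PoleSet,
    UpfoldedHamiltonian,
    block_lanczos,
    diagonalize,
    downfold_sigma,
    dyson_orbitals,
    recover_moments,
    spectral_function,
)


def _random_pole_moments(m, n_hole, n_part, n_max, seed, scale=0.5):
    rng = np.random.default_rng(seed)
    poles = [(rng.uniform(-2.5, -0.3), rng.normal(size=m) * scale)
             for _ in range(n_hole)]
    poles += [(rng.uniform(0.3, 2.5), rng.normal(size=m) * scale)
              for _ in range(n_part)]
    return pole_model_moments(poles, n_max, mu=0.0), poles


class TestBlockLanczos:
    def test_single_pole_sequence_is_identified_exactly(self):
        w = np.array([0.2, 0.5, 0.1])
        moments = pole_model_moments([(-1.3, w)], 5, mu=0.0)
        h = block_lanczos(moments, np.zeros((3, 3)))
        assert h.n_external == 1
        assert h.external[0, 0] == pytest.approx(-1.3, abs=1e-12)
        np.testing.assert_allclose(np.abs(h.coupling[:, 0]), w, atol=1e-12)

    def test_zero_moments_leave_only_the_physical_block(self):
        m = 3
        zero = SelfEnergyMoments(lesser=np.zeros((4, m, m)),
                                 greater=np.zeros((4, m, m)),
                                 static=np.zeros((m, m)), n_max=3)
        phys = np.diag([-1.0, 0.5, 1.5])
        h = block_lanczos(zero, phys)
        assert h.n_external == 0
        np.testing.assert_allclose(np.linalg.eigvalsh(h.matrix),
                                   np.diag(phys), atol=1e-14)

    def test_six_pole_model_round_trips_conserved_orders_only(self):
        # more poles per sector than the order-5 truncation can identify
        moments, poles = _random_pole_moments(2, 8, 8, 5, seed=2)
        h = block_lanczos(moments, np.zeros((2, 2)))
        rec = recover_moments(h, 6)
        for n in range(6):
            np.testing.assert_allclose(
                rec.lesser[n] + rec.greater[n],
                moments.lesser[n] + moments.greater[n],
                atol=1e-8 * max(1, np.abs(moments.lesser[n]).max()))
        # order 6 was never conserved: it generally differs
        exact6 = pole_model_moments(poles, 6, mu=0.0)
        err6 = np.abs(rec.lesser[6] - exact6.lesser[6]).max()
        assert err6 > 1e-6

    @pytest.mark.parametrize("n_max", [1, 3, 5, 9, 13])
    def test_moment_conservation_round_trip(self, n_max):
        moments, _ = _random_pole_moments(4, 8, 8, n_max, seed=n_max)
        h = block_lanczos(moments, np.zeros((4, 4)))
        rec = recover_moments(h, n_max)
        for name in ("lesser", "greater"):
            a, b = getattr(rec, name), getattr(moments, name)
            scale = np.abs(b).max()
            assert np.abs(a - b).max() <= 1e-8 * scale

    def test_even_order_is_rejected(self):
        moments, _ = _random_pole_moments(2, 2, 2, 4, seed=5)
        with pytest.raises(ValueError, match="odd"):
            block_lanczos(moments, np.zeros((2, 2)))

    def test_non_psd_zeroth_moment_is_rejected(self):
        m = 2
        bad = SelfEnergyMoments(
            lesser=np.array([-np.eye(m), np.zeros((m, m))]),
            greater=np.zeros((2, m, m)),
            static=np.zeros((m, m)), n_max=1)
        with pytest.raises(ValueError, match="invalid moment sequence"):
            block_lanczos(bad, np.zeros((m, m)))


class TestRecoverMoments:
    def test_order_zero_is_the_coupling_gram(self):
        moments, _ = _random_pole_moments(3, 2, 2, 3, seed=7)
        h = block_lanczos(moments, np.zeros((3, 3)))
        rec = recover_moments(h, 0)
        np.testing.assert_allclose(rec.lesser[0] + rec.greater[0],
                                   h.coupling @ h.coupling.T, atol=1e-12)

    def test_diagonal_external_block_powers(self):
        w = np.array([[0.4], [0.1]])
        h = UpfoldedHamiltonian(physical=np.zeros((2, 2)), coupling=w,
                                external=np.array([[0.7]]))
        rec = recover_moments(h, 3, mu=0.0)
        for n in range(4):
            np.testing.assert_allclose(rec.greater[n],
                                       0.7**n * (w @ w.T), atol=1e-14)

    def test_mu_split_matches_sector_slices(self):
        moments, _ = _random_pole_moments(3, 2, 2, 3, seed=8)
        h = block_lanczos(moments, np.zeros((3, 3)))
        by_slice = recover_moments(h, 3)
        h_anon = UpfoldedHamiltonian(physical=h.physical,
                                     coupling=h.coupling,
                                     external=h.external)
        by_mu = recover_moments(h_anon, 3, mu=0.0)
        for n in range(4):
            np.testing.assert_allclose(by_mu.lesser[n], by_slice.lesser[n],
                                       atol=1e-8)


class TestDiagonalize:
    def test_zero_coupling_gives_unit_and_zero_weights(self):
        phys = np.diag([-1.0, 1.0])
        h = UpfoldedHamiltonian(physical=phys,
                                coupling=np.zeros((2, 2)),
                                external=np.diag([-2.0, 2.0]))
        poles = diagonalize(h, 2)
        order = np.argsort(poles.energies)
        np.testing.assert_allclose(np.sort(poles.energies),
                                   [-2.0, -1.0, 1.0, 2.0], atol=1e-14)
        np.testing.assert_allclose(poles.weights[order], [0, 1, 1, 0],
                                   atol=1e-14)

    def test_completeness_of_residues(self):
        moments, _ = _random_pole_moments(3, 3, 3, 5, seed=9)
        h = block_lanczos(moments, np.diag([-1.0, 0.2, 1.0]))
        poles = diagonalize(h, 2)
        np.testing.assert_allclose(poles.residues @ poles.residues.T,
                                   np.eye(3), atol=1e-8)
        assert np.all(poles.weights <= 1 + 1e-10)
        assert np.all(poles.weights >= 0)

    def test_total_weight_per_orbital_sums_to_one(self):
        moments, _ = _random_pole_moments(3, 3, 3, 5, seed=10)
        h = block_lanczos(moments, np.diag([-1.0, 0.2, 1.0]))
        poles = diagonalize(h, 2)
        np.testing.assert_allclose((poles.residues**2).sum(axis=1),
                                   np.ones(3), atol=1e-10)

    @pytest.mark.parametrize("screening", ["tda"])
    def test_pole_positions_converge_monotonically_to_oracle(self, small_ref,
                                                             screening):
        spec = exact_tda_excitations(small_ref.interaction_ph,
                                     small_ref.orbital_energy_differences)
        exact = exact_gw_poles(small_ref, spec).quasiparticle_energies()
        errs = []
        for n_max in (1, 3, 5, 7, 9, 11, 13):
            res = run_g0w0(small_ref, SolverConfig(
                variant="g0w0", screening=screening, n_max=n_max,
                naf_threshold=0.0))
            errs.append(np.abs(res.poles.quasiparticle_energies()
                               - exact).max())
        assert all(b <= a + 1e-9 for a, b in zip(errs, errs[1:]))
        assert errs[-1] < 1e-6


class TestDownfoldedSelfEnergy:
    def test_single_pole_formula(self):
        v = np.array([[0.4], [0.1]])
        h = UpfoldedHamiltonian(physical=np.zeros((2, 2)), coupling=v,
                                external=np.array([[0.7]]))
        sig = downfold_sigma(h, [0.9], delta=0.0)
        np.testing.assert_allclose(sig[0].real, np.outer(v, v) / (0.9 - 0.7),
                                   atol=1e-14)

    def test_hermitian_part_is_symmetric_on_a_grid(self):
        moments, _ = _random_pole_moments(3, 2, 2, 3, seed=11)
        h = block_lanczos(moments, np.zeros((3, 3)))
        sig = downfold_sigma(h, np.linspace(-2, 2, 7), delta=0.05)
        np.testing.assert_allclose(sig.real, sig.real.transpose(0, 2, 1),
                                   atol=1e-12)

    def test_matches_dense_resolvent_solve(self):
        moments, _ = _random_pole_moments(3, 2, 2, 3, seed=12)
        h = block_lanczos(moments, np.zeros((3, 3)))
        grid = np.array([-1.1, 0.3, 1.7])
        sig = downfold_sigma(h, grid, delta=0.02)
        k = h.n_external
        for i, w in enumerate(grid):
            dense = h.coupling @ np.linalg.solve(
                (w + 0.02j) * np.eye(k) - h.external, h.coupling.T)
            np.testing.assert_allclose(sig[i], dense, atol=1e-10)

    def test_singular_evaluation_raises(self):
        h = UpfoldedHamiltonian(physical=np.zeros((1, 1)),
                                coupling=np.array([[0.3]]),
                                external=np.array([[0.7]]))
        with pytest.raises(ValueError, match="singular"):
            downfold_sigma(h, [0.7], delta=0.0)


class TestSpectralFunction:
    def test_single_unit_pole_integrates_to_one(self):
        poles = PoleSet(energies=np.array([0.0]),
                        residues=np.array([[1.0]]),
                        chemical_potential=-1.0,
                        occupied=np.array([False]))
        grid = np.linspace(-60, 60, 120001)
        a = spectral_function(poles, grid, delta=0.05)
        assert np.all(a >= 0)
        assert np.trapezoid(a, grid) >= 0.99

    def test_sum_rule_counts_physical_orbitals(self, small_ref):
        res = run_g0w0(small_ref, SolverConfig(n_max=5, naf_threshold=0.0))
        grid = np.linspace(-80, 80, 200001)
        a = spectral_function(res.poles, grid, delta=0.05)
        assert abs(np.trapezoid(a, grid) - small_ref.n_orbitals) < 1e-2

    def test_zero_coupling_reproduces_the_mean_field_spectrum(self, free_ref):
        res = run_g0w0(free_ref, SolverConfig(n_max=3, naf_threshold=0.0))
        grid = np.linspace(-3, 3, 1201)
        a = spectral_function(res.poles, grid, delta=0.02)
        mf_poles = PoleSet(energies=free_ref.orbital_energies,
                           residues=np.eye(free_ref.n_orbitals),
                           chemical_potential=0.0,
                           occupied=free_ref.orbital_energies < 0)
        a_mf = spectral_function(mf_poles, grid, delta=0.02)
        np.testing.assert_allclose(a, a_mf, atol=1e-8)

    def test_nonpositive_broadening_rejected(self):
        poles = PoleSet(energies=np.array([0.0]),
                        residues=np.array([[1.0]]),
                        chemical_potential=-1.0,
                        occupied=np.array([False]))
        with pytest.raises(ValueError):
            spectral_function(poles, [0.0], delta=0.0)


class TestDysonOrbitals:
    def test_identity_coefficients_return_residue_columns(self, small_ref):
        res = run_g0w0(small_ref, SolverConfig(n_max=5, naf_threshold=0.0))
        vec, w = dyson_orbitals(res.poles, np.eye(small_ref.n_orbitals),
                                [res.poles.homo_index])
        np.testing.assert_allclose(
            vec[:, 0], res.poles.residues[:, res.poles.homo_index],
            atol=1e-14)
        assert w[0] == pytest.approx(
            (res.poles.residues[:, res.poles.homo_index] ** 2).sum())

    def test_zero_coupling_homo_equals_the_homo_mo(self, free_ref):
        res = run_g0w0(free_ref, SolverConfig(n_max=3, naf_threshold=0.0))
        vec, w = dyson_orbitals(res.poles, free_ref.mo_coefficients,
                                [res.poles.homo_index])
        o = free_ref.n_occupied
        expect = free_ref.mo_coefficients[:, o - 1]
        np.testing.assert_allclose(np.abs(vec[:, 0]), np.abs(expect),
                                   atol=1e-10)
        assert w[0] == pytest.approx(1.0, abs=1e-10)
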