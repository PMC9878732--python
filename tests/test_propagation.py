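"""Ground-state preparation, Koopman excitation and the MMUT integrator."""

import numpy as np
import pytest
from scipy.linalg import expm

import chargeflow as cf
from chargeflow.constants import AU_TIME_PER_FS
from chargeflow.state import DensityMatrix, FockMatrix


def _random_spd(rng, n):
    A = rng.normal(size=(n, n))
    return A @ A.T + n * np.eye(n)


def _random_hermitian(rng, n):
    A = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
    return (A + A.conj().T) / 2


class TestLowdin:
    def test_identity_overlap_is_identity_transform(self, rng):
        P = _random_hermitian(rng, 4)
        assert np.array_equal(cf.lowdin_transform(P, np.eye(4)).values, P)

    def test_diagonal_overlap_hand_example(self):
        """S = diag(4, 1), P = I: P' = diag(4, 1) and Tr(P') = Tr(PS) = 5."""
        S = np.diag([4.0, 1.0])
        P = np.eye(2, dtype=complex)
        Pp = cf.lowdin_transform(P, S)
        assert np.allclose(Pp.values, np.diag([4.0, 1.0]), atol=1e-14)
        assert Pp.trace() == pytest.approx(5.0, abs=1e-12)

    def test_trace_maps_to_tr_ps_and_round_trips(self, rng):
        for n in (2, 3, 5):
            S = _random_spd(rng, n)
            P = _random_hermitian(rng, n)
            Pp = cf.lowdin_transform(P, S)
            assert Pp.trace() == pytest.approx(np.trace(P @ S).real, abs=1e-10)
            back = cf.lowdin_inverse(Pp, S)
            assert np.allclose(back.values, P, atol=1e-10)

    def test_non_spd_overlap_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            cf.lowdin_transform(np.eye(2), np.diag([1.0, -1.0]))


class TestGroundState:
    def test_linear_model_energies_equal_h0_spectrum(self, chain3):
        _, orb = cf.ground_state(chain3)
        assert orb.energies == pytest.approx(np.linalg.eigvalsh(chain3.core_hamiltonian()))

    def test_nonlinear_scf_energy_is_minimal_over_aufbau_configurations(self, chain3_hubbard):
        """Self-consistent filling beats every other self-consistent occupation."""
        P0, orb = cf.ground_state(chain3_hubbard)
        e_scf = cf.total_energy(chain3_hubbard, P0)

        def scf_energy_with_occupied(which):
            # fixed-point iteration occupying orbital `which` of F(P)
            P = np.zeros((3, 3), dtype=complex)
            for _ in range(2000):
                F = cf.mean_field_fock(
                    chain3_hubbard, DensityMatrix(P, "orthonormal")
                ).values
                w, V = np.linalg.eigh(F)
                P_new = 2.0 * np.outer(V[:, which], V[:, which].conj())
                if np.max(np.abs(P_new - P)) < 1e-12:
                    break
                P = 0.5 * P_new + 0.5 * P
            return cf.total_energy(chain3_hubbard, DensityMatrix(P_new, "orthonormal"))

        energies = [scf_energy_with_occupied(k) for k in range(3)]
        assert e_scf == pytest.approx(min(energies), abs=1e-8)

    def test_density_is_idempotent_in_occupation_sense(self, chain3_hubbard):
        P0, _ = cf.ground_state(chain3_hubbard)
        assert np.allclose(P0.values @ P0.values, 2.0 * P0.values, atol=1e-8)

    def test_fermi_level_degeneracy_is_an_error(self):
        # two uncoupled identical sites: HOMO and LUMO coincide
        m = cf.build_chain_model(2, [0.0, 0.0], 0.0, 2.0, 0.0, (1,), 2)
        with pytest.raises(RuntimeError, match="degenerate"):
            cf.ground_state(m)


class TestKoopmanExcitation:
    def test_swap_moves_two_electrons_between_orbitals(self, detuned_dimer):
        P0, orb = cf.ground_state(detuned_dimer)
        P1 = cf.koopman_excitation(P0, orb, 0, 1, "swap")
        occ = cf.mo_occupations(
            cf.ElectronicTrajectory(1.0, [0.0], [P1.values], [0.0]), orb, window=None
        )
        assert occ.values[0] == pytest.approx([0.0, 2.0], abs=1e-12)

    def test_single_promotion_leaves_one_electron_each(self, detuned_dimer):
        P0, orb = cf.ground_state(detuned_dimer)
        P1 = cf.koopman_excitation(P0, orb, 0, 1, "single")
        occ = cf.mo_occupations(
            cf.ElectronicTrajectory(1.0, [0.0], [P1.values], [0.0]), orb, window=None
        )
        assert occ.values[0] == pytest.approx([1.0, 1.0], abs=1e-12)

    def test_swap_site_populations_reflect_target_orbital(self, detuned_dimer):
        P0, orb = cf.ground_state(detuned_dimer)
        P1 = cf.koopman_excitation(P0, orb, 0, 1, "swap")
        lumo = orb.ortho_coefficients[:, 1]
        assert np.diag(P1.values).real == pytest.approx(2.0 * lumo**2, abs=1e-10)

    @pytest.mark.parametrize("mode", ["swap", "single"])
    def test_trace_conserved(self, detuned_dimer, mode):
        P0, orb = cf.ground_state(detuned_dimer)
        P1 = cf.koopman_excitation(P0, orb, 0, 1, mode)
        assert abs(P1.trace() - P0.trace()) < 1e-12

    def test_promoting_from_virtual_rejected(self, detuned_dimer):
        P0, orb = cf.ground_state(detuned_dimer)
        with pytest.raises(ValueError, match="not doubly occupied"):
            cf.koopman_excitation(P0, orb, 1, 0)

    def test_orbital_label_parsing(self, detuned_dimer):
        _, orb = cf.ground_state(detuned_dimer)
        assert orb.index_of("HOMO") == 0
        assert orb.index_of("LUMO") == 1
        assert orb.label(0) == "HOMO"
        assert orb.label(1) == "LUMO"


class TestMMUTStep:
    def test_zero_fock_leaves_density_unchanged(self, rng):
        P = DensityMatrix(_random_hermitian(rng, 3), "orthonormal")
        out = cf.mmut_step(P, FockMatrix(np.zeros((3, 3))), 0.01, "fs")
        assert np.allclose(out.values, P.values, atol=1e-14)

    def test_simultaneously_diagonal_f_and_p_are_stationary(self):
        P = DensityMatrix(np.diag([2.0, 0.0]).astype(complex), "orthonormal")
        F = FockMatrix(np.diag([-0.5, 0.3]))
        out = cf.mmut_step(P, F, 1.0, "as")
        assert np.allclose(out.values, P.values, atol=1e-14)

    def test_two_level_rabi_matches_closed_form(self):
        """Constant two-level F: the exact-exponential step reproduces the
        closed-form Rabi populations at any step size."""
        delta, v = 0.03, -0.02
        F = FockMatrix(np.array([[0.0, v], [v, delta]]))
        P = DensityMatrix(np.diag([2.0, 0.0]).astype(complex), "orthonormal")
        t_fs = 0.4
        out = cf.mmut_step(P, F, t_fs / 2.0, "fs")  # U spans 2*dt = t
        omega = np.sqrt(delta**2 + 4 * v**2)
        t_au = t_fs * AU_TIME_PER_FS
        p_transfer = 2.0 * (4 * v**2 / omega**2) * np.sin(omega * t_au / 2.0) ** 2
        assert out.values[1, 1].real == pytest.approx(p_transfer, abs=1e-12)

    def test_step_is_exactly_unitary(self, rng):
        F = FockMatrix(_random_hermitian(rng, 4))
        P = DensityMatrix(_random_hermitian(rng, 4) + 4 * np.eye(4), "orthonormal")
        out = cf.mmut_step(P, F, 1.0, "as")
        assert np.linalg.eigvalsh(out.values) == pytest.approx(
            np.linalg.eigvalsh(P.values), abs=1e-12
        )

    def test_non_hermitian_fock_rejected(self):
        P = DensityMatrix(np.eye(2, dtype=complex), "orthonormal")
        F = FockMatrix.__new__(FockMatrix)  # bypass constructor check
        F.values = np.array([[0.0, 1e-3], [0.0, 0.0]], dtype=complex)
        F.basis = "orthonormal"
        with pytest.raises(ValueError, match="Hermitian"):
            cf.mmut_step(P, F, 1.0, "as")


class TestPropagate:
    def test_ground_state_is_stationary(self, chain3_hubbard):
        P0, _ = cf.ground_state(chain3_hubbard)
        traj = cf.propagate(chain3_hubbard, P0, 1.0, 200, dt_unit="as")
        assert np.max(np.abs(traj.densities - traj.densities[0])) < 1e-10

    def test_linear_dynamics_matches_matrix_exponential_oracle(self, chain3):
        """U = 0: the propagated density equals exp(-iHt) P exp(+iHt)."""
        P0, orb = cf.ground_state(chain3)
        P_exc = cf.koopman_excitation(P0, orb, 0, 1, "swap")
        # site-localized coherence so the state actually evolves
        psi = np.array([1.0, 0.0, 0.0], dtype=complex)
        P_start = DensityMatrix(P_exc.values * 0.5 + np.outer(psi, psi), "orthonormal")
        n_steps = 400
        traj = cf.propagate(chain3, P_start, 2.0, n_steps, dt_unit="as")
        H = chain3.core_hamiltonian()
        t_au = traj.times_fs[-1] * AU_TIME_PER_FS
        U = expm(-1j * H * t_au)
        expected = U @ P_start.values @ U.conj().T
        assert np.max(np.abs(traj.densities[-1] - expected)) < 1e-12

    def test_linear_energy_constant_to_machine_precision(self, chain3):
        P0, orb = cf.ground_state(chain3)
        P_exc = cf.koopman_excitation(P0, orb, 0, 2, "swap")
        traj = cf.propagate(chain3, P_exc, 1.0, 500, dt_unit="as")
        assert np.max(np.abs(traj.energies - traj.energies[0])) < 1e-12

    def test_nonlinear_integrator_is_second_order(self, chain3_hubbard):
        """Global error vs a tight ODE oracle drops ~4x when dt halves."""
        from scipy.integrate import solve_ivp

        m = chain3_hubbard
        P0, orb = cf.ground_state(m)
        P_exc = cf.koopman_excitation(P0, orb, 0, 1, "swap")
        t_final_fs = 2.0

        def rhs(t, y):
            P = y[:9].reshape(3, 3) + 1j * y[9:].reshape(3, 3)
            F = cf.mean_field_fock(m, DensityMatrix(P, "orthonormal")).values
            dP = -1j * (F @ P - P @ F)
            return np.concatenate([dP.real.ravel(), dP.imag.ravel()])

        y0 = np.concatenate([P_exc.values.real.ravel(), P_exc.values.imag.ravel()])
        sol = solve_ivp(
            rhs, (0.0, t_final_fs * AU_TIME_PER_FS), y0, rtol=1e-12, atol=1e-13,
            dense_output=False,
        )
        P_ref = sol.y[:9, -1].reshape(3, 3) + 1j * sol.y[9:, -1].reshape(3, 3)

        def global_error(dt_as):
            n = int(round(t_final_fs * 1000 / dt_as))
            traj = cf.propagate(m, P_exc, dt_as, n, dt_unit="as", restart_every=0)
            return np.max(np.abs(traj.densities[-1] - P_ref))

        ratio = global_error(8.0) / global_error(4.0)
        assert 3.5 < ratio < 4.5

    def test_time_reversal_recovers_initial_state(self, chain3):
        P0, orb = cf.ground_state(chain3)
        P_exc = cf.koopman_excitation(P0, orb, 0, 1, "swap")
        fwd = cf.propagate(chain3, P_exc, 1.0, 300, dt_unit="as")
        back = cf.propagate(
            chain3, DensityMatrix(fwd.densities[-1], "orthonormal"), -1.0, 300, dt_unit="as"
        )
        assert np.max(np.abs(back.densities[-1] - P_exc.values)) < 1e-6

    def test_eigenvalue_spectrum_conserved_along_trajectory(self, chain3_hubbard):
        P0, orb = cf.ground_state(chain3_hubbard)
        P_exc = cf.koopman_excitation(P0, orb, 0, 1, "swap")
        traj = cf.propagate(chain3_hubbard, P_exc, 1.0, 1000, dt_unit="as")
        ev0 = np.sort(np.linalg.eigvalsh(traj.densities[0]))
        drift = max(
            np.max(np.abs(np.sort(np.linalg.eigvalsh(traj.densities[k])) - ev0))
            for k in (250, 500, 1000)
        )
        assert drift < 1e-10

    def test_uniform_time_grid_enforced(self):
        with pytest.raises(ValueError, match="uniform"):
            cf.ElectronicTrajectory(
                dt_fs=1.0, times_fs=[0.0, 1.0, 2.5],
                densities=np.zeros((3, 2, 2)), energies=np.zeros(3),
            )


class TestTotalEnergy:
    def test_linear_aufbau_energy_is_twice_occupied_sum(self, chain3):
        P0, orb = cf.ground_state(chain3)
        assert cf.total_energy(chain3, P0) == pytest.approx(
            2.0 * orb.energies[0], abs=1e-12
        )

    def test_invariant_under_lowdin_round_trip(self, chain3_hubbard):
        P0, _ = cf.ground_state(chain3_hubbard)
        e1 = cf.total_energy(chain3_hubbard, P0)
        P_AO = cf.lowdin_inverse(P0, chain3_hubbard.overlap)
        e2 = cf.total_energy(chain3_hubbard, P_AO)
        assert e1 == pytest.approx(e2, abs=1e-12)

    def test_energy_time_derivative_vanishes_on_linear_trajectory(self, chain3):
        P0, orb = cf.ground_state(chain3)
        P_exc = cf.koopman_excitation(P0, orb, 0, 1, "swap")
        traj = cf.propagate(chain3, P_exc, 1.0, 100, dt_unit="as")
        dE = np.gradient(traj.energies, traj.dt_fs)
        assert np.max(np.abs(dE)) < 1e-10
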