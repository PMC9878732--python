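"""MO occupations, dipole moments, fragment charges and carrier kinetics."""

import numpy as np
import pytest

import chargeflow as cf
from chargeflow.constants import AU_TIME_PER_FS, BOHR_PER_ANGSTROM
from chargeflow.state import DensityMatrix


def _single_frame(P, orb=None):
    return cf.ElectronicTrajectory(1.0, [0.0], [P.values], [0.0])


class TestMOOccupations:
    def test_ground_state_occupations_are_two_and_zero(self, chain3):
        P0, orb = cf.ground_state(chain3)
        occ = cf.mo_occupations(_single_frame(P0), orb, window=None)
        assert occ.values[0] == pytest.approx([2.0, 0.0, 0.0], abs=1e-12)

    def test_swap_excitation_inverts_the_pair(self, chain3):
        P0, orb = cf.ground_state(chain3)
        P1 = cf.koopman_excitation(P0, orb, 0, 2, "swap")
        occ = cf.mo_occupations(_single_frame(P1), orb, window=None)
        assert occ.values[0] == pytest.approx([0.0, 0.0, 2.0], abs=1e-12)

    def test_occupation_closure_along_nonlinear_trajectory(self, chain_run_short):
        model, traj, orb = chain_run_short
        occ = cf.mo_occupations(traj, orb, window=None)
        totals = occ.values.sum(axis=1)
        assert np.max(np.abs(totals - model.n_electrons)) < 1e-8

    def test_window_clipping_and_labels(self, chain_run_short):
        model, traj, orb = chain_run_short
        occ = cf.mo_occupations(traj, orb, window=(20, 20))
        assert len(occ.orbital_labels) == model.n_sites  # clipped to all 7
        assert "HOMO" in occ.orbital_labels and "LUMO" in occ.orbital_labels
        occ2 = cf.mo_occupations(traj, orb, window=(1, 0))
        assert occ2.orbital_labels == ["HOMO-1", "HOMO", "LUMO"]

    def test_two_level_occupation_oscillation_period(self, detuned_dimer):
        """A charge-localized coherent state beats between the two levels with
        period 2*pi*hbar/dE; occupations onto the eigenbasis stay constant,
        site populations oscillate."""
        P0, orb = cf.ground_state(detuned_dimer)
        psi = np.array([1.0, 0.0], dtype=complex)  # electron pair on site 0
        P = DensityMatrix(2.0 * np.outer(psi, psi), "orthonormal")
        dt_as = 2.0
        traj = cf.propagate(detuned_dimer, P, dt_as, 4000, dt_unit="as")
        dE = orb.energies[1] - orb.energies[0]
        period_fs = 2.0 * np.pi / dE / AU_TIME_PER_FS
        pop0 = traj.densities[:, 0, 0].real
        # successive maxima of the site population are one period apart
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(pop0)
        measured = np.mean(np.diff(peaks)) * traj.dt_fs
        assert measured == pytest.approx(period_fs, abs=traj.dt_fs)


class TestDipole:
    def test_symmetric_dimer_ground_state_has_zero_dipole(self, symmetric_dimer):
        P0, orb = cf.ground_state(symmetric_dimer)
        traj = _single_frame(P0)
        # origin at the midpoint: shift positions symmetrically
        d = symmetric_dimer.to_dict()
        pos = np.array(d["site_positions"])
        pos -= pos.mean(axis=0)
        d["site_positions"] = pos.tolist()
        import copy

        m = cf.ModelSystem.from_dict(d)
        m.dipole_operators = np.stack(
            [np.diag(pos[:, i] * BOHR_PER_ANGSTROM) for i in range(3)]
        )
        dip = cf.dipole_series(traj, m)
        assert np.max(np.abs(dip.values)) < 1e-10

    def test_translation_leaves_neutral_dipole_unchanged(self, chain3):
        P0, _ = cf.ground_state(chain3)
        traj = _single_frame(P0)
        mu1 = cf.dipole_series(traj, chain3).values[0]
        d = chain3.to_dict()
        shift = np.array([1.7, -0.4, 2.2])
        pos = np.array(d["site_positions"]) + shift
        d["site_positions"] = pos.tolist()
        d["dipole_operators"] = np.stack(
            [np.diag(pos[:, i] * BOHR_PER_ANGSTROM) for i in range(3)]
        ).tolist()
        m2 = cf.ModelSystem.from_dict(d)
        mu2 = cf.dipole_series(traj, m2).values[0]
        # neutral system: nuclear and electronic origin shifts cancel
        assert mu2 == pytest.approx(mu1, abs=1e-10)

    def test_dipole_consistent_with_site_charge_transfer(self, chain_run_short):
        """The two independent extractors agree: the dipole change equals the
        site-resolved Mulliken charge deviations weighted by site positions."""
        model, traj, orb = chain_run_short
        dip = cf.dipole_series(traj, model)
        site = cf.fragment_charges(traj, model, per_site=True)
        x = model.site_positions[:, 0] * BOHR_PER_ANGSTROM
        mu_pred = site.values @ x
        mu_x = dip.values[:, 0] - dip.values[0, 0]
        assert np.max(np.abs(mu_x - mu_pred)) < 1e-10

    def test_dipole_and_donor_charge_share_their_leading_frequency(self, chain_run_short):
        """Coarse-grained consistency: mu_x(t) and dq_donor(t) peak within one
        spectral bin of each other."""
        model, traj, _ = chain_run_short
        dip = cf.dipole_series(traj, model)
        frag = cf.fragment_charges(traj, model)
        sp_mu = cf.cross_power_spectrum(
            dip.values[:, 0], dip.values[:, 0], traj.dt_fs
        )
        sp_dq = cf.cross_power_spectrum(
            frag.series("donor"), frag.series("donor"), traj.dt_fs
        )
        nu_mu = cf.dominant_frequencies(sp_mu, 1)[0][0]
        nu_dq = cf.dominant_frequencies(sp_dq, 1)[0][0]
        bin_cm1 = cf.spectral_resolution(traj.duration_fs / 2.0)
        assert abs(nu_mu - nu_dq) <= bin_cm1 + 1e-9

    def test_projection_onto_x_axis_reproduces_mu_x(self, chain_run_short):
        model, traj, _ = chain_run_short
        dip = cf.dipole_series(traj, model)
        proj = cf.project_dipole(dip, {"x": [1.0, 0.0, 0.0]})
        assert np.array_equal(proj.series("x"), dip.values[:, 0])

    def test_orthogonal_projections_recombine_pythagorean(self, chain_run_short):
        model, traj, _ = chain_run_short
        dip = cf.dipole_series(traj, model)
        proj = cf.project_dipole(dip, {"a": [1, 0, 0], "b": [0, 1, 0]})
        norm_sq = proj.series("a") ** 2 + proj.series("b") ** 2
        expected = dip.values[:, 0] ** 2 + dip.values[:, 1] ** 2
        assert norm_sq == pytest.approx(expected, abs=1e-12)

    def test_zero_direction_rejected(self, chain_run_short):
        model, traj, _ = chain_run_short
        dip = cf.dipole_series(traj, model)
        with pytest.raises(ValueError, match="zero length"):
            cf.project_dipole(dip, {"bad": [0.0, 0.0, 0.0]})


class TestFragmentCharges:
    def test_ground_state_trajectory_has_zero_deviations(self, chain3_hubbard):
        P0, _ = cf.ground_state(chain3_hubbard)
        traj = cf.propagate(chain3_hubbard, P0, 2.0, 50, dt_unit="as")
        frag = cf.fragment_charges(traj, chain3_hubbard)
        assert np.max(np.abs(frag.values)) < 1e-10

    def test_total_charge_closure(self, chain_run_short):
        model, traj, _ = chain_run_short
        frag = cf.fragment_charges(traj, model, relative=False)
        totals = frag.values.sum(axis=1)
        expected = model.site_nuclear_charges.sum() - model.n_electrons
        assert np.max(np.abs(totals - expected)) < 1e-9

    def test_matches_brute_force_mulliken_with_general_overlap(self, rng):
        """q_A = Z_A - sum_{mu in A} (P S)_mumu, evaluated by explicit loops."""
        n = 4
        A = rng.normal(size=(n, n))
        S = A @ A.T + n * np.eye(n)
        S = S / np.max(np.abs(S))
        S = S + n * np.eye(n)  # diagonally dominant SPD
        X = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
        P_AO = X @ X.conj().T
        P_AO *= 4.0 / np.trace(P_AO @ S).real
        m = cf.ModelSystem(
            site_positions=rng.normal(size=(n, 3)),
            site_energies=np.zeros(n),
            coupling=np.zeros((n, n)),
            interaction_strengths=np.zeros(n),
            dipole_operators=np.zeros((3, n, n)),
            fragments=cf.FragmentScheme(["left", "right"], [0, 0, 1, 1]),
            n_electrons=4,
            overlap=S,
            site_nuclear_charges=[1.0, 1.0, 1.0, 1.0],
        )
        Pp = cf.lowdin_transform(P_AO, S)
        traj = cf.ElectronicTrajectory(1.0, [0.0], [Pp.values], [0.0])
        frag = cf.fragment_charges(traj, m, relative=False)

        brute = {"left": 0.0, "right": 0.0}
        for mu in range(n):
            pop = 0.0
            for nu in range(n):
                pop += (P_AO[mu, nu] * S[nu, mu]).real
            name = m.fragments.names[m.fragments.site_to_fragment[mu]]
            brute[name] += 1.0 - pop
        assert frag.values[0] == pytest.approx(
            [brute["left"], brute["right"]], abs=1e-10
        )


class TestBarycenters:
    def test_two_point_pattern_gives_exact_barycenters(self):
        dq = np.array([[0.5, -0.5]])
        pos = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        b = cf.charge_barycenters(dq, pos, dt_fs=1.0)
        assert b.r_hole[0] == pytest.approx([0.0, 0.0, 0.0], abs=0)
        assert b.r_electron[0] == pytest.approx([2.0, 0.0, 0.0], abs=0)

    def test_mirror_symmetric_pattern_gives_mirror_barycenters(self):
        pos = np.array([[-2.0, 0, 0], [-1.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        dq = np.array([[0.3, -0.1, 0.1, -0.3]])
        b = cf.charge_barycenters(dq, pos, dt_fs=1.0)
        assert b.r_hole[0, 0] == pytest.approx(-b.r_electron[0, 0], abs=1e-12)

    def test_random_sparse_patterns_match_direct_summation(self, rng):
        n, T = 6, 40
        pos = rng.normal(size=(n, 3))
        dq = rng.normal(scale=0.2, size=(T, n))
        dq[rng.random(size=(T, n)) < 0.5] = 0.0
        dq = dq[(np.abs(dq).sum(axis=1) > 0)]
        b = cf.charge_barycenters(dq, pos, threshold=1e-12, dt_fs=1.0)
        for t in range(dq.shape[0]):
            wp = np.clip(dq[t], 0, None)
            if wp.sum() > 1e-12:
                assert b.r_hole[t] == pytest.approx(wp @ pos / wp.sum(), abs=1e-12)

    def test_low_weight_frames_marked_invalid_not_interpolated(self):
        dq = np.array([[0.5, -0.5], [1e-5, -1e-5], [0.4, -0.4]])
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        b = cf.charge_barycenters(dq, pos, threshold=1e-3, dt_fs=1.0)
        assert not b.valid_hole[1] and b.valid_hole[0] and b.valid_hole[2]
        assert np.isnan(b.r_hole[1]).all()

    def test_all_invalid_is_an_error(self):
        with pytest.raises(ValueError, match="threshold"):
            cf.charge_barycenters(np.zeros((5, 2)), np.zeros((2, 3)), dt_fs=1.0)

    def test_doubling_charge_magnitudes_leaves_barycenters_unchanged(self, rng):
        pos = rng.normal(size=(5, 3))
        dq = rng.normal(size=(20, 5))
        b1 = cf.charge_barycenters(dq, pos, dt_fs=0.1)
        b2 = cf.charge_barycenters(2.0 * dq, pos, dt_fs=0.1)
        assert np.allclose(b1.r_hole, b2.r_hole, equal_nan=True)
        m1, m2 = cf.rms_metrics(b1), cf.rms_metrics(b2)
        assert m1.d_he == pytest.approx(m2.d_he, abs=1e-12)
        assert m1.v_hole == pytest.approx(m2.v_hole, abs=1e-12)


class TestRMSMetrics:
    def _static(self, T=10):
        r_h = np.tile([0.0, 0.0, 0.0], (T, 1))
        r_e = np.tile([1.0, 0.0, 0.0], (T, 1))
        valid = np.ones(T, dtype=bool)
        return cf.BarycenterSeries(
            r_h, r_e, np.ones(T), np.ones(T), valid, valid, 1.0, np.arange(T, dtype=float)
        )

    def test_static_case(self):
        m = cf.rms_metrics(self._static())
        assert m.d_he == pytest.approx(1.0, abs=1e-14)
        assert m.v_hole == 0.0 and m.v_electron == 0.0

    def test_sinusoidal_track_rms_speed_is_a_omega_over_sqrt2(self):
        A, period_fs = 1.5, 2.0
        omega = 2 * np.pi / period_fs
        dt = 0.001  # 1 as sampling
        t = np.arange(0.0, 10 * period_fs, dt)
        r_h = np.zeros((t.size, 3))
        r_h[:, 0] = A * np.sin(omega * t)
        r_e = np.zeros_like(r_h)
        valid = np.ones(t.size, dtype=bool)
        b = cf.BarycenterSeries(
            r_h, r_e, np.ones(t.size), np.ones(t.size), valid, valid, dt, t
        )
        m = cf.rms_metrics(b)
        assert m.v_hole == pytest.approx(A * omega / np.sqrt(2.0), rel=1e-2)
        assert m.v_electron == 0.0

    def test_fewer_than_three_valid_frames_rejected(self):
        b = self._static(T=2)
        with pytest.raises(ValueError, match="3 jointly valid"):
            cf.rms_metrics(b)
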