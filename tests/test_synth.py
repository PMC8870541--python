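"""Synthetic strike/session generator: phase structure, energy transfer,
learning dynamics, reproducibility."""

import math

import numpy as np
import pytest

from strikeslide.design import make_design
from strikeslide.segmentation import axial_speed, detect_contact
from strikeslide.synth import (
    ParticipantProfile,
    energy_transfer,
    invert_energy_transfer,
    joint_amplitudes_deg,
    performance_table,
    simulate_limb_markers,
    simulate_participant_session,
    simulate_strike_kinematics,
)

DT = 0.004


class TestStrikeKinematics:
    def test_peak_forward_speed_equals_impact_speed(self):
        st = simulate_strike_kinematics(2.0, dt=DT)
        v = axial_speed(st.positions, DT)
        # interior central differences under-read the analytic peak only at
        # discretization order
        assert v.max() == pytest.approx(2.0, rel=5e-3)
        assert int(np.argmax(v)) in (st.contact_index - 1, st.contact_index)

    def test_arming_end_is_at_rest(self):
        st = simulate_strike_kinematics(1.5, dt=DT)
        v = axial_speed(st.positions, DT)
        assert abs(v[st.arming_end_index]) < 5e-3
        # maximal retraction: most negative position at the arming end
        assert st.positions[st.arming_end_index] == pytest.approx(
            st.positions.min(), abs=1e-9
        )

    def test_strike_speed_monotone_to_contact(self):
        st = simulate_strike_kinematics(2.2, dt=DT)
        v = axial_speed(st.positions, DT)
        seg = v[st.arming_end_index + 2 : st.contact_index - 1]
        assert np.all(np.diff(seg) > -1e-9)

    def test_contact_transient_concentrates_deceleration(self):
        st = simulate_strike_kinematics(2.0, dt=DT)
        v = axial_speed(st.positions, DT)
        a = axial_speed(v, DT)
        k = st.contact_index
        assert a[k : k + 4].min() < 0.4 * a.min() < 0
        assert a[: k - 1].min() > 0.4 * a.min()

    def test_detector_recovers_contact_on_noiseless_output(self):
        for speed in (0.97, 1.5, 2.5):
            st = simulate_strike_kinematics(speed, dt=DT)
            v = axial_speed(st.positions, DT)
            a = axial_speed(v, DT)
            imax = int(np.argmax(v))
            ic = detect_contact(a, imax, min(imax + 25, len(a) - 1))
            assert abs(ic - st.contact_index) <= 1

    def test_coarse_dt_rejected(self):
        with pytest.raises(ValueError):
            simulate_strike_kinematics(2.0, dt=0.01)

    def test_seeded_noise_reproducible(self):
        a = simulate_strike_kinematics(2.0, dt=DT, noise_sd=5e-4, seed=3)
        b = simulate_strike_kinematics(2.0, dt=DT, noise_sd=5e-4, seed=3)
        assert np.array_equal(a.positions, b.positions)


class TestEnergyTransfer:
    def test_affine_form(self):
        assert energy_transfer(2.62, (1.0, 0.94)) == pytest.approx(1.68)

    def test_at_offset_no_launch(self):
        assert energy_transfer(0.94, (1.0, 0.94)) == 0.0

    def test_identity_parameters(self):
        assert energy_transfer(1.7, (1.0, 0.0)) == pytest.approx(1.7)

    def test_clipped_at_zero(self):
        assert energy_transfer(0.2, (1.0, 0.94)) == 0.0

    def test_inverse(self):
        t = (1.15, 1.16)
        assert energy_transfer(invert_energy_transfer(1.68, t), t) == pytest.approx(1.68)


class TestLimbMarkers:
    def test_fingertip_speed_at_contact_within_one_percent(self):
        prof = ParticipantProfile()
        # fine sampling isolates the continuous construction from
        # finite-difference bias at the speed peak
        limb = simulate_limb_markers("forearm", 2.0, prof, dt=0.0005)
        v = axial_speed(limb.markers["fingertip"][:, 1], 0.0005)
        assert v.max() == pytest.approx(2.0, rel=0.01)

    def test_strategy_amplitude_ordering(self):
        for v in (1.2, 1.8, 2.4):
            a_w = joint_amplitudes_deg("wrist", v)
            a_f = joint_amplitudes_deg("forearm", v)
            assert a_w["wrist"] > a_f["wrist"]
            assert a_w["forearm"] < a_f["forearm"]

    def test_amplitudes_affine_in_impact_speed(self):
        a1 = joint_amplitudes_deg("wrist", 1.0)
        a2 = joint_amplitudes_deg("wrist", 2.0)
        a3 = joint_amplitudes_deg("wrist", 3.0)
        for j in ("forearm", "wrist", "index"):
            assert a3[j] - a2[j] == pytest.approx(a2[j] - a1[j], abs=1e-9)

    def test_elbow_fixed_throughout(self):
        limb = simulate_limb_markers("wrist", 2.0, ParticipantProfile())
        e = limb.markers["elbow"]
        assert np.ptp(e, axis=0).max() == 0.0

    def test_planted_amplitudes_recovered_by_geometry(self):
        from strikeslide.biomechanics import angular_amplitude, joint_angle_series

        limb = simulate_limb_markers("forearm", 1.7, ParticipantProfile())
        angles = joint_angle_series(limb.markers)
        amp = angular_amplitude(angles, limb.arming_end_index, limb.contact_index)
        for j in ("forearm", "wrist", "index"):
            assert amp[j] == pytest.approx(limb.amplitudes[j], abs=1e-4)


class TestSessionLearning:
    def test_one_step_convergence_with_full_learning(self):
        prof = ParticipantProfile(learning_rate=1.0, motor_noise_sd=0.0)
        s = simulate_participant_session(prof, make_design(1, 10), seed=0,
                                         include_kinematics=False)
        errs = [gt.spatial_error_pct for gt in s.ground_truth]
        assert errs[0] != 0.0
        assert all(abs(e) < 1e-9 for e in errs[1:10])

    def test_spatial_error_matches_hand_iterated_recursion(self):
        lam, mu0, mu_true = 0.4, 0.25, 0.47
        prof = ParticipantProfile(learning_rate=lam, subjective_mu0=mu0,
                                  motor_noise_sd=0.0)
        s = simulate_participant_session(
            prof, make_design(2, 10), seed=0, include_kinematics=False,
            true_mu={"aluminum": 0.37, "balsa": mu_true},
        )
        mu = mu0
        expected = []
        for _ in range(10):
            expected.append(100.0 * (mu / mu_true - 1.0))
            mu += lam * (mu_true - mu)
        got = [gt.spatial_error_pct for gt in s.ground_truth[:10]]
        assert got == pytest.approx(expected, abs=1e-9)

    def test_error_decays_geometrically(self):
        lam = 0.3
        prof = ParticipantProfile(learning_rate=lam, motor_noise_sd=0.0)
        s = simulate_participant_session(prof, make_design(1, 10), seed=0,
                                         include_kinematics=False)
        errs = np.array([gt.spatial_error_pct for gt in s.ground_truth[:10]])
        ratios = errs[1:] / errs[:-1]
        assert ratios == pytest.approx(np.full(9, 1 - lam), abs=1e-9)

    def test_first_trial_speed_material_independent(self):
        """Identical first-strike launch speed whatever the surface, hence a
        larger undershoot on the high-friction material."""
        prof = ParticipantProfile(motor_noise_sd=0.0)
        v1 = {}
        e1 = {}
        for group in (1, 2):  # group 1 starts aluminum, group 2 balsa
            s = simulate_participant_session(prof, make_design(group, 10), seed=0,
                                             include_kinematics=False)
            rec, gt = s.trials[0], s.ground_truth[0]
            v1[rec.material] = gt.launch_speed
            e1[rec.material] = gt.spatial_error_pct
        assert v1["aluminum"] == pytest.approx(v1["balsa"], rel=1e-12)
        assert e1["balsa"] < e1["aluminum"] < 0

    def test_no_learning_keeps_error_constant(self):
        prof = ParticipantProfile(learning_rate=1e-12, motor_noise_sd=0.0)
        with pytest.raises(ValueError):
            ParticipantProfile(learning_rate=0.0)
        s = simulate_participant_session(prof, make_design(1, 10), seed=0,
                                         include_kinematics=False)
        errs = [gt.spatial_error_pct for gt in s.ground_truth[:10]]
        assert max(errs) - min(errs) < 1e-6

    def test_session_reproducible_for_seed(self):
        prof = ParticipantProfile()
        a = simulate_participant_session(prof, make_design(3, 2), seed=9)
        b = simulate_participant_session(prof, make_design(3, 2), seed=9)
        for ra, rb in zip(a.trials, b.trials):
            assert np.array_equal(ra.markers["fingertip"], rb.markers["fingertip"])
            assert np.array_equal(ra.cube_y, rb.cube_y)

    def test_performance_table_shape(self):
        prof = ParticipantProfile()
        s = simulate_participant_session(prof, make_design(1, 2), seed=0,
                                         include_kinematics=False)
        df = performance_table(s)
        assert len(df) == 24
        assert set(df["block"]) == set(range(1, 13))


class TestSessionFileRoundTrip:
    def test_write_read_identical(self, tmp_path, noiseless_session):
        from strikeslide.session_io import read_session, write_session

        write_session(noiseless_session, tmp_path)
        back = read_session(tmp_path, noiseless_session.participant)
        assert len(back.trials) == len(noiseless_session.trials)
        for ra, rb in zip(noiseless_session.trials, back.trials):
            assert rb.material == ra.material
            assert rb.target_distance == ra.target_distance
            np.testing.assert_allclose(rb.cube_y, ra.cube_y, atol=1e-8)
            np.testing.assert_allclose(
                rb.markers["fingertip"], ra.markers["fingertip"], atol=1e-8
            )
        for ga, gb in zip(noiseless_session.ground_truth, back.ground_truth):
            assert gb.launch_speed == pytest.approx(ga.launch_speed, rel=1e-12)
            assert gb.contact_index == ga.contact_index
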