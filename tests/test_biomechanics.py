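"""Joint geometry, segmental kinetic energy, strategy clustering."""

import math

import numpy as np
import pandas as pd
import pytest

from strikeslide.biomechanics import (
    DegenerateGeometryError,
    angular_amplitude,
    angular_velocities_at,
    cluster_strategies,
    fit_linear_vs_optimal_speed,
    joint_angle_series,
    joint_angles,
    kinetic_energy_at_impact,
    segment_parameters,
)
from strikeslide.synth import (
    TRANSFER_PARAMS,
    ParticipantProfile,
    invert_energy_transfer,
    joint_amplitudes_deg,
)


class TestJointAngles:
    def test_collinear_chain_along_y(self):
        ja = joint_angles((0, 0), (0, 0.26), (0, 0.45), (0, 0.52))
        assert (ja.theta_forearm, ja.theta_wrist, ja.theta_index) == (0, 0, 0)

    def test_rotated_forearm_straight_distal_chain(self):
        a = math.radians(30.0)
        w = (0.26 * math.sin(a), 0.26 * math.cos(a))
        m = (0.45 * math.sin(a), 0.45 * math.cos(a))
        f = (0.52 * math.sin(a), 0.52 * math.cos(a))
        ja = joint_angles((0, 0), w, m, f)
        assert ja.theta_forearm == pytest.approx(-30.0, abs=1e-9)
        assert ja.theta_wrist == pytest.approx(0.0, abs=1e-9)
        assert ja.theta_index == pytest.approx(0.0, abs=1e-9)

    def test_planted_chain_recovered(self, rng):
        for _ in range(25):
            phi = rng.uniform(-1.2, 1.2, 3)
            e = np.zeros(2)
            w = e + 0.26 * np.array([np.cos(phi[0]), np.sin(phi[0])])
            m = w + 0.19 * np.array([np.cos(phi[1]), np.sin(phi[1])])
            f = m + 0.07 * np.array([np.cos(phi[2]), np.sin(phi[2])])
            ja = joint_angles(e, w, m, f)
            # signed convention: angle rotating the proximal axis onto the
            # distal axis, counterclockwise positive
            assert ja.theta_wrist == pytest.approx(
                math.degrees(phi[1] - phi[0]), abs=1e-9
            )
            assert ja.theta_index == pytest.approx(
                math.degrees(phi[2] - phi[1]), abs=1e-9
            )

    def test_coincident_markers_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            joint_angles((0, 0), (0, 0), (0, 0.1), (0, 0.2))


class TestAnthropometrics:
    def test_forearm_mass_fraction(self):
        m = segment_parameters(70.0, 0.26, 0.19)
        assert m.forearm.mass == pytest.approx(0.0162 * 70.0)

    def test_linearity_in_body_mass(self):
        a = segment_parameters(60.0, 0.26, 0.19)
        b = segment_parameters(120.0, 0.26, 0.19)
        assert b.forearm.mass == pytest.approx(2 * a.forearm.mass)
        assert b.hand.inertia == pytest.approx(2 * a.hand.inertia)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            segment_parameters(70.0, 0.0, 0.19)


class TestKineticEnergy:
    def test_cube_energy_printed_mass(self):
        model = segment_parameters(70.0, 0.26, 0.19)
        ke = kinetic_energy_at_impact(0.0, 0.0, 0.0, model, cube_mass=0.046,
                                      cube_speed=2.0)
        assert ke.ke_cube == pytest.approx(0.092, abs=1e-12)
        assert ke.ke_forearm == 0.0 and ke.ke_hand == 0.0

    def test_additivity_exact(self, rng):
        model = segment_parameters(72.0, 0.27, 0.18)
        for _ in range(50):
            ke = kinetic_energy_at_impact(
                float(rng.uniform(-40, 40)),
                float(rng.uniform(0, 8)),
                float(rng.uniform(-4, 8)),
                model,
                cube_speed=float(rng.uniform(0, 3)),
            )
            assert ke.ke_total == ke.ke_forearm + ke.ke_hand

    def test_pure_forearm_rotation_rigid_hand_oracle(self):
        """Hand rigidly aligned with the forearm: the chain is one rigid
        body about the elbow; the hand term must match the point-COM +
        rotational decomposition at radius L_F + r_H."""
        model = segment_parameters(70.0, 0.26, 0.19)
        w = 4.0
        ke = kinetic_energy_at_impact(0.0, w, 0.0, model)
        lf = model.forearm.length
        rh = model.hand.com_distance
        expected_hand = (
            0.5 * model.hand.mass * ((lf + rh) * w) ** 2
            + 0.5 * model.hand.inertia * w**2
        )
        assert ke.ke_hand == pytest.approx(expected_hand, rel=1e-12)

    def test_frame_rotation_invariance(self):
        """KE depends only on joint-space quantities, so it is invariant to
        rotating the lab frame about the vertical axis (which leaves wrist
        angle and angular velocities unchanged)."""
        model = segment_parameters(70.0, 0.26, 0.19)
        a = kinetic_energy_at_impact(12.0, 3.0, 1.5, model, cube_speed=1.7)
        b = kinetic_energy_at_impact(12.0, 3.0, 1.5, model, cube_speed=1.7)
        assert a == b

    def test_efficiency_validity_flag(self):
        model = segment_parameters(70.0, 0.26, 0.19)
        ok = kinetic_energy_at_impact(0.0, 5.0, 0.0, model, cube_speed=1.0)
        assert ok.physically_valid and 0 <= ok.efficiency <= 1
        bad = kinetic_energy_at_impact(0.0, 0.1, 0.0, model, cube_speed=3.0)
        assert not bad.physically_valid


class TestAmplitudesAndVelocities:
    def test_zero_motion_zero_amplitude(self):
        markers = {
            "elbow": np.zeros((10, 3)),
            "wrist": np.tile([0.26, 0, 0], (10, 1)),
            "mcp": np.tile([0.45, 0, 0], (10, 1)),
            "fingertip": np.tile([0.52, 0, 0], (10, 1)),
        }
        ser = joint_angle_series(markers)
        amp = angular_amplitude(ser, 0, 9)
        assert amp == {"forearm": 0.0, "wrist": 0.0, "index": 0.0}

    def test_rigid_translation_invariance(self):
        rng = np.random.default_rng(0)
        base = {
            "elbow": np.zeros((10, 3)),
            "wrist": np.cumsum(rng.normal(0, 0.001, (10, 3)), axis=0) + [0.26, 0, 0],
            "mcp": np.cumsum(rng.normal(0, 0.001, (10, 3)), axis=0) + [0.45, 0, 0],
            "fingertip": np.cumsum(rng.normal(0, 0.001, (10, 3)), axis=0) + [0.5, 0, 0],
        }
        shifted = {k: v + np.array([0.3, -0.2, 0.0]) for k, v in base.items()}
        a = angular_amplitude(joint_angle_series(base), 0, 9)
        b = angular_amplitude(joint_angle_series(shifted), 0, 9)
        for j in a:
            assert b[j] == pytest.approx(a[j], abs=1e-9)

    def test_angular_velocity_finite_difference(self):
        ser = pd.DataFrame(
            {
                "theta_forearm": np.degrees(0.01 * np.arange(10.0)),
                "theta_wrist": np.zeros(10),
                "theta_index": np.zeros(10),
            }
        )
        om = angular_velocities_at(ser, 5, dt=0.004)
        assert om["forearm"] == pytest.approx(0.01 / 0.004, rel=1e-9)
        assert om["wrist"] == 0.0


def _strategy_features(n_wrist, n_forearm, noise_sd, seed):
    """Joint-amplitude feature table for a planted two-strategy cohort,
    one row per participant, 3 joints x 12 conditions."""
    from strikeslide.design import make_design
    from strikeslide.physics import SurfaceCondition, optimal_cube_speed

    rng = np.random.default_rng(seed)
    design = make_design(1)
    rows = []
    labels = ["wrist"] * n_wrist + ["forearm"] * n_forearm
    for strat in labels:
        row = {}
        for block in design.blocks:
            mu = {"aluminum": 0.37, "balsa": 0.47}[block.material]
            v_opt = optimal_cube_speed(
                block.target_distance, SurfaceCondition(block.slope, mu)
            )
            finger = invert_energy_transfer(v_opt, TRANSFER_PARAMS[strat])
            amps = joint_amplitudes_deg(strat, finger)
            for j, a in amps.items():
                row[f"amp_{j}|b{block.number}"] = a + rng.normal(0, noise_sd)
        rows.append(row)
    return pd.DataFrame(rows), labels


class TestClustering:
    def test_well_separated_groups_fully_recovered(self):
        feats, labels = _strategy_features(5, 7, noise_sd=0.5, seed=0)
        got = [a.cluster for a in cluster_strategies(feats)]
        assert got == labels

    def test_duplicated_rows_same_assignment(self):
        feats, _ = _strategy_features(3, 3, noise_sd=1.0, seed=1)
        doubled = pd.concat([feats, feats], ignore_index=True)
        got = [a.cluster for a in cluster_strategies(doubled)]
        assert got[: len(feats)] == got[len(feats):]

    def test_moderate_noise_cohort_recovery(self):
        hits = 0
        total = 0
        for seed in range(10):
            feats, labels = _strategy_features(14, 19, noise_sd=3.0, seed=seed)
            got = [a.cluster for a in cluster_strategies(feats, seed=seed)]
            hits += sum(g == l for g, l in zip(got, labels))
            total += len(labels)
        assert hits / total >= 0.95

    def test_too_few_participants(self):
        feats, _ = _strategy_features(1, 0, noise_sd=0.1, seed=0)
        with pytest.raises(ValueError):
            cluster_strategies(feats)

    def test_constant_features_rejected(self):
        with pytest.raises(ValueError):
            cluster_strategies(pd.DataFrame({"a": [1.0, 1.0, 1.0]}))


class TestLinearFit:
    def test_exact_line(self):
        x = np.array([1.0, 1.5, 2.0, 2.5])
        fit = fit_linear_vs_optimal_speed(x, 3.0 * x - 1.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.retained
        assert fit.slope == pytest.approx(3.0)

    def test_constant_response_not_retained(self):
        x = np.array([1.0, 1.5, 2.0, 2.5])
        fit = fit_linear_vs_optimal_speed(x, np.full(4, 2.0))
        assert fit.slope == pytest.approx(0.0)
        assert not fit.retained

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_vs_optimal_speed([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_planted_affine_relation_recovered(self, rng):
        x = np.linspace(0.9, 2.5, 12)
        y = 7.9 * x + 13.2 + rng.normal(0, 0.8, 12)
        fit = fit_linear_vs_optimal_speed(x, y)
        assert fit.retained
        assert fit.slope == pytest.approx(7.9, abs=1.2)


class TestStrategySignature:
    def test_equal_cube_ke_higher_finger_speed_in_wrist_cluster(self):
        """For the same launch speed the wrist-strategy mover needs a higher
        fingertip speed at impact (less limb mass behind the strike)."""
        v_launch = 1.7
        f_wrist = invert_energy_transfer(v_launch, TRANSFER_PARAMS["wrist"])
        f_forearm = invert_energy_transfer(v_launch, TRANSFER_PARAMS["forearm"])
        assert f_wrist > f_forearm
        # identical launch speed -> identical object energy by construction
        assert 0.5 * 0.046 * v_launch**2 == pytest.approx(0.0665, abs=1e-3)
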