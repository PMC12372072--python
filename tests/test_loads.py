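import math

import numpy as np
import pytest

import presschain as pc
from presschain.kinematics import ChainState
from presschain.loads import _application_point

from _oracles import dae_acceleration, muscle_moment_bruteforce


def _state(bench_chain, theta1_deg=-30.0, w1=0.0, d=0.25):
    return ChainState.from_theta1(math.radians(theta1_deg), w1, bench_chain, d)


def _state_with_theta2_90(chain, d):
    """Configuration with link 2 vertical (theta2 = 90 deg)."""
    th1 = math.acos(d / chain.l1)  # then cos(theta2) = 0
    return ChainState.from_theta1(th1, 0.0, chain, d)


class TestMuscleTorques:
    def test_empty_force_set(self, bench_chain):
        state = _state(bench_chain)
        assert pc.muscle_torques([], state, bench_chain) == (0.0, 0.0)

    def test_perpendicular_lever_arm(self, bench_chain):
        """Force F normal to link 2 at distance r from J2 gives tau2 = r*F."""
        state = _state(bench_chain)
        r, F = 0.05, 200.0
        w2 = np.array([-math.sin(state.theta2), math.cos(state.theta2)])
        muscle = pc.MuscleForce("elbow-flexor", 1, 2, (r, 0.0), tuple(F * w2))
        t1, t2 = pc.muscle_torques([muscle], state, bench_chain)
        assert t2 == pytest.approx(r * F, rel=1e-12)
        assert t1 == 0.0  # single-joint elbow muscle spans only J2

    def test_two_joint_muscle_contributes_to_both(self, bench_chain):
        state = _state(bench_chain)
        muscle = pc.MuscleForce("triceps-long-head", 0, 2, (0.04, 0.01), (-150.0, 80.0))
        t1, t2 = pc.muscle_torques([muscle], state, bench_chain)
        P = _application_point(muscle, state, bench_chain)
        J2 = bench_chain.l1 * np.array([math.cos(state.theta1), math.sin(state.theta1)])
        assert t2 == pytest.approx(muscle_moment_bruteforce([P], [muscle.vector], J2), abs=1e-12)
        assert t1 == pytest.approx(muscle_moment_bruteforce([P], [muscle.vector], (0, 0)), abs=1e-12)

    def test_random_force_set_against_cross_product_oracle(self, bench_chain, rng):
        state = _state(bench_chain, -15.0)
        forces = []
        pairs = [(1, 2), (0, 2), (0, 1)]
        for i in range(8):
            origin, insertion = pairs[rng.integers(0, 3)]
            forces.append(
                pc.MuscleForce(
                    f"m{i}", int(origin), int(insertion),
                    tuple(rng.uniform(-0.05, 0.2, 2)), tuple(rng.normal(0, 300, 2)),
                )
            )
        t1, t2 = pc.muscle_torques(forces, state, bench_chain)
        J1 = np.zeros(2)
        J2 = bench_chain.l1 * np.array([math.cos(state.theta1), math.sin(state.theta1)])
        pts = [_application_point(f, state, bench_chain) for f in forces]
        t2_oracle = muscle_moment_bruteforce(
            [p for p, f in zip(pts, forces) if f.insertion_link == 2],
            [f.vector for f in forces if f.insertion_link == 2], J2,
        )
        t1_oracle = muscle_moment_bruteforce(
            [p for p, f in zip(pts, forces) if f.origin_link == 0],
            [f.vector for f in forces if f.origin_link == 0], J1,
        )
        assert t2 == pytest.approx(t2_oracle, abs=1e-12)
        assert t1 == pytest.approx(t1_oracle, abs=1e-12)


class TestTrackReaction:
    def test_static_vertical_link2_gives_zero(self, bench_chain):
        state = _state_with_theta2_90(bench_chain, 0.25)
        assert pc.track_reaction(state, 0.0, 0.0, bench_chain, 0.25) == pytest.approx(0.0, abs=1e-9)

    def test_static_closed_form(self, bench_chain):
        state = _state(bench_chain, -30.0)
        Rx = pc.track_reaction(state, 0.0, 0.0, bench_chain, 0.25)
        expected = (
            -bench_chain.m2 * bench_chain.g * bench_chain.lC2 * math.cos(state.theta2)
        ) / (bench_chain.l2 * math.sin(state.theta2))
        assert Rx == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("theta1_deg,w1,tau1_Mg,k", [
        (-40.0, 1.0, 0.35, 0.0), (0.0, 2.5, 0.30, 0.5), (30.0, -0.5, 0.5, 1.0),
    ])
    def test_equals_dae_lagrange_multiplier(self, theta1_deg, w1, tau1_Mg, k, bench_chain):
        d = 0.25
        tau1 = tau1_Mg * bench_chain.M * bench_chain.g
        tau2 = -k * tau1
        state = ChainState.from_theta1(math.radians(theta1_deg), w1, bench_chain, d)
        a1 = pc.angular_acceleration(state, tau1, tau2, bench_chain, d)
        Rx = pc.track_reaction(state, a1, tau2, bench_chain, d)
        _, _, lam = dae_acceleration(state.theta1, w1, tau1, tau2, bench_chain, d)
        assert Rx == pytest.approx(lam, rel=1e-8)


class TestJointReactions:
    def test_static_vertical_link2_elbow_supports_weight(self, bench_chain):
        state = _state_with_theta2_90(bench_chain, 0.25)
        load = pc.elbow_reaction(state, 0.0, 0.0, None, bench_chain, 0.25)
        assert load.force == pytest.approx(
            np.array([0.0, bench_chain.m2 * bench_chain.g]), abs=1e-9
        )

    def test_newton_balance_of_link2(self, bench_chain):
        """phi21 + gravity + track + muscles = m2*a_C2 at a dynamic state."""
        d = 0.25
        state = _state(bench_chain, -25.0, 2.0)
        muscle = pc.MuscleForce("elbow-flexor", 1, 2, (0.03, 0.0), (50.0, 120.0))
        _, tau2 = pc.muscle_torques([muscle], state, bench_chain)
        a1 = pc.angular_acceleration(state, 80.0, tau2, bench_chain, d)
        load = pc.elbow_reaction(state, a1, tau2, [muscle], bench_chain, d)
        _, a_C2 = pc.point_accelerations(state, a1, bench_chain)
        lhs = (
            load.force
            + np.array([0.0, -bench_chain.m2 * bench_chain.g])
            + np.array([load.Rx, 0.0])
            + np.asarray(muscle.vector)
        )
        assert np.max(np.abs(lhs - bench_chain.m2 * a_C2)) < 1e-9

    def test_static_system_balance_at_shoulder(self, bench_chain):
        """phi10 + Rx*x_hat + total weight = 0 for the whole chain at rest."""
        state = _state(bench_chain, -35.0)
        tau2 = -30.0
        # hold the configuration static: theta1_ddot = 0 by construction
        load = pc.shoulder_reaction(state, 0.0, tau2, None, bench_chain, 0.25)
        total = (
            load.force
            + np.array([load.Rx, 0.0])
            + np.array([0.0, -(bench_chain.m1 + bench_chain.m2) * bench_chain.g])
        )
        assert np.max(np.abs(total)) < 1e-9

    def test_dynamic_shoulder_reaction_vs_system_newton(self, bench_chain):
        d = 0.25
        state = _state(bench_chain, -10.0, 1.5)
        tau1, tau2 = 120.0, -40.0
        a1 = pc.angular_acceleration(state, tau1, tau2, bench_chain, d)
        load = pc.shoulder_reaction(state, a1, tau2, None, bench_chain, d)
        from presschain.kinematics import com_acceleration_link1

        a_C1 = com_acceleration_link1(state, a1, bench_chain)
        _, a_C2 = pc.point_accelerations(state, a1, bench_chain)
        expected = (
            bench_chain.m1 * a_C1
            + bench_chain.m2 * a_C2
            - np.array([0.0, -(bench_chain.m1 + bench_chain.m2) * bench_chain.g])
            - np.array([load.Rx, 0.0])
        )
        assert np.max(np.abs(load.force - expected)) < 1e-9

    def test_link1_moment_balance_reassembles_dynamics(self, bench_chain):
        """I1*th1dd = tau1 - tau2 - m1 g lC1 c1 + (l1 u1 x phi12)_z closes the loop."""
        d = 0.25
        state = _state(bench_chain, -20.0, 1.0)
        tau1, tau2 = 150.0, -50.0
        a1 = pc.angular_acceleration(state, tau1, tau2, bench_chain, d)
        phi21 = pc.elbow_reaction(state, a1, tau2, None, bench_chain, d)
        phi12 = -phi21.force
        J2 = bench_chain.l1 * np.array([math.cos(state.theta1), math.sin(state.theta1)])
        moment_phi12 = J2[0] * phi12[1] - J2[1] * phi12[0]
        lhs = bench_chain.I1 * a1
        rhs = (
            (tau1 - tau2)
            - bench_chain.m1 * bench_chain.g * bench_chain.lC1 * math.cos(state.theta1)
            + moment_phi12
        )
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_track_reaction_does_no_work(self, bench_max_trajectory, bench_chain):
        """The endpoint moves vertically, Rx horizontally: integrated power ~ 0."""
        traj = bench_max_trajectory
        d = traj.scenario.d
        th2 = pc.solve_theta2(traj.theta1, bench_chain, d)
        xP = bench_chain.l1 * np.cos(traj.theta1) + bench_chain.l2 * np.cos(th2)
        vx = np.gradient(xP, traj.t)
        assert np.max(np.abs(vx)) < 1e-6  # endpoint x is pinned to the track

    def test_torque_consistency_helper(self, bench_chain):
        state = _state(bench_chain)
        muscle = pc.MuscleForce("elbow-flexor", 1, 2, (0.05, 0.0), (0.0, 100.0))
        t1, t2 = pc.muscle_torques([muscle], state, bench_chain)
        assert pc.check_torque_consistency([muscle], state, bench_chain, t1, t2)
        assert not pc.check_torque_consistency([muscle], state, bench_chain, t1 + 1.0, t2)
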