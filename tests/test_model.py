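"""Planar model: seated pose construction, forward dynamics, contact, feedback."""

import math

import numpy as np
import pytest

import stsreflex as sr
from stsreflex.model import NDOF, step_dynamics


class TestBuildModel:
    def test_seated_pose_reported_angles(self, model, seated_state):
        angles = model.reported_angles_deg(seated_state)
        assert angles["hip"] == pytest.approx(12.0, abs=1e-9)
        assert angles["knee"] == pytest.approx(85.0, abs=1e-9)
        assert angles["ankle"] == pytest.approx(61.0, abs=1e-9)
        assert seated_state.time == 0.0
        assert np.all(seated_state.qd == 0.0)

    def test_pelvis_sphere_clearance_above_seat(self, model, seated_state):
        x, y = model.point_position(seated_state.q, "pelvis_sphere")
        clearance = (y - model.config.contact_sphere_radius) - model.seat_y
        assert clearance == pytest.approx(0.035, abs=1e-9)

    def test_pose_independent_of_segment_masses(self, seated_state):
        heavy = sr.ModelConfig(total_mass=160.0)
        _, s2 = sr.build_model(heavy)
        np.testing.assert_allclose(s2.q, seated_state.q, atol=1e-12)

    def test_inconsistent_geometry_rejected(self):
        with pytest.raises((sr.ConfigurationError, ValueError)):
            sr.build_model(sr.ModelConfig(pelvis_seat_clearance=-0.30))

    def test_feet_spheres_start_near_4cm_clearance(self, model, seated_state):
        # the placed pose hovers: heel spheres ~4 cm above the ground, and
        # the whole pose drops together into the static sitting equilibrium
        for name in ("calcaneus_l", "calcaneus_r"):
            x, y = model.point_position(seated_state.q, name)
            assert y - model.config.contact_sphere_radius == pytest.approx(
                0.04, abs=5e-3
            )

    def test_settled_state_is_static_sitting(self, model):
        s = model.settled_state()
        assert np.all(s.qd == 0.0)
        np.testing.assert_allclose(
            s.q[2:], model.initial_state().q[2:], atol=1e-12
        )
        _, forces = model.dynamics(s)
        assert forces[4, 0] > 100.0            # seat is loaded
        assert forces[[1, 3], 0].sum() > 50.0  # heels are loaded


class TestStepDynamics:
    def test_zero_gravity_equilibrium(self, model, seated_state):
        s = seated_state.copy()
        for _ in range(200):
            s = step_dynamics(m := model, s, dt=1e-3, contacts=False, gravity=0.0)
        np.testing.assert_allclose(s.q, seated_state.q, atol=1e-10)

    def test_free_fall_matches_closed_form(self, model, seated_state):
        s = seated_state.copy()
        y0 = s.q[1]
        t = 0.5
        for _ in range(int(t / 1e-3)):
            s = step_dynamics(model, s, dt=1e-3, contacts=False)
        assert (y0 - s.q[1]) == pytest.approx(0.5 * 9.81 * t**2, abs=1e-3)

    def test_invalid_dt_rejected(self, model, seated_state):
        with pytest.raises(ValueError):
            step_dynamics(model, seated_state, dt=0.0)
        with pytest.raises(ValueError):
            step_dynamics(model, seated_state, dt=1.0)

    def test_pendulum_frequency_matches_linearized_closed_form(self, model):
        # one straight leg swinging about the hip (all other DOFs held)
        c = model.config
        free = np.zeros(NDOF, dtype=bool)
        free[3] = True
        s = sr.BodyState(0.0, np.zeros(NDOF), np.zeros(NDOF))
        s.q[3] = 0.05
        lt, ls = c.thigh_length, c.shank_length
        fx, fy = c.foot_com_offset
        I_hip = (
            c.thigh_inertia + c.thigh_mass * (0.433 * lt) ** 2
            + c.shank_inertia + c.shank_mass * (lt + 0.433 * ls) ** 2
            + c.foot_inertia + c.foot_mass * ((lt + ls - fy) ** 2 + fx**2)
        )
        mgd = c.gravity * (
            c.thigh_mass * 0.433 * lt
            + c.shank_mass * (lt + 0.433 * ls)
            + c.foot_mass * (lt + ls - fy)
        )
        w_ref = math.sqrt(mgd / I_hip)
        T = 2 * math.pi / w_ref
        angles = []
        for _ in range(int(5 * T / 1e-3)):
            s = step_dynamics(model, s, dt=1e-3, contacts=False, free_dofs=free)
            angles.append(s.q[3])
        a = np.asarray(angles) - np.mean(angles)  # oscillation about equilibrium
        zc = np.flatnonzero(np.diff(np.sign(a)) != 0)
        w_sim = math.pi / (np.mean(np.diff(zc)) * 1e-3)
        assert w_sim == pytest.approx(w_ref, rel=0.02)

    def test_energy_conservation_without_contacts(self, model, seated_state):
        s = seated_state.copy()
        s.qd[:] = np.random.default_rng(0).normal(0.0, 0.5, NDOF)
        E0 = model.mechanical_energy(s)
        sim_t = 2.0
        for _ in range(int(sim_t / 1e-3)):
            s = step_dynamics(model, s, dt=1e-3, contacts=False)
        drift = abs(model.mechanical_energy(s) - E0) / abs(E0)
        assert drift < 1e-3 * sim_t  # < 0.1% per simulated second


class TestContact:
    def test_non_penetrating_sphere_is_force_free(self):
        pt = sr.ContactPoint(center=(0.0, 0.1), radius=0.04)
        assert sr.contact_force(pt) == (0.0, 0.0)
        assert pt.penetration < 0

    def test_friction_cone_bound(self, rng):
        mu = 0.9
        for _ in range(200):
            pt = sr.ContactPoint(center=(0.0, rng.uniform(0.0, 0.05)), radius=0.04)
            v = (rng.normal(0, 2.0), rng.normal(0, 2.0))
            fn, ft = sr.contact_force(pt, velocity=v, mu=mu)
            assert fn >= 0.0
            assert abs(ft) <= mu * fn + 1e-12

    def test_static_weight_support(self, model):
        # the settled sitting equilibrium carries the whole body weight
        free = np.zeros(NDOF, dtype=bool)
        free[:2] = True
        s = model.settled_state()
        for _ in range(500):  # a few more steps from the cached equilibrium
            s = step_dynamics(model, s, dt=1e-3, free_dofs=free)
        _, forces = model.dynamics(s)
        total = forces[:, 0].sum()
        weight = model.config.total_mass * model.config.gravity
        assert total == pytest.approx(weight, rel=0.01)
        mu = model.config.friction_coefficient
        assert np.all(np.abs(forces[:, 1]) <= mu * forces[:, 0] + 1e-9)


class TestFeedback:
    def test_static_pose_velocities_and_accelerations_zero(self, model, seated_state):
        fb = sr.derive_feedback(model, seated_state)
        for name in ("omega_torso", "alpha_torso", "v_torso_x", "v_torso_y",
                     "a_torso_x", "a_torso_y", "v_pelvis_x", "v_talus_y"):
            assert fb[name] == 0.0

    def test_torso_past_feet_flag(self, model, seated_state):
        fb = sr.derive_feedback(model, seated_state)
        assert fb.p_torso_x < fb.p_feet_x  # seated: torso CoM behind the heels
        s = seated_state.copy()
        s.q[2] += 1.0  # pitch far forward
        fb2 = sr.derive_feedback(model, s)
        assert fb2.p_torso_x >= fb2.p_feet_x

    def test_feedback_consistent_with_finite_differences(self, model, seated_state):
        # root follows a quadratic trajectory: FD of position matches v and a
        q0 = seated_state.q.copy()
        v = np.zeros(NDOF)
        a = np.zeros(NDOF)
        v[[0, 1, 2]] = (0.3, -0.2, 0.5)
        a[[0, 1, 2]] = (0.1, 0.4, -0.3)
        h = 1e-4

        def fb_at(t):
            s = sr.BodyState(t, q0 + v * t + 0.5 * a * t**2, v + a * t, a.copy())
            return sr.derive_feedback(model, s)

        t0 = 0.05
        fm, f0, fp = fb_at(t0 - h), fb_at(t0), fb_at(t0 + h)
        for pos, vel, acc in (
            ("p_torso_x", "v_torso_x", "a_torso_x"),
            ("p_torso_y", "v_torso_y", "a_torso_y"),
        ):
            fd_v = (fp[pos] - fm[pos]) / (2 * h)
            fd_a = (fp[pos] - 2 * f0[pos] + fm[pos]) / h**2
            assert fd_v == pytest.approx(f0[vel], abs=1e-6)
            assert fd_a == pytest.approx(f0[acc], abs=1e-6)

    def test_symmetric_rollout_stays_symmetric(self, sts2):
        p = sts2.zero_params()
        p.A0[:, :] = 0.1
        res = sts2.simulate(p, horizon=1.0)
        f = res.frame
        for l, r in (("q_hip_l", "q_hip_r"), ("q_knee_l", "q_knee_r"),
                     ("q_ankle_l", "q_ankle_r")):
            np.testing.assert_allclose(f[l], f[r], atol=1e-9)
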