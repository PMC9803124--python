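"""Reflex law, feedback routing, phase machine, parameter codec."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stsreflex as sr
from stsreflex import _kernels as K
from stsreflex.config import DEG
from stsreflex.control import ParamLayout, n_phases
from stsreflex.muscles import channel_names


def _params(ctrl="2phase"):
    names = channel_names(sr.default_channels())
    return sr.ControllerParams.zeros(ctrl, names, names.index("RF"))


def _fb(**kwargs):
    arr = np.zeros(K.N_FB)
    fb = sr.BodyFeedback(arr)
    for name, value in kwargs.items():
        arr[sr.BodyFeedback._NAMES[name]] = value
    return fb


def _states(params, L=1.0):
    return [sr.MuscleState(fiber_length=L) for _ in range(params.n_channels)]


class TestRouting:
    def test_flexion_momentum_uses_vestibular_angular_signals(self):
        for ctrl in ("4phase", "2phase"):
            assert sr.route_feedback(1, ctrl) == (
                "theta_torso", "omega_torso", "alpha_torso"
            )

    def test_stabilization_routes_torso_and_pelvis_x(self):
        assert sr.route_feedback(4, "4phase") == (
            "p_torso_x", "p_pelvis_x", "v_torso_x", "v_pelvis_x",
            "a_torso_x", "a_pelvis_x",
        )

    def test_merged_phase_matches_momentum_transfer_routing(self):
        assert sr.route_feedback(2, "2phase") == sr.route_feedback(2, "4phase")

    def test_unknown_phase_rejected(self):
        with pytest.raises(ValueError):
            sr.route_feedback(3, "2phase")
        with pytest.raises(ValueError):
            sr.route_feedback(5, "4phase")


class TestStimulationLaw:
    def test_collapses_to_tonic_with_zero_gains(self):
        p = _params()
        p.A0[:, :] = 0.3
        out = sr.compute_stimulation(_fb(), _states(p), p, 1)
        np.testing.assert_allclose(out, 0.3, atol=1e-15)

    def test_length_term_vanishes_at_offset(self):
        p = _params()
        p.A0[:, :] = 0.25
        p.klen[:] = 1.7
        p.L0[:] = 1.1
        out = sr.compute_stimulation(_fb(), _states(p, L=1.1), p, 2)
        np.testing.assert_allclose(out, 0.25, atol=1e-15)

    def test_direct_arithmetic_example(self):
        # A0 + k_p * p + k_l (L - L0) = 0.05 + 0.2*0.3 + 0.5*0.1 = 0.16
        p = _params()
        m = 0
        p.A0[1, m] = 0.05
        p.G[1, m, 0] = 0.2
        p.klen[m] = 0.5
        p.L0[m] = 1.0
        out = sr.compute_stimulation(
            _fb(p_torso_x=0.3), _states(p, L=1.1), p, 2
        )
        assert out[m] == pytest.approx(0.16, abs=1e-12)

    def test_position_reference_subtracted(self):
        p = _params()
        p.G[1, 0, 0] = 1.0
        p.pref[1, 0] = 0.2
        out = sr.compute_stimulation(_fb(p_torso_x=0.5), _states(p), p, 2)
        assert out[0] == pytest.approx(0.3, abs=1e-12)

    def test_clamped_to_unit_interval(self):
        p = _params()
        p.A0[0, :] = 0.9
        p.G[0, p.rf_index, 0] = 1.0
        out = sr.compute_stimulation(_fb(theta_torso=0.5), _states(p), p, 1)
        assert out[p.rf_index] == 1.0
        p.A0[0, :] = -5.0
        out = sr.compute_stimulation(_fb(), _states(p), p, 1)
        np.testing.assert_allclose(out, 0.01)

    def test_phase1_vestibular_terms_only_for_rf(self):
        p = _params()
        p.A0[:, :] = 0.2
        p.G[0, :, :3] = 3.0  # gains on every channel; only RF may use them
        fb = _fb(theta_torso=0.4, omega_torso=0.1, alpha_torso=0.05)
        out = sr.compute_stimulation(fb, _states(p), p, 1)
        for m in range(p.n_channels):
            if m == p.rf_index:
                assert out[m] == 1.0  # clamped, vestibular terms active
            else:
                assert out[m] == pytest.approx(0.2, abs=1e-15)

    def test_routing_exclusivity_by_gain_perturbation(self, rng):
        # signals not routed in phase 1 (translation slots) contribute nothing
        p = _params()
        p.A0[:, :] = 0.3
        fb = _fb(theta_torso=0.2, p_torso_x=0.7, v_torso_y=-0.4)
        base = sr.compute_stimulation(fb, _states(p), p, 1)
        p.G[0, :, 3:] = rng.normal(0, 10, size=(p.n_channels, 3))
        pert = sr.compute_stimulation(fb, _states(p), p, 1)
        np.testing.assert_array_equal(base, pert)

    def test_merged_phase_equals_4phase_phase2(self, rng):
        names = channel_names(sr.default_channels())
        p2 = _params("2phase")
        p4 = _params("4phase")
        G = rng.normal(0, 1, size=(p2.n_channels, 6))
        A0 = rng.uniform(0, 0.5, p2.n_channels)
        for p in (p2, p4):
            p.G[1] = G
            p.A0[1] = A0
            p.pref[1] = (0.1, 1.2)
            p.klen[:] = 0.4
            p.L0[:] = 0.9
        fb = _fb(p_torso_x=0.3, p_torso_y=1.0, v_torso_x=-0.2, v_torso_y=0.4,
                 a_torso_x=1.0, a_torso_y=-0.5)
        s = _states(p2, L=1.05)
        np.testing.assert_array_equal(
            sr.compute_stimulation(fb, s, p2, 2),
            sr.compute_stimulation(fb, s, p4, 2),
        )

    def test_non_finite_feedback_rejected(self):
        p = _params()
        arr = np.zeros(K.N_FB)
        arr[0] = np.nan
        with pytest.raises(ValueError):
            sr.compute_stimulation(sr.BodyFeedback(arr), _states(p), p, 1)


class TestPhaseMachine:
    def _advance(self, phase, ctrl, **fb):
        st0 = sr.PhaseState(phase)
        return sr.advance_phase(_fb(**fb), st0, ctrl, time=1.0).phase

    def test_liftoff_threshold_strict(self):
        for ctrl in ("4phase", "2phase"):
            assert self._advance(1, ctrl, theta_torso=78 * DEG) == 2
            assert self._advance(1, ctrl, theta_torso=77 * DEG) == 1

    def test_extension_entry_conjunction(self):
        base = dict(p_torso_x=0.1, p_feet_x=0.0, v_torso_x=-0.1,
                    theta_shank_x=80 * DEG)
        assert self._advance(2, "4phase", **base) == 3
        for breaker in (
            dict(p_torso_x=-0.1),
            dict(v_torso_x=0.1),
            dict(theta_shank_x=95 * DEG),
        ):
            assert self._advance(2, "4phase", **{**base, **breaker}) == 2

    def test_stabilization_entry(self):
        assert self._advance(3, "4phase", theta_knee=4 * DEG,
                             theta_torso=-1 * DEG) == 4
        assert self._advance(3, "4phase", theta_knee=6 * DEG,
                             theta_torso=-1 * DEG) == 3
        assert self._advance(3, "4phase", theta_knee=4 * DEG,
                             theta_torso=1 * DEG) == 3

    def test_two_phase_machine_stops_at_merged_phase(self):
        assert self._advance(2, "2phase", theta_torso=80 * DEG, p_torso_x=1.0,
                             v_torso_x=-1.0) == 2

    def test_exhaustive_boundary_truth_table(self):
        eps = 1e-6
        for hip in (77 * DEG - eps, 77 * DEG, 77 * DEG + eps):
            expect = 2 if hip > 77 * DEG else 1
            assert self._advance(1, "4phase", theta_torso=hip) == expect
        for knee in (5 * DEG - eps, 5 * DEG, 5 * DEG + eps):
            for hip in (-eps, 0.0, eps):
                expect = 4 if (knee <= 5 * DEG and hip <= 0.0) else 3
                assert self._advance(3, "4phase", theta_knee=knee,
                                     theta_torso=hip) == expect
        for dpx in (-eps, 0.0, eps):
            for vx in (-eps, 0.0, eps):
                for shank in (90 * DEG - eps, 90 * DEG, 90 * DEG + eps):
                    expect = 3 if (dpx >= 0 and vx <= 0 and shank < 90 * DEG) else 2
                    assert self._advance(
                        2, "4phase", p_torso_x=dpx, p_feet_x=0.0,
                        v_torso_x=vx, theta_shank_x=shank,
                    ) == expect

    def test_never_returns_and_never_skips(self, rng):
        for _ in range(200):
            st0 = sr.PhaseState(1)
            prev = 1
            for t in range(50):
                arr = rng.normal(0, 1, K.N_FB)
                st0 = sr.advance_phase(sr.BodyFeedback(arr), st0, "4phase", t * 0.01)
                assert st0.phase >= prev
                assert st0.phase - prev <= 1
                prev = st0.phase

    def test_backwards_transition_rejected(self):
        st0 = sr.PhaseState(3)
        with pytest.raises(ValueError):
            st0.advance_to(2, 1.0)


class TestParamCodec:
    @pytest.mark.parametrize("ctrl,expected", [("4phase", 226), ("2phase", 96)])
    def test_count_formula_matches_enumeration(self, ctrl, expected):
        names = channel_names(sr.default_channels())
        layout = ParamLayout(ctrl, names, names.index("RF"))
        assert layout.n_params == len(layout.entries) == expected
        assert ParamLayout.expected_size(ctrl, len(names)) == expected

    def test_count_formula_scales_with_channels(self):
        for C in (3, 5, 12):
            names = [f"M{i}" for i in range(C - 1)] + ["RF"]
            layout = ParamLayout("4phase", names, C - 1)
            assert layout.n_params == 24 * C + 10
            layout2 = ParamLayout("2phase", names, C - 1)
            assert layout2.n_params == 10 * C + 6

    @pytest.mark.parametrize("ctrl", ["4phase", "2phase"])
    def test_pack_unpack_bijection(self, ctrl, rng):
        names = channel_names(sr.default_channels())
        layout = ParamLayout(ctrl, names, names.index("RF"))
        vec = rng.normal(0, 2, layout.n_params)
        params = sr.unpack_params(vec, layout)
        back = sr.pack_params(params)
        np.testing.assert_array_equal(back, vec)

    def test_truncated_vector_rejected(self):
        names = channel_names(sr.default_channels())
        layout = ParamLayout("2phase", names, names.index("RF"))
        with pytest.raises(ValueError):
            sr.unpack_params(np.zeros(layout.n_params - 1), layout)

    def test_json_round_trip(self, tmp_path, rng):
        names = channel_names(sr.default_channels())
        layout = ParamLayout("2phase", names, names.index("RF"))
        params = sr.unpack_params(rng.normal(0, 1, layout.n_params), layout)
        path = tmp_path / "p.json"
        sr.params_to_json(params, path)
        back = sr.params_from_json(path)
        np.testing.assert_array_equal(sr.pack_params(back), sr.pack_params(params))

    def test_gain_table_is_long_format(self):
        p = _params()
        df = p.to_gain_table()
        assert set(df.columns) == {"phase", "channel", "signal", "value"}
        assert (df["signal"] == "tonic").sum() == 2 * p.n_channels


@settings(max_examples=100, deadline=None)
@given(data=st.data())
def test_stimulation_matches_independent_oracle(data):
    """Reflex law vs a direct numpy transcription on random draws."""
    names = channel_names(sr.default_channels())
    layout = ParamLayout("4phase", names, names.index("RF"))
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    vec = rng.normal(0, 1, layout.n_params)
    params = sr.unpack_params(vec, layout)
    phase = data.draw(st.integers(1, 4))
    fb_arr = rng.normal(0, 1, K.N_FB)
    Lm = rng.uniform(0.5, 1.5, len(names))
    states = [sr.MuscleState(fiber_length=L) for L in Lm]
    got = sr.compute_stimulation(sr.BodyFeedback(fb_arr), states, params, phase)

    # independent oracle
    sig_idx = {
        1: [K.FB_THETA, K.FB_OMEGA, K.FB_ALPHA],
        2: [K.FB_PX, K.FB_PY, K.FB_VX, K.FB_VY, K.FB_AX, K.FB_AY],
        3: [K.FB_PX, K.FB_PY, K.FB_VX, K.FB_VY, K.FB_AX, K.FB_AY],
        4: [K.FB_PX, K.FB_PPX, K.FB_VX, K.FB_PVX, K.FB_AX, K.FB_PAX],
    }[phase]
    x = fb_arr[sig_idx].astype(float).copy()
    npos = 1 if phase == 1 else 2
    for k in range(npos):
        x[k] -= params.pref[phase - 1, k]
    for m in range(len(names)):
        a = params.A0[phase - 1, m] + params.klen[m] * (Lm[m] - params.L0[m])
        if phase != 1 or m == params.rf_index:
            a += float(params.G[phase - 1, m, : len(x)] @ x)
        expected = min(1.0, max(0.01, a))
        assert got[m] == pytest.approx(expected, abs=1e-12)
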