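"""Measurement chain: phase detection, success rules, normalization,
cross-correlation, aggregation -- checked against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

import stsreflex as sr
from stsreflex.analysis import (
    EXT_ACC_THRESH, N_CYCLE, PhaseBoundaries, Trajectory, _crossing_below,
)


@pytest.fixture()
def trace():
    return sr.generate_sts_trace(sr.FixtureSpec(seed=3))


class TestDetectPhases:
    def test_liftoff_at_planted_time(self, trace):
        spec = sr.FixtureSpec(liftoff_pct=35.0, cycle_duration=2.0, seed=0)
        traj = sr.generate_sts_trace(spec)
        b = sr.detect_phases(traj)
        assert b.times["liftoff"] == pytest.approx(0.35 * 2.0, abs=traj.dt)

    def test_momentum_transfer_at_shank_minimum(self, trace):
        b = sr.detect_phases(trace)
        shank = trace.channel("shank_x_deg")
        assert b.momentum_transfer == b.liftoff + int(
            np.argmin(shank[b.liftoff :])
        )

    def test_extension_end_matches_bruteforce_crossing_scan(self):
        # decreasing ramp of |hip extension acceleration| crossing the
        # threshold at a known sample
        mag = np.linspace(1.0, 0.0, 500)
        got = _crossing_below(mag, EXT_ACC_THRESH, 0)
        brute = next(
            i for i in range(1, len(mag))
            if mag[i] < EXT_ACC_THRESH and np.any(mag[:i] >= EXT_ACC_THRESH)
        )
        assert got == brute

    def test_crossing_detector_requires_arming(self):
        mag = np.full(100, 1e-5)  # never reaches the threshold
        assert _crossing_below(mag, EXT_ACC_THRESH, 0) is None

    def test_boundaries_strictly_ordered(self, trace):
        b = sr.detect_phases(trace)
        assert b.all_present()
        assert b.is_ordered()

    def test_experimental_mode_uses_dorsiflexion_maximum(self):
        traj = sr.generate_sts_trace(sr.FixtureSpec(seed=1))
        b = sr.detect_phases(traj, mode="experimental")
        ankle = traj.channel("ankle_deg")
        assert b.momentum_transfer == b.liftoff + int(np.argmax(ankle[b.liftoff :]))
        assert b.stabilization is None

    def test_invalid_mode_rejected(self, trace):
        with pytest.raises(ValueError):
            sr.detect_phases(trace, mode="banana")

    def test_roundtrip_on_randomized_fixtures(self):
        # planted lift-off / momentum-transfer recovered within one cycle bin
        rng = np.random.default_rng(7)
        for k in range(40):
            lo = rng.uniform(20, 45)
            mt = lo + rng.uniform(8, 30)
            dur = rng.uniform(1.5, 3.0)
            spec = sr.FixtureSpec(
                liftoff_pct=lo, momentum_transfer_pct=mt,
                cycle_duration=dur, seed=int(k),
                noise={"ground_force_N": 5.0},
            )
            traj = sr.generate_sts_trace(spec)
            b = sr.detect_phases(traj)
            cyc = sr.normalize_cycle(traj, b)
            bin_pct = 100.0 / (N_CYCLE - 1)
            assert cyc.boundaries_pct["liftoff"] == pytest.approx(lo, abs=1.5 * bin_pct)
            assert cyc.boundaries_pct["momentum_transfer"] == pytest.approx(
                mt, abs=1.5 * bin_pct
            )


class TestDegenerateTraces:
    def test_expected_detector_outcomes(self):
        traces = sr.generate_degenerate_traces()
        traj, exp = traces["seat_never_zero"]
        assert sr.detect_phases(traj).liftoff is None
        traj, exp = traces["constant_hip"]
        assert sr.detect_phases(traj).extension is None
        traj, exp = traces["short_standing"]
        ok, reasons = sr.check_success(sr.detect_phases(traj))
        assert not ok
        assert reasons == ["standing < 3 s"]


class TestCheckSuccess:
    def _boundaries(self, lift, mt, ext, stab, end):
        b = PhaseBoundaries(
            liftoff=0, momentum_transfer=1, extension=2, stabilization=3, end=4
        )
        b.times = {
            "liftoff": lift, "momentum_transfer": mt, "extension": ext,
            "stabilization": stab, "end": end,
        }
        return b

    def test_long_extension_fails(self):
        b = self._boundaries(0.5, 1.0, 2.2, 2.5, 10.0)
        ok, reasons = sr.check_success(b)
        assert not ok and reasons == ["extension > 1 s"]

    def test_short_standing_fails(self):
        b = self._boundaries(0.5, 1.0, 1.8, 2.5, 5.4)
        ok, reasons = sr.check_success(b)
        assert not ok and reasons == ["standing < 3 s"]

    def test_all_conditions_met(self):
        b = self._boundaries(0.5, 1.0, 1.8, 2.5, 10.0)
        ok, reasons = sr.check_success(b)
        assert ok and reasons == []

    def test_missing_boundary_reported(self):
        b = self._boundaries(0.5, 1.0, None, None, 10.0)
        ok, reasons = sr.check_success(b)
        assert not ok
        assert "missing extension" in reasons


class TestNormalizeCycle:
    def test_idempotent_on_normalized_input(self):
        t = np.linspace(0.0, 1.0, N_CYCLE)
        df = pd.DataFrame({"time": t, "hip_deg": np.sin(t * 3)})
        traj = Trajectory(df)
        b = PhaseBoundaries(liftoff=30, momentum_transfer=50,
                            extension=N_CYCLE - 1, end=N_CYCLE - 1)
        b.times = {"liftoff": t[30], "momentum_transfer": t[50],
                   "extension": t[-1], "stabilization": None, "end": t[-1]}
        cyc = sr.normalize_cycle(traj, b)
        np.testing.assert_allclose(cyc.channel("hip_deg"), df["hip_deg"], atol=1e-9)

    def test_linear_ramp_preserved_exactly(self):
        t = np.arange(0.0, 3.0, 0.01)
        df = pd.DataFrame({"time": t, "hip_deg": 5.0 * t})
        traj = Trajectory(df)
        b = PhaseBoundaries(liftoff=50, momentum_transfer=100,
                            extension=200, end=len(t) - 1)
        b.times = {"liftoff": t[50], "momentum_transfer": t[100],
                   "extension": t[200], "stabilization": None, "end": t[-1]}
        cyc = sr.normalize_cycle(traj, b)
        assert len(cyc.channels) == N_CYCLE
        assert cyc.channel("hip_deg")[0] == pytest.approx(0.0, abs=1e-12)
        assert cyc.channel("hip_deg")[-1] == pytest.approx(5.0 * t[200], abs=1e-9)
        d = np.diff(cyc.channel("hip_deg"))
        np.testing.assert_allclose(d, d[0], atol=1e-9)

    def test_boundary_percentages(self):
        t = np.arange(0.0, 10.0, 0.01)
        df = pd.DataFrame({"time": t, "hip_deg": np.cos(t)})
        traj = Trajectory(df)
        n_ext = 600
        b = PhaseBoundaries(liftoff=180, momentum_transfer=336,
                            extension=n_ext, end=len(t) - 1)
        b.times = {"liftoff": t[180], "momentum_transfer": t[336],
                   "extension": t[n_ext], "stabilization": None, "end": t[-1]}
        cyc = sr.normalize_cycle(traj, b)
        assert cyc.boundaries_pct["liftoff"] == pytest.approx(30.0, abs=0.5)
        assert cyc.boundaries_pct["momentum_transfer"] == pytest.approx(56.0, abs=0.5)

    def test_missing_extension_rejected(self, trace):
        b = PhaseBoundaries()
        with pytest.raises(ValueError):
            sr.normalize_cycle(trace, b)


class TestCrossCorrelate:
    def test_identity(self):
        x = np.sin(np.linspace(0, 3, N_CYCLE))
        r, lag, match = sr.cross_correlate(x, x)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert lag == 0
        assert match is True

    def test_known_shift_recovered(self):
        base = np.sin(np.linspace(0, 4 * np.pi, N_CYCLE + 12))
        ref = base[:N_CYCLE]
        sim = base[12 : N_CYCLE + 12]  # sim[t] = ref[t + 12] -> sim leads
        r, lag, _ = sr.cross_correlate(sim, ref)
        assert abs(lag) == 12
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_matches_exhaustive_lag_scan(self, rng):
        for _ in range(25):
            x = rng.normal(0, 1, N_CYCLE)
            y = rng.normal(0, 1, N_CYCLE)
            got = sr.cross_correlate(x, y)
            best = (-np.inf, 0)
            for lag in range(-50, 51):
                if lag >= 0:
                    xs, ys = x[lag:], y[: N_CYCLE - lag]
                else:
                    xs, ys = x[: N_CYCLE + lag], y[-lag:]
                r = np.corrcoef(xs, ys)[0, 1]
                if r > best[0] + 1e-15:
                    best = (r, lag)
            assert got.r == pytest.approx(best[0], abs=1e-10)

    def test_match_flag_is_strict(self):
        x = np.sin(np.linspace(0, 3, N_CYCLE))
        noise = np.sin(np.linspace(0, 40, N_CYCLE))
        for target, expect in ((0.71, True), (0.69, False)):
            # mix signals to land near the target correlation at lag 0
            from scipy.optimize import brentq

            def r_of(alpha):
                y = alpha * x + (1 - alpha) * noise
                return float(np.corrcoef(x, y)[0, 1]) - target

            alpha = brentq(r_of, 0.01, 0.99)
            y = alpha * x + (1 - alpha) * noise
            cc = sr.cross_correlate(x, y)
            if cc.r > 0.7:
                assert cc.matched is True
            else:
                assert cc.matched is False

    def test_constant_channel_undefined_not_zero(self):
        x = np.ones(N_CYCLE)
        y = np.sin(np.linspace(0, 3, N_CYCLE))
        cc = sr.cross_correlate(x, y)
        assert np.isnan(cc.r)
        assert cc.matched is False


class TestAggregateRuns:
    def _cycle(self, offset, b=36.0):
        df = pd.DataFrame({"hip_deg": np.linspace(0, 1, N_CYCLE) + offset})
        return sr.STSCycle(df, {"liftoff": b, "momentum_transfer": 50.0,
                                "extension": 100.0}, 2.0)

    def test_single_cycle_mean_is_cycle(self):
        c = self._cycle(0.0)
        stats = sr.aggregate_runs([c])
        np.testing.assert_allclose(stats.mean["hip_deg"], c.channel("hip_deg"))
        np.testing.assert_allclose(stats.std["hip_deg"], 0.0)

    def test_two_cycle_statistics_by_hand(self):
        stats = sr.aggregate_runs([self._cycle(0.0, 36.0), self._cycle(2.0, 38.0)])
        assert stats.boundary_pct_mean["liftoff"] == pytest.approx(37.0)
        assert stats.boundary_pct_std["liftoff"] == pytest.approx(1.0)
        np.testing.assert_allclose(
            stats.mean["hip_deg"], np.linspace(0, 1, N_CYCLE) + 1.0
        )

    def test_order_invariance(self):
        a, b = self._cycle(0.0), self._cycle(1.0, 40.0)
        s1 = sr.aggregate_runs([a, b])
        s2 = sr.aggregate_runs([b, a])
        np.testing.assert_array_equal(s1.mean.to_numpy(), s2.mean.to_numpy())
        assert s1.boundary_pct_mean == s2.boundary_pct_mean

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sr.aggregate_runs([])


def test_experimental_liftoff_at_seat_force_derivative_minimum():
    traj = sr.generate_sts_trace(sr.FixtureSpec(seed=4))
    b = sr.detect_phases(traj, mode="experimental", smooth_hz=10.0)
    seat = traj.channel("seat_force_N")
    # oracle: steepest decline of the (smoothed) seat force
    from stsreflex.analysis import _smooth

    dseat = np.gradient(_smooth(seat, traj.dt, 10.0), traj.dt)
    assert b.liftoff == int(np.argmin(dseat))
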