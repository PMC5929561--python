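"""Activation mapping and conduction diagnostics on constructed signals
and synthetic maps."""

import numpy as np
import pytest

from cardiofuse import analysis as an
from cardiofuse import tissue as ts


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestActivationTimes:
    def test_sigmoid_upstroke_at_50ms(self):
        t = np.arange(0.0, 100.0, 0.05)
        v = -80.0 + 100.0 * sigmoid((t - 50.0) / 1.0)
        got = an.activation_times_from_traces(t, v[:, None])[0]
        # brute-force argmax of the finite-difference derivative
        dv = np.diff(v) / np.diff(t)
        expect = t[int(np.argmax(dv)) + 1]
        assert got == pytest.approx(expect, abs=0.1)
        assert got == pytest.approx(50.0, abs=0.5)

    def test_flat_trace_unactivated(self):
        t = np.arange(0.0, 100.0, 0.1)
        v = np.full_like(t, -80.0)
        assert np.isnan(an.activation_times_from_traces(t, v[:, None])[0])

    def test_translation_invariance(self):
        t = np.arange(0.0, 200.0, 0.05)
        v1 = -80.0 + 100.0 * sigmoid((t - 50.0) / 1.5)
        v2 = -80.0 + 100.0 * sigmoid((t - 83.0) / 1.5)
        a = an.activation_times_from_traces(t, np.column_stack([v1, v2]))
        assert a[1] - a[0] == pytest.approx(33.0, abs=0.1)

    def test_empty_result_rejected(self):
        with pytest.raises(ValueError):
            an.activation_times_from_traces(np.array([0.0]), np.zeros((1, 1)))


def _map_for(geometry, times):
    return an.ActivationMap(np.asarray(times, float), (0.0, 1e3))


class TestClassifyAndDelay:
    @pytest.fixture()
    def block_geo(self):
        return ts.build_elongated_tissue(2, 2, 30, (12, 17),
                                         ts.BoundaryProfile(sigma=0.0, seed=0))

    def test_full_activation_is_success(self, block_geo):
        amap = _map_for(block_geo, np.arange(block_geo.n_cells, dtype=float))
        assert an.classify_conduction(amap, block_geo)

    def test_silent_distal_is_failure(self, block_geo):
        t = np.arange(block_geo.n_cells, dtype=float)
        t[18 * 4:] = np.nan  # nothing distal of the block activates
        assert not an.classify_conduction(_map_for(block_geo, t), block_geo)

    def test_constant_velocity_identity(self, block_geo):
        """A wave at speed c gives delay = (gap between the CM layers
        flanking the block) / c."""
        c = 2.0  # layers per ms
        nl = 4
        z = np.arange(block_geo.n_cells) // nl
        amap = _map_for(block_geo, z / c)
        # flanking CM layers are z=11 and z=18: 7 layers apart
        assert an.center_block_delay(amap, block_geo) == pytest.approx(7 / c)

    def test_two_plateau_step(self, block_geo):
        nl = 4
        z = np.arange(block_geo.n_cells) // nl
        t = np.where(z <= 11, 5.0, np.nan)
        t = np.where(z >= 18, 47.5, t)
        assert an.center_block_delay(_map_for(block_geo, t),
                                     block_geo) == pytest.approx(42.5)

    def test_delay_undefined_on_failure(self, block_geo):
        t = np.full(block_geo.n_cells, np.nan)
        t[:12 * 4] = 1.0
        with pytest.raises(ValueError):
            an.center_block_delay(_map_for(block_geo, t), block_geo)


class TestDoubleDepolarization:
    def test_single_ap_gives_one_event(self):
        t = np.arange(0.0, 150.0, 0.05)
        v = -80.0 + 110.0 * sigmoid((t - 40.0) / 0.8) * np.exp(-(t - 40.0).clip(0) / 200.0)
        ev, _ = an.detect_double_depolarization(t, v)
        assert len(ev) == 1
        assert ev[0] == pytest.approx(40.0, abs=2.0)

    def test_two_shifted_sigmoids(self):
        t = np.arange(0.0, 150.0, 0.05)
        v = -80.0 + 30.0 * sigmoid((t - 40.0) / 1.0) + 25.0 * sigmoid((t - 90.0) / 1.0)
        ev, _ = an.detect_double_depolarization(t, v)
        assert len(ev) == 2
        assert ev[0] == pytest.approx(40.0, abs=2.0)
        assert ev[1] == pytest.approx(90.0, abs=2.0)

    def test_synchrony_reporting(self):
        t = np.arange(0.0, 150.0, 0.05)
        cf = -80.0 + 25.0 * sigmoid((t - 40.0) / 1.0) + 20.0 * sigmoid((t - 90.0) / 1.0)
        prox = -80.0 + 110.0 * sigmoid((t - 39.0) / 0.5)
        dist = -80.0 + 110.0 * sigmoid((t - 91.0) / 0.5)
        ev, sync = an.detect_double_depolarization(t, cf, prox, dist)
        assert sync == {"first_with_proximal": True, "second_with_distal": True}

    def test_flat_trace_no_events(self):
        t = np.arange(0.0, 100.0, 0.1)
        ev, sync = an.detect_double_depolarization(t, np.full_like(t, -70.0))
        assert len(ev) == 0 and sync == {}


class TestAmplitudeProfile:
    def test_decaying_fronts_strictly_decreasing(self):
        """Exponentially decaying passive fronts give a decreasing profile."""
        from cardiofuse import simulator as sm
        t = np.arange(0.0, 100.0, 0.1)
        geo = ts.build_elongated_tissue(1, 1, 6)
        traces = np.stack([-60.0 + 40.0 * np.exp(-d / 2.0)
                           * sigmoid((t - 30.0 - 3 * d) / 2.0)
                           for d in range(6)], axis=1)
        res = sm.SimulationResult(
            times=t, traces=traces, trace_cells=np.arange(6),
            layer_mean=traces, act_time=np.full(6, np.nan),
            act_dvdt=np.full(6, np.nan), geometry=geo,
            config=None, stimulus=None, t_end=100.0, status="completed",
            dt_us_used=5.0)
        amps = an.amplitude_profile(res, np.arange(6))
        assert np.all(np.diff(amps) < 0)

    def test_uniform_fronts_near_constant(self):
        from cardiofuse import simulator as sm
        t = np.arange(0.0, 100.0, 0.1)
        geo = ts.build_elongated_tissue(1, 1, 5)
        traces = np.stack([-80.0 + 120.0 * sigmoid((t - 20.0 - 2 * d) / 0.5)
                           for d in range(5)], axis=1)
        res = sm.SimulationResult(
            times=t, traces=traces, trace_cells=np.arange(5),
            layer_mean=traces, act_time=np.full(5, np.nan),
            act_dvdt=np.full(5, np.nan), geometry=geo,
            config=None, stimulus=None, t_end=100.0, status="completed",
            dt_us_used=5.0)
        amps = an.amplitude_profile(res, np.arange(5))
        assert np.ptp(amps) < 0.05 * amps.mean()


class TestThresholdSearch:
    def test_bisection_recovers_switch_point(self):
        """Monotone synthetic classifier: threshold found to resolution."""
        true_thr = 0.374
        calls = []

        def runner(g):
            calls.append(g)
            return g >= true_thr

        got = an.find_gna_threshold(0.1, 0.6, resolution=0.01, runner=runner)
        assert true_thr <= got <= true_thr + 0.011

    def test_unbracketed_endpoints_rejected(self):
        with pytest.raises(ValueError):
            an.find_gna_threshold(0.1, 0.6, runner=lambda g: True)
        with pytest.raises(ValueError):
            an.find_gna_threshold(0.1, 0.6, runner=lambda g: False)
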