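"""Monodomain integration: unit conversion, stepping semantics, kernel
against exact and dense-ODE references."""

import numpy as np
import pytest

from cardiofuse import ionic_models as im
from cardiofuse import simulator as sm
from cardiofuse import tissue as ts


class TestDensityToAbsolute:
    @pytest.mark.parametrize("dens,cap,expect", [
        (0.0, 63.0, 0.0),
        (1.0, 63.0, 63.0),
        (1.0, 6.3, 6.3),
    ])
    def test_unit_identity(self, dens, cap, expect):
        assert sm.density_to_absolute(dens, cap) == pytest.approx(expect)

    def test_invalid_capacitance(self):
        with pytest.raises(ValueError):
            sm.density_to_absolute(1.0, 0.0)


class TestStepSemantics:
    def test_uniform_voltage_has_zero_gap_term(self, tiny_mixed):
        geo, coup = tiny_mixed
        V = np.full(geo.n_cells, -60.0)
        gap = sm._gap_current(V, coup)
        assert np.all(gap == 0.0)

    def test_gap_currents_sum_to_zero(self, tiny_mixed):
        """Pairwise antisymmetry: total gap current vanishes identically."""
        geo, coup = tiny_mixed
        rng = np.random.default_rng(0)
        for _ in range(5):
            V = rng.uniform(-90, 30, geo.n_cells)
            assert sm._gap_current(V, coup).sum() == pytest.approx(0.0, abs=1e-9)

    def test_two_cell_pair_sequential_activation(self):
        """A stimulated CM drags its coupled neighbour to threshold later."""
        geo = ts.build_elongated_tissue(1, 1, 2)
        coup = ts.build_coupling_map(geo)
        cmp_, cfp = im.CMParams(), im.CFParams()
        V, G, aux = sm.initial_state_arrays(geo, cmp_, cfp)
        ct, cap = geo.flat_types(), geo.capacitances()
        dt = 0.005
        stim = np.array([4000.0, 0.0])
        t_act = [None, None]
        for step in range(int(20.0 / dt)):
            t = step * dt
            V, G, aux = sm.reference_step(V, G, aux, ct, cap, coup, cmp_, cfp,
                                          dt, stim if t < 2.0 else None)
            for i in range(2):
                if t_act[i] is None and V[i] > 0.0:
                    t_act[i] = t
        assert t_act[0] is not None and t_act[1] is not None
        assert t_act[1] > t_act[0]

    def test_kernel_matches_reference_step(self, tiny_mixed):
        """Lookup-table kernel against the exact NumPy stepper."""
        geo, coup = tiny_mixed
        cmp_, cfp = im.CMParams(), im.CFParams(g_Na=0.6)
        stim = sm.StimulusProtocol(amplitude_pA=4000.0, n_layers=1)
        cfg = sm.SimulationConfig(dt_us=5.0, duration_ms=15.0,
                                  record_every_ms=0.25, equilibrate_ms=0.0,
                                  sleep_quiescent=False,
                                  record_cells=np.arange(geo.n_cells))
        res = sm.run(geo, stim, cfg, coup, cmp_, cfp)
        V, G, aux = sm.initial_state_arrays(geo, cmp_, cfp)
        ct, cap = geo.flat_types(), geo.capacitances()
        dt = 0.005
        target = stim.target_cells(geo)
        amp = np.zeros(geo.n_cells)
        amp[target] = 4000.0
        traj = [V.copy()]
        for step in range(int(15.0 / dt)):
            t = step * dt
            V, G, aux = sm.reference_step(V, G, aux, ct, cap, coup, cmp_, cfp,
                                          dt, amp if t < 2.0 else None)
            if (step + 1) % 50 == 0:
                traj.append(V.copy())
        ref = np.stack(traj)
        assert np.abs(res.traces - ref).max() < 0.35

    def test_nonfinite_abort_names_cell(self, tiny_mixed):
        geo, coup = tiny_mixed
        V = np.full(geo.n_cells, -80.0)
        V[5] = np.nan
        G = np.zeros((geo.n_cells, 6))
        aux = np.full(geo.n_cells, 1e-4)
        # the NaN reaches coupled neighbours within the step; some cell
        # index is reported
        with pytest.raises(FloatingPointError, match=r"cell \d+"):
            sm.reference_step(V, G, aux, geo.flat_types(),
                              geo.capacitances(), coup, im.CMParams(),
                              im.CFParams(), 0.005)


class TestKernelIntegration:
    def test_isolated_cell_matches_single_cell_model(self):
        """A 1x1x1 'network' reproduces the single-cell trajectory."""
        geo = ts.build_elongated_tissue(1, 1, 1)
        coup = ts.build_coupling_map(geo)
        cmp_, cfp = im.CMParams(), im.CFParams()
        stim = sm.StimulusProtocol(amplitude_pA=2500.0, n_layers=1,
                                   pulse_ms=1.0)
        cfg = sm.SimulationConfig(dt_us=2.0, duration_ms=50.0,
                                  record_every_ms=0.5, equilibrate_ms=0.0,
                                  sleep_quiescent=False,
                                  record_cells=np.array([0]))
        res = sm.run(geo, stim, cfg, coup, cmp_, cfp)

        from scipy.integrate import solve_ivp
        from cardiofuse.ionic_models import _cm_rhs
        y0 = sm.initial_state_arrays(geo, cmp_, cfp)
        y0 = np.concatenate([y0[0], y0[1][0], [y0[2][0]]])
        dens = 2500.0 / cmp_.C
        s1 = solve_ivp(lambda t, y: _cm_rhs(t, y, cmp_, dens), (0, 1.0), y0,
                       method="BDF", rtol=1e-8, atol=1e-10, dense_output=True)
        s2 = solve_ivp(lambda t, y: _cm_rhs(t, y, cmp_, 0.0), (1.0, 50.0),
                       s1.y[:, -1], method="BDF", rtol=1e-8, atol=1e-10,
                       dense_output=True)
        ref = np.array([(s1.sol(t) if t <= 1.0 else s2.sol(t))[0]
                        for t in res.times])
        assert np.abs(res.traces[:, 0] - ref).max() < 0.5

    def test_oracle_equivalence_dense_ode(self, tiny_mixed):
        """Kernel trajectory vs a stiff general-purpose solve of the same
        coupled system: max |dV| < 0.5 mV over the paced beat."""
        geo, coup = tiny_mixed
        cmp_, cfp = im.CMParams(), im.CFParams(g_Na=0.6)
        ct, cap = geo.flat_types(), geo.capacitances()
        stim = sm.StimulusProtocol(amplitude_pA=4000.0, n_layers=1)
        cfg = sm.SimulationConfig(dt_us=2.0, duration_ms=40.0,
                                  record_every_ms=0.5, equilibrate_ms=0.0,
                                  sleep_quiescent=False,
                                  record_cells=np.arange(geo.n_cells))
        res = sm.run(geo, stim, cfg, coup, cmp_, cfp)

        from scipy.integrate import solve_ivp
        V0, G0, aux0 = sm.initial_state_arrays(geo, cmp_, cfp)
        y0 = np.concatenate([V0, G0.reshape(-1), aux0])
        istim = np.zeros(geo.n_cells)
        istim[stim.target_cells(geo)] = 4000.0
        s1 = solve_ivp(sm.network_rhs, (0, 2.0), y0,
                       args=(ct, cap, coup, cmp_, cfp, istim),
                       method="BDF", rtol=1e-8, atol=1e-9, dense_output=True)
        s2 = solve_ivp(sm.network_rhs, (2.0, 40.0), s1.y[:, -1],
                       args=(ct, cap, coup, cmp_, cfp, None),
                       method="BDF", rtol=1e-8, atol=1e-9, dense_output=True)
        oracle = np.stack([(s1.sol(t) if t <= 2.0 else s2.sol(t))[:geo.n_cells]
                           for t in res.times])
        assert np.abs(res.traces - oracle).max() < 0.5

    def test_sleep_optimisation_does_not_change_activation(self, tiny_mixed):
        geo, coup = tiny_mixed
        cmp_, cfp = im.CMParams(), im.CFParams(g_Na=0.6)
        stim = sm.StimulusProtocol(amplitude_pA=4000.0, n_layers=1)
        maps = []
        for sleep in (False, True):
            cfg = sm.SimulationConfig(duration_ms=30.0, equilibrate_ms=0.0,
                                      sleep_quiescent=sleep,
                                      record_cells=np.array([0]))
            res = sm.run(geo, stim, cfg, coup, cmp_, cfp)
            maps.append(res.act_time)
        a, b = maps
        both = np.isfinite(a) & np.isfinite(b)
        assert np.array_equal(np.isfinite(a), np.isfinite(b))
        assert np.abs(a[both] - b[both]).max() < 0.1

    def test_cf_trace_passive_shaped_at_low_gna(self):
        """In mixed tissue with weak CF sodium currents, the fibroblast
        depolarisation peaks well below the CM overshoot."""
        geo = ts.build_elongated_tissue(3, 3, 12, (5, 6),
                                        ts.BoundaryProfile(sigma=0.0, seed=0))
        coup = ts.build_coupling_map(geo)
        cmp_, cfp = im.CMParams(), im.CFParams(g_Na=0.05)
        stim = sm.StimulusProtocol(amplitude_pA=4000.0, n_layers=1)
        cfg = sm.SimulationConfig(duration_ms=40.0, equilibrate_ms=60.0,
                                  record_cells=np.arange(geo.n_cells))
        res = sm.run(geo, stim, cfg, coup, cmp_, cfp)
        t = geo.flat_types()
        cm_peak = res.traces[:, t == ts.CM].max()
        cf_peak = res.traces[:, t == ts.CF].max()
        assert cm_peak > 20.0
        assert cf_peak < cm_peak - 15.0

    def test_warns_on_large_dt(self):
        with pytest.warns(UserWarning, match="exceeds"):
            sm.SimulationConfig(dt_us=8.0)
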