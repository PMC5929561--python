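"""Monodomain lattice simulation driver.

Integrates C_i dV_i/dt = -I_ion,i + sum_k g_gap,ik (V_k - V_i) (+ stimulus)
over the typed lattice: forward Euler on voltages, Rush-Larsen on gates,
synchronous update.  The fast path is the compiled kernel in
:mod:`cardiofuse._kernel`; an exact (table-free) NumPy stepper and a dense
ODE right-hand side are provided for verification at small lattice sizes.

Units: mV, ms, pA, pF, nS throughout the network equation
(nS x mV = pA; pA/pF = mV/ms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import ionic_models as im
from . import _kernel
from .tissue import CM, CF, TissueGeometry, CouplingMap, build_coupling_map

__all__ = [
    "StimulusProtocol", "SimulationConfig", "SimulationResult",
    "density_to_absolute", "initial_state_arrays", "reference_step",
    "network_rhs", "run", "find_stim_threshold",
]


def density_to_absolute(current_density, capacitance):
    """Convert a current density (uA/uF) to absolute current (pA).

    uA/uF is identical to pA/pF, so the conversion is a plain product with
    the membrane capacitance in pF.
    """
    capacitance = np.asarray(capacitance, dtype=float)
    if np.any(capacitance <= 0):
        raise ValueError("capacitance must be positive")
    return np.asarray(current_density, dtype=float) * capacitance


@dataclass
class StimulusProtocol:
    """Current injection into the CMs of the first ``n_layers`` z-layers.

    ``amplitude_pA`` is the per-cell injected current during the pulse.
    ``target`` may be given explicitly (flat cell indices); otherwise all
    CMs in the first ``n_layers`` layers are stimulated.
    """

    amplitude_pA: float = 4000.0
    pulse_ms: float = 2.0
    period_ms: float = 1000.0
    count: int = 1
    n_layers: int = 2
    target: np.ndarray | None = None

    def __post_init__(self):
        if self.pulse_ms <= 0:
            raise ValueError("pulse duration must be positive")
        if self.amplitude_pA < 0:
            raise ValueError("amplitude must be nonnegative")

    def target_cells(self, geometry: TissueGeometry) -> np.ndarray:
        if self.target is not None:
            return np.asarray(self.target, dtype=np.int64)
        types = geometry.flat_types()
        n_layer = geometry.nx * geometry.ny
        first = np.arange(n_layer * self.n_layers)
        return first[types[first] == CM]


@dataclass
class SimulationConfig:
    dt_us: float = 5.0
    duration_ms: float = 300.0
    record_every_ms: float = 0.05
    record_cells: np.ndarray | None = None   # default: central axial line
    chunk_ms: float = 5.0
    equilibrate_ms: float = 120.0   # max coupled-rest relaxation before stim
    sleep_quiescent: bool = True
    wake_tol_pA: float = 0.05
    stop_on_watch_fraction: float | None = None  # e.g. 0.95 of watch cells
    watch_cells: np.ndarray | None = None
    stagnation_ms: float | None = None  # stop if no new activation this long
    max_dt_retries: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.dt_us <= 0 or self.duration_ms <= 0:
            raise ValueError("dt and duration must be positive")
        if self.dt_us > 5.0 + 1e-12:
            warnings.warn(f"dt = {self.dt_us} us exceeds the validated 1-5 us "
                          "range", stacklevel=2)


@dataclass
class SimulationResult:
    times: np.ndarray                 # ms, recorded sample times
    traces: np.ndarray                # (n_samples, n_recorded) mV
    trace_cells: np.ndarray           # flat indices of recorded cells
    layer_mean: np.ndarray            # (n_samples, nz) mV
    act_time: np.ndarray              # (N,) ms; NaN where never activated
    act_dvdt: np.ndarray              # (N,) mV/ms at activation
    geometry: TissueGeometry
    config: SimulationConfig
    stimulus: StimulusProtocol
    t_end: float
    status: str                       # "completed" | "watch" | "stagnated"
    dt_us_used: float

    @property
    def activated(self) -> np.ndarray:
        return np.isfinite(self.act_time)

    def trace(self, cell: int) -> np.ndarray:
        pos = np.nonzero(self.trace_cells == cell)[0]
        if pos.size == 0:
            raise KeyError(f"cell {cell} was not recorded")
        return self.traces[:, pos[0]]

    def to_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            for name in ("times", "traces", "trace_cells", "layer_mean",
                         "act_time", "act_dvdt"):
                f.create_dataset(name, data=getattr(self, name))
            f.create_dataset("cell_type", data=self.geometry.cell_type)
            f.attrs["t_end"] = self.t_end
            f.attrs["status"] = self.status
            f.attrs["dt_us_used"] = self.dt_us_used


_SETTLE_CACHE: dict = {}


def _settled(model: str, params) -> np.ndarray:
    key = (model, tuple(sorted(vars(params).items())))
    if key not in _SETTLE_CACHE:
        _SETTLE_CACHE[key] = im.settle_to_rest(model, params).as_array()
    return _SETTLE_CACHE[key]


def initial_state_arrays(geometry: TissueGeometry,
                         cm_params: im.CMParams, cf_params: im.CFParams):
    """Per-cell (V, gates, aux) arrays initialised at each type's rest.

    Gate columns: CM (m, h, j, d, f, X), CF (r, s, m_TR, h_TR, j_TR, h_TS);
    ``aux`` is Ca_i for CMs, K_i for CFs.
    """
    ct = geometry.flat_types()
    n = ct.size
    V = np.empty(n)
    G = np.empty((n, 6))
    aux = np.empty(n)
    cm0 = _settled("CM", cm_params)      # V m h j d f X Ca
    cf0 = _settled("CF", cf_params)      # V r s Ki mTR hTR jTR hTS
    cm_mask = ct == CM
    V[cm_mask] = cm0[0]
    G[cm_mask] = cm0[1:7]
    aux[cm_mask] = cm0[7]
    cf_mask = ~cm_mask
    V[cf_mask] = cf0[0]
    G[cf_mask] = np.concatenate([cf0[1:3], cf0[4:8]])
    aux[cf_mask] = cf0[3]
    return V, G, aux


def _gap_current(V, coupling: CouplingMap):
    idx = coupling.nbr_idx
    vk = np.where(idx >= 0, V[np.maximum(idx, 0)], 0.0)
    return (coupling.nbr_g * (vk - V[:, None]) * (idx >= 0)).sum(axis=1)


def reference_step(V, G, aux, ct, cap, coupling: CouplingMap,
                   cm_params: im.CMParams, cf_params: im.CFParams,
                   dt_ms: float, i_stim=None):
    """One exact synchronous step (no lookup tables); returns new arrays.

    Semantics match the compiled kernel: forward Euler on V, Ca_i and K_i,
    Rush-Larsen on all gates, gap term evaluated on the old voltages.
    """
    if i_stim is None:
        i_stim = 0.0
    V = np.asarray(V, float)
    gap = _gap_current(V, coupling)
    i_ion = np.empty_like(V)
    Gn = G.copy()
    auxn = aux.copy()

    cm_mask = ct == CM
    if cm_mask.any():
        v = V[cm_mask]
        g = G[cm_mask]
        ca = aux[cm_mask]
        cur = im.cm_current_density(v, g[:, 0], g[:, 1], g[:, 2], g[:, 3],
                                    g[:, 4], g[:, 5], ca, cm_params)
        i_ion[cm_mask] = cur["total"] * cap[cm_mask]
        inf, tau = im.cm_gate_kinetics(v)
        Gn[cm_mask] = (inf - (inf - g.T) * np.exp(-dt_ms / tau)).T
        auxn[cm_mask] = ca + dt_ms * im.cm_ca_derivative(cur["I_si"], ca)

    cf_mask = ~cm_mask
    if cf_mask.any():
        v = V[cf_mask]
        g = G[cf_mask]
        ki = aux[cf_mask]
        base = im.cf_base_current_density(v, g[:, 0], g[:, 1], ki, cf_params)
        i_na = (im.i_na_tr(v, g[:, 2], g[:, 3], g[:, 4], cf_params)
                + im.i_na_ts(v, g[:, 2], g[:, 5], cf_params))
        i_ion[cf_mask] = base["total"] * cap[cf_mask] + i_na
        inf, tau = im.cf_gate_kinetics(v)
        Gn[cf_mask] = (inf - (inf - g.T) * np.exp(-dt_ms / tau)).T
        auxn[cf_mask] = ki + dt_ms * im.cf_ki_derivative(
            base["I_Kv"], base["I_K1"], base["I_NaK"], cf_params)

    stim = np.zeros_like(V) + i_stim
    Vn = V + dt_ms * (-i_ion + gap + stim) / cap
    if not np.all(np.isfinite(Vn)):
        bad = int(np.nonzero(~np.isfinite(Vn))[0][0])
        raise FloatingPointError(f"non-finite voltage at cell {bad}")
    return Vn, Gn, auxn


def network_rhs(t, y, ct, cap, coupling: CouplingMap,
                cm_params: im.CMParams, cf_params: im.CFParams,
                i_stim=None):
    """Dense ODE right-hand side of the identical coupled system.

    State layout: y = [V (N), gates (N x 6 flattened), aux (N)].  Used with
    a general-purpose stiff solver as the independent oracle for the
    explicit lattice scheme.
    """
    n = ct.size
    V = y[:n]
    G = np.clip(y[n:7 * n].reshape(n, 6), 0.0, 1.0)
    aux = np.maximum(y[7 * n:], 1e-8)
    gap = _gap_current(V, coupling)
    dV = np.empty(n)
    dG = np.empty((n, 6))
    daux = np.empty(n)

    cm_mask = ct == CM
    if cm_mask.any():
        v = V[cm_mask]
        g = G[cm_mask]
        ca = aux[cm_mask]
        cur = im.cm_current_density(v, g[:, 0], g[:, 1], g[:, 2], g[:, 3],
                                    g[:, 4], g[:, 5], ca, cm_params)
        i_ion = cur["total"] * cap[cm_mask]
        inf, tau = im.cm_gate_kinetics(v)
        dG[cm_mask] = ((inf - g.T) / tau).T
        daux[cm_mask] = im.cm_ca_derivative(cur["I_si"], ca)
        dV[cm_mask] = i_ion
    cf_mask = ~cm_mask
    if cf_mask.any():
        v = V[cf_mask]
        g = G[cf_mask]
        ki = aux[cf_mask]
        base = im.cf_base_current_density(v, g[:, 0], g[:, 1], ki, cf_params)
        i_na = (im.i_na_tr(v, g[:, 2], g[:, 3], g[:, 4], cf_params)
                + im.i_na_ts(v, g[:, 2], g[:, 5], cf_params))
        dV[cf_mask] = base["total"] * cap[cf_mask] + i_na
        inf, tau = im.cf_gate_kinetics(v)
        dG[cf_mask] = ((inf - g.T) / tau).T
        daux[cf_mask] = im.cf_ki_derivative(
            base["I_Kv"], base["I_K1"], base["I_NaK"], cf_params)

    stim = np.zeros(n) if i_stim is None else np.asarray(i_stim, float)
    dVdt = (-dV + gap + stim) / cap
    return np.concatenate([dVdt, dG.reshape(-1), daux])


def run(geometry: TissueGeometry,
        stimulus: StimulusProtocol | None = None,
        config: SimulationConfig | None = None,
        coupling: CouplingMap | None = None,
        cm_params: im.CMParams | None = None,
        cf_params: im.CFParams | None = None) -> SimulationResult:
    """Run a full lattice simulation with the compiled kernel.

    Initial conditions are each cell type's settled resting state.  The
    integration restarts with a halved time step (up to
    ``config.max_dt_retries`` times) if a non-finite voltage appears.
    """
    stimulus = stimulus or StimulusProtocol()
    config = config or SimulationConfig()
    cm_params = cm_params or im.CMParams()
    cf_params = cf_params or im.CFParams()
    if coupling is None:
        coupling = build_coupling_map(geometry)

    dt_us = config.dt_us
    for attempt in range(config.max_dt_retries + 1):
        result = _run_once(geometry, stimulus, config, coupling,
                           cm_params, cf_params, dt_us)
        if result is not None:
            return result
        dt_us /= 2.0
        warnings.warn(f"instability detected; retrying with dt = {dt_us} us",
                      stacklevel=2)
    raise FloatingPointError("simulation unstable even after dt halving")


_EQUIL_CACHE: dict = {}


def _equilibrated_states(geometry, coupling, cm_params, cf_params, dt, config):
    """Coupled diastolic state of the whole lattice.

    The per-type resting states are not an equilibrium of the coupled
    tissue (CM and CF rest ~35 mV apart), and relaxing with sodium
    channels available lets isolated CMs in CF-rich layers fire spuriously
    at t = 0.  We therefore relax the network with all Na conductances
    zeroed (the equilibrium is then independent of g_Na, so it can be
    cached per geometry) and afterwards set every Na gate to its steady
    state at the local equilibrium potential.
    """
    key = (geometry.cell_type.tobytes(), round(dt, 9),
           tuple(sorted(vars(cm_params).items())),
           tuple(sorted((k, v) for k, v in vars(cf_params).items()
                        if k not in ("g_Na", "gamma"))))
    if key in _EQUIL_CACHE:
        V, G, aux = _EQUIL_CACHE[key]
        return V.copy(), G.copy(), aux.copy()

    ct = geometry.flat_types()
    cap = geometry.capacitances()
    V, G, aux = initial_state_arrays(geometry, cm_params, cf_params)
    Vnew = V.copy()
    cm_na_off = replace(cm_params, g_Na=0.0)
    cf_na_off = replace(cf_params, g_Na=0.0)
    cm_tab, cf_tab, k1_tab = _kernel.build_tables(dt, cm_na_off, cf_na_off)
    cmp_, cfp = _kernel.build_params(cm_na_off, cf_na_off)

    n = V.size
    no_stim = np.zeros(n)
    act_phase = np.zeros(n, dtype=np.uint8)
    act_t = np.full(n, np.nan)
    act_dv = np.full(n, np.nan)
    quiet = np.zeros(n, dtype=np.int64)
    asleep = np.zeros(n, dtype=np.uint8)
    sleep_gap = np.zeros(n)
    rec_idx = np.zeros(1, dtype=np.int64)
    rec_buf = np.zeros((1, 1))
    layer_of = np.zeros(n, dtype=np.int64)
    layer_inv = np.ones(1)
    layer_buf = np.zeros((1, 1))

    chunk = max(int(round(10.0 / dt)), 1)
    total = int(round(config.equilibrate_ms / dt))
    step = 0
    v_prev = V.copy()
    while step < total:
        nsteps = min(chunk, total - step)
        code, step = _kernel.run_chunk(
            V, Vnew, G, aux, ct, cap, coupling.nbr_idx, coupling.nbr_g,
            cm_tab, cf_tab, k1_tab, cmp_, cfp,
            dt, step, nsteps,
            no_stim, 1, 10 ** 9, 0,
            act_phase, act_t, act_dv,
            quiet, asleep, sleep_gap, config.sleep_quiescent,
            config.wake_tol_pA, 0.01 * dt, int(round(1.0 / dt)),
            rec_idx, rec_buf, layer_of, layer_inv, layer_buf, 10 ** 9)
        if code != 0:
            raise FloatingPointError("instability during pre-equilibration")
        if np.max(np.abs(V - v_prev)) / (nsteps * dt) < 0.02:
            break
        v_prev[:] = V

    # sodium gates to steady state at the local equilibrium potential
    cm_mask = ct == CM
    if cm_mask.any():
        inf, _ = im.cm_gate_kinetics(V[cm_mask])
        G[cm_mask, 0:3] = inf[0:3].T
    cf_mask = ~cm_mask
    if cf_mask.any():
        inf, _ = im.cf_gate_kinetics(V[cf_mask])
        G[cf_mask, 2:6] = inf[2:6].T
    _EQUIL_CACHE[key] = (V.copy(), G.copy(), aux.copy())
    if len(_EQUIL_CACHE) > 8:
        _EQUIL_CACHE.pop(next(iter(_EQUIL_CACHE)))
    return V, G, aux


def _run_once(geometry, stimulus, config, coupling, cm_params, cf_params,
              dt_us):
    dt = dt_us * 1e-3  # ms
    n = geometry.n_cells
    ct = geometry.flat_types()
    cap = geometry.capacitances()
    if config.equilibrate_ms > 0:
        V, G, aux = _equilibrated_states(geometry, coupling, cm_params,
                                         cf_params, dt, config)
    else:
        V, G, aux = initial_state_arrays(geometry, cm_params, cf_params)
    Vnew = V.copy()

    cm_tab, cf_tab, k1_tab = _kernel.build_tables(dt, cm_params, cf_params)
    cmp_, cfp = _kernel.build_params(cm_params, cf_params)

    stim_amp = np.zeros(n)
    stim_amp[stimulus.target_cells(geometry)] = stimulus.amplitude_pA
    stim_dur_steps = max(int(round(stimulus.pulse_ms / dt)), 1)
    stim_period_steps = max(int(round(stimulus.period_ms / dt)), 1)

    rec_stride = max(int(round(config.record_every_ms / dt)), 1)
    total_steps = int(round(config.duration_ms / dt))
    n_samples = total_steps // rec_stride + 1
    if config.record_cells is None:
        xc, yc = geometry.nx // 2, geometry.ny // 2
        rec_idx = geometry.flat_index(xc, yc, np.arange(geometry.nz))
    else:
        rec_idx = np.asarray(config.record_cells, dtype=np.int64)
    rec_buf = np.full((n_samples, rec_idx.size), np.nan)
    rec_buf[0] = V[rec_idx]
    layer_of = (np.arange(n) // (geometry.nx * geometry.ny)).astype(np.int64)
    layer_inv = 1.0 / np.bincount(layer_of).astype(float)
    layer_buf = np.full((n_samples, geometry.nz), np.nan)
    layer_buf[0] = [V[layer_of == z].mean() for z in range(geometry.nz)]

    act_phase = np.zeros(n, dtype=np.uint8)
    act_t = np.full(n, np.nan)
    act_dv = np.full(n, np.nan)
    quiet = np.zeros(n, dtype=np.int64)
    asleep = np.zeros(n, dtype=np.uint8)
    sleep_gap = np.zeros(n)
    quiet_dv = 0.01 * dt       # |dV/dt| < 0.01 mV/ms counts as quiet
    quiet_steps = int(round(1.0 / dt))  # ... sustained for 1 ms

    watch = config.watch_cells
    watch_frac = config.stop_on_watch_fraction
    stag_ms = config.stagnation_ms
    last_count = 0
    last_progress_t = 0.0

    chunk_steps = max(int(round(config.chunk_ms / dt)) // rec_stride, 1) * rec_stride
    step = 0
    status = "completed"
    while step < total_steps:
        nsteps = min(chunk_steps, total_steps - step)
        code, step = _kernel.run_chunk(
            V, Vnew, G, aux, ct, cap, coupling.nbr_idx, coupling.nbr_g,
            cm_tab, cf_tab, k1_tab, cmp_, cfp,
            dt, step, nsteps,
            stim_amp, stim_dur_steps, stim_period_steps, stimulus.count,
            act_phase, act_t, act_dv,
            quiet, asleep, sleep_gap,
            config.sleep_quiescent, config.wake_tol_pA,
            quiet_dv, quiet_steps,
            rec_idx, rec_buf, layer_of, layer_inv, layer_buf, rec_stride)
        if code != 0:
            return None  # instability -> caller halves dt
        t_now = step * dt
        if watch is not None and watch_frac is not None:
            frac = np.mean(act_phase[watch] > 0)
            if frac >= watch_frac:
                status = "watch"
                break
        if stag_ms is not None:
            count = int((act_phase > 0).sum())
            if count > last_count:
                last_count = count
                last_progress_t = t_now
            elif (t_now - last_progress_t > stag_ms
                  and t_now > stimulus.pulse_ms + stag_ms):
                status = "stagnated"
                break

    filled = step // rec_stride + 1
    times = np.arange(filled) * rec_stride * dt
    act_time = np.where(act_phase > 0, act_t, np.nan)
    return SimulationResult(
        times=times, traces=rec_buf[:filled], trace_cells=rec_idx,
        layer_mean=layer_buf[:filled], act_time=act_time, act_dvdt=act_dv,
        geometry=geometry, config=config, stimulus=stimulus,
        t_end=step * dt, status=status, dt_us_used=dt_us)


def find_stim_threshold(geometry: TissueGeometry,
                        coupling: CouplingMap | None = None,
                        cm_params: im.CMParams | None = None,
                        cf_params: im.CFParams | None = None,
                        pulse_ms: float = 2.0, n_layers: int = 2,
                        check_layer: int = 4, lo: float = 50.0,
                        hi: float = 51200.0, rel_tol: float = 0.25,
                        dt_us: float = 5.0) -> float:
    """Diastolic per-cell stimulus threshold (pA) of the end layers.

    Bisects the pulse amplitude until the margin between capture and
    no-capture (any CM in ``check_layer`` activating within a short window)
    is below ``rel_tol``.  Used to set the default stimulus at twice
    threshold.
    """
    if coupling is None:
        coupling = build_coupling_map(geometry)
    cm_params = cm_params or im.CMParams()
    cf_params = cf_params or im.CFParams()
    n_layer_cells = geometry.nx * geometry.ny
    probe = np.arange(n_layer_cells * check_layer,
                      n_layer_cells * (check_layer + 1))
    probe = probe[geometry.flat_types()[probe] == CM]

    def captures(amp):
        stim = StimulusProtocol(amplitude_pA=amp, pulse_ms=pulse_ms,
                                n_layers=n_layers, count=1)
        cfg = SimulationConfig(dt_us=dt_us, duration_ms=15.0,
                               record_every_ms=0.5, chunk_ms=15.0,
                               record_cells=probe[:1])
        res = run(geometry, stim, cfg, coupling, cm_params, cf_params)
        return bool(res.activated[probe].any())

    if captures(lo):
        raise ValueError("lower bound already captures; lower `lo`")
    while not captures(hi):
        hi *= 2.0
        if hi > 1e7:
            raise ValueError("no capture even at very large amplitude")
    while (hi - lo) / hi > rel_tol:
        mid = np.sqrt(lo * hi)
        if captures(mid):
            hi = mid
        else:
            lo = mid
    return hi
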