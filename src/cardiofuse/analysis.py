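"""Activation mapping, conduction classification and parameter sweeps.

Operationalises the optical-mapping style readouts on simulated tissue:

* activation time = time of maximum dV/dt during the first upstroke that
  crosses -20 mV (standard optical-mapping practice, robust against the
  sub-threshold electrotonic depolarisations of fibroblasts);
* conduction success = at least 95 % of the CMs distal to the central CF
  block activate within the analysis window (one pacing cycle);
* centre-block delay = difference of mean activation times of the first
  fully-CM layer distal and the last fully-CM layer proximal to the block;
* double-depolarisation and decremental-amplitude diagnostics on traces;
* bisection of the conducting g_Na threshold and the Gaussian-width
  (sigma) conduction-window sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks

from . import ionic_models as im
from . import simulator as sm
from .tissue import CM, CF, BoundaryProfile, TissueGeometry, \
    build_elongated_tissue

__all__ = [
    "ActivationMap", "ConductionSummary",
    "activation_times_from_traces", "activation_map",
    "classify_conduction", "center_block_delay",
    "detect_double_depolarization", "amplitude_profile", "normalize_trace",
    "run_cf_center", "find_gna_threshold", "sweep_gna",
    "sigma_conduction_window", "SweepPoint",
]

ACT_THRESHOLD_MV = -20.0


@dataclass
class ActivationMap:
    """Per-cell activation time (ms); NaN marks cells that never activated."""

    times: np.ndarray
    window: tuple[float, float]

    @property
    def activated(self) -> np.ndarray:
        return np.isfinite(self.times)


@dataclass
class ConductionSummary:
    success: bool
    delay_ms: float | None
    layer_activation: np.ndarray
    g_na: float | None = None
    sigma: float | None = None
    seed: int | None = None

    def __post_init__(self):
        if not self.success:
            self.delay_ms = None


def activation_times_from_traces(times, traces,
                                 threshold=ACT_THRESHOLD_MV) -> np.ndarray:
    """Activation time of each trace column (NaN if never suprathreshold).

    The activation time is the sample of maximum finite-difference dV/dt
    within the first contiguous suprathreshold segment of the trace.
    """
    times = np.asarray(times, float)
    traces = np.atleast_2d(np.asarray(traces, float))
    if traces.shape[0] == times.size and traces.ndim == 2:
        pass
    if times.size < 2:
        raise ValueError("need at least two samples")
    out = np.full(traces.shape[1], np.nan)
    dv = np.diff(traces, axis=0) / np.diff(times)[:, None]
    above = traces >= threshold
    for c in range(traces.shape[1]):
        idx = np.nonzero(above[:, c])[0]
        if idx.size == 0:
            continue
        cross = idx[0]
        # the upstroke containing the crossing: walk to where dV/dt <= 0
        lo = min(cross, dv.shape[0] - 1)
        while lo > 0 and dv[lo - 1, c] > 0:
            lo -= 1
        hi = min(cross, dv.shape[0] - 1)
        while hi < dv.shape[0] - 1 and dv[hi, c] > 0:
            hi += 1
        seg = dv[lo:hi + 1, c]
        out[c] = times[lo + int(np.argmax(seg)) + 1]
    return out


def activation_map(result: sm.SimulationResult) -> ActivationMap:
    """Whole-lattice activation map from the online upstroke detector."""
    if result.act_time.size == 0:
        raise ValueError("empty simulation result")
    return ActivationMap(result.act_time.copy(), (0.0, result.t_end))


def _distal_cm_cells(geometry: TissueGeometry, first_distal_layer: int):
    n_layer = geometry.nx * geometry.ny
    cells = np.arange(n_layer * first_distal_layer, geometry.n_cells)
    return cells[geometry.flat_types()[cells] == CM]


def classify_conduction(amap: ActivationMap, geometry: TissueGeometry,
                        frac: float = 0.95) -> bool:
    """Success iff >= ``frac`` of CMs distal to the CF block activated.

    The block position is taken from the geometry's boundary profile; an
    all-CM tissue is classified on the distal half of the lattice.
    """
    prof = geometry.profile
    first_distal = prof.z_hi + 1 if prof is not None else geometry.nz // 2
    cells = _distal_cm_cells(geometry, first_distal)
    if cells.size == 0:
        return False
    return bool(np.isfinite(amap.times[cells]).mean() >= frac)


def center_block_delay(amap: ActivationMap, geometry: TissueGeometry) -> float:
    """Activation-time step across the central block (ms).

    Mean activation of the first fully-CM layer distal to the block minus
    that of the last fully-CM layer proximal to it.  Mixed boundary layers
    are excluded because fibroblast "activation" is ill-defined.
    """
    prof = geometry.profile
    if prof is None:
        raise ValueError("geometry has no central block")
    frac = geometry.layer_cf_counts() / (geometry.nx * geometry.ny)

    def endpoint(layers):
        """Least-infiltrated layer nearest the block: prefer pure CM, then
        CM-majority, else the minimum-CF layer (its CM cells still carry a
        well-defined upstroke)."""
        if layers.size == 0:
            raise ValueError("no layer outside the block on one side")
        for thr in (0.0, 0.5):
            q = layers[frac[layers] <= thr]
            if q.size:
                return q
        return layers[frac[layers] == frac[layers].min()]

    prox = endpoint(np.arange(0, prof.z_lo))
    dist = endpoint(np.arange(prof.z_hi + 1, geometry.nz))
    n_layer = geometry.nx * geometry.ny
    t = amap.times
    types = geometry.flat_types()

    def layer_mean(z):
        cells = np.arange(z * n_layer, (z + 1) * n_layer)
        cells = cells[types[cells] == CM]
        if cells.size == 0:
            return np.nan
        return np.nanmean(t[cells])

    t_prox = layer_mean(int(prox.max()))
    t_dist = layer_mean(int(dist.min()))
    if not (np.isfinite(t_prox) and np.isfinite(t_dist)):
        raise ValueError("conduction failure: delay undefined")
    return float(t_dist - t_prox)


def normalize_trace(v):
    """Per-trace min-max normalisation (optical-mapping dF/F emulation)."""
    v = np.asarray(v, float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def detect_double_depolarization(times, trace, proximal_ref=None,
                                 distal_ref=None, prominence_mv: float = 5.0,
                                 min_separation_ms: float = 10.0,
                                 sync_tol_ms: float = 15.0):
    """Times of distinct depolarisation events in a (CF) trace.

    Events are prominence-filtered maxima of dV/dt.  If reference CM traces
    are given, reports whether the first event is synchronous with the
    proximal upstroke and the second with the distal upstroke (within
    ``sync_tol_ms``).

    Returns ``(event_times, sync)`` where sync is a dict (empty if no
    references were supplied).
    """
    times = np.asarray(times, float)
    trace = np.asarray(trace, float)
    dt = np.diff(times)
    dv = np.diff(trace) / dt
    # prominence on dV/dt scaled by the typical event width
    min_dist = max(int(round(min_separation_ms / dt.mean())), 1)
    vspan = trace.max() - trace.min()
    if vspan < prominence_mv:
        return np.array([]), {}
    peaks, props = find_peaks(dv, distance=min_dist,
                              prominence=prominence_mv / min_separation_ms)
    if peaks.size:
        # keep events whose local depolarisation amplitude is significant
        keep = []
        for p in peaks:
            lo = max(p - min_dist, 0)
            hi = min(p + min_dist, trace.size - 1)
            if trace[lo:hi + 1].max() - trace[lo] >= prominence_mv:
                keep.append(p)
        peaks = np.array(keep, dtype=int)
    event_times = times[peaks + 1]
    sync = {}
    if proximal_ref is not None and event_times.size >= 1:
        t_prox = activation_times_from_traces(times, proximal_ref[:, None])[0]
        sync["first_with_proximal"] = bool(
            np.isfinite(t_prox) and abs(event_times[0] - t_prox) <= sync_tol_ms)
    if distal_ref is not None and event_times.size >= 2:
        t_dist = activation_times_from_traces(times, distal_ref[:, None])[0]
        sync["second_with_distal"] = bool(
            np.isfinite(t_dist) and abs(event_times[-1] - t_dist) <= sync_tol_ms)
    return event_times, sync


def amplitude_profile(result: sm.SimulationResult, cells) -> np.ndarray:
    """Peak first-depolarisation amplitude (mV above diastole) per cell.

    ``cells`` must be ordered by distance from the proximal block face and
    recorded in the result.  The first depolarisation is bounded by the
    trace's first local dV/dt maximum and the subsequent dV/dt minimum;
    in practice the peak V within a fixed window after the event onset.
    """
    amps = []
    t = result.times
    for c in cells:
        v = result.trace(int(c))
        v0 = v[0]
        dv = np.diff(v)
        rising = np.nonzero(dv > 0.02)[0]
        if rising.size == 0:
            amps.append(max(float(v.max() - v0), 0.0))
            continue
        start = rising[0]
        # end of first depolarisation: first sustained fall after the rise
        fall = np.nonzero(dv[start:] < -0.002)[0]
        end = start + fall[0] if fall.size else v.size - 1
        amps.append(float(v[start:end + 1].max() - v0))
    return np.asarray(amps)


# ---------------------------------------------------------------------------
# experiment drivers
# ---------------------------------------------------------------------------

@dataclass
class SweepPoint:
    g_na: float
    sigma: float
    seed: int
    success: bool
    delay_ms: float | None
    mode: str


def run_cf_center(g_na: float,
                  sigma: float = 3.0,
                  mode: str = "shoulder",
                  dims: tuple[int, int, int] = (10, 10, 100),
                  block: tuple[int, int] | None = None,
                  seed: int = 1,
                  stim_amplitude_pA: float = 4000.0,
                  duration_ms: float = 600.0,
                  stagnation_ms: float = 100.0,
                  cf_params: im.CFParams | None = None,
                  cm_params: im.CMParams | None = None,
                  record_every_ms: float = 0.05) -> tuple[sm.SimulationResult, ConductionSummary]:
    """One CF-centre conduction experiment; returns (result, summary).

    The block defaults to the central fifth of the lattice (one spheroid).
    Early exit on distal capture or on activation stagnation keeps failure
    runs short.
    """
    nx, ny, nz = dims
    if block is None:
        b = nz // 5
        block = (2 * b, 3 * b - 1)
    geo = build_elongated_tissue(nx, ny, nz, block,
                                 BoundaryProfile(sigma=sigma, mode=mode,
                                                 seed=seed))
    ctf = geo.flat_types()
    n_layer = nx * ny
    watch = np.arange((block[1] + 1) * n_layer, nz * n_layer)
    watch = watch[ctf[watch] == CM]
    cfg = sm.SimulationConfig(duration_ms=duration_ms,
                              record_every_ms=record_every_ms,
                              watch_cells=watch, stop_on_watch_fraction=0.95,
                              stagnation_ms=stagnation_ms)
    cfp = cf_params if cf_params is not None else im.CFParams()
    cfp = replace(cfp, g_Na=g_na)
    res = sm.run(geo, sm.StimulusProtocol(amplitude_pA=stim_amplitude_pA),
                 cfg, cf_params=cfp, cm_params=cm_params)
    amap = activation_map(res)
    ok = classify_conduction(amap, geo)
    delay = center_block_delay(amap, geo) if ok else None
    layer_act = np.array([np.nanmean(res.act_time[z * n_layer:(z + 1) * n_layer])
                          for z in range(nz)])
    return res, ConductionSummary(success=ok, delay_ms=delay,
                                  layer_activation=layer_act, g_na=g_na,
                                  sigma=sigma, seed=seed)


def find_gna_threshold(lo: float, hi: float, resolution: float = 0.05,
                       runner=None, **kwargs) -> float:
    """Smallest conducting g_Na (nS) by bisection to ``resolution``.

    ``runner(g)`` must return True on conduction success; by default it is
    :func:`run_cf_center` on the baseline CF-centre tissue.  Raises if the
    endpoints do not bracket (lo must fail, hi must conduct).
    """
    if runner is None:
        def runner(g):
            return run_cf_center(g, **kwargs)[1].success
    if runner(lo):
        raise ValueError(f"g_Na = {lo} nS already conducts; lower `lo`")
    if not runner(hi):
        raise ValueError(f"g_Na = {hi} nS does not conduct; raise `hi`")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if runner(mid):
            hi = mid
        else:
            lo = mid
    return hi


def sweep_gna(g_values, sigma: float = 3.0, seed: int = 1,
              **kwargs) -> list[SweepPoint]:
    """Classification plus centre-block delay across a g_Na grid."""
    out = []
    for g in g_values:
        _, summ = run_cf_center(float(g), sigma=sigma, seed=seed, **kwargs)
        out.append(SweepPoint(float(g), sigma, seed, summ.success,
                              summ.delay_ms, kwargs.get("mode", "shoulder")))
    return out


def sigma_conduction_window(sigmas, g_na: float, seeds=(1, 2, 3, 4, 5),
                            majority: float = 0.5, collect_delays: bool = True,
                            **kwargs):
    """Majority-vote conduction window over a sigma grid.

    For each sigma, runs one simulation per seed (random CF placement) and
    records the majority classification; evaluation of the remaining seeds
    stops once the majority is decided.  Returns
    ``(first_sigma, last_sigma, points)`` where the edges are the smallest
    and largest sigma with majority success (None if no sigma conducts).
    """
    points: list[SweepPoint] = []
    votes: dict[float, bool] = {}
    for s in sigmas:
        n_needed = len(seeds) // 2 + 1
        succ = fail = 0
        delays = []
        for seed in seeds:
            _, summ = run_cf_center(g_na, sigma=float(s), seed=int(seed),
                                    **kwargs)
            points.append(SweepPoint(g_na, float(s), int(seed), summ.success,
                                     summ.delay_ms, kwargs.get("mode",
                                                               "shoulder")))
            if summ.success:
                succ += 1
                if summ.delay_ms is not None:
                    delays.append(summ.delay_ms)
            else:
                fail += 1
            if succ >= n_needed or fail >= n_needed:
                break
        votes[float(s)] = succ >= n_needed
    conducting = [s for s, ok in votes.items() if ok]
    if not conducting:
        return None, None, points
    return min(conducting), max(conducting), points
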