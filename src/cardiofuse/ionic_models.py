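"""Single-cell ionic models.

Two cell types are modelled:

* **Cardiomyocyte (CM)** — the Luo-Rudy 1991 guinea-pig ventricular action
  potential model: fast sodium current ``I_Na``, slow inward (L-type calcium)
  current ``I_si`` with a minimal intracellular Ca pool, time-dependent
  potassium current ``I_K``, inward rectifier ``I_K1``, plateau potassium
  current ``I_Kp`` and a linear background current ``I_b``.  Six
  Hodgkin-Huxley gates (m, h, j, d, f, X) plus intracellular calcium.

* **Cardiac fibroblast (CF)** — the MacCannell "active" fibroblast model
  (time/voltage-dependent Kv current with activation ``r`` and inactivation
  ``s``, inward-rectifier ``I_K1``, Na/K pump, sodium background current,
  dynamic intracellular K+), extended with two voltage-gated sodium
  currents: a TTX-resistant current ``I_Na,TR`` with Luo-Rudy m/h/j kinetics
  and a TTX-sensitive current ``I_Na,TS`` in GHK form that shares the TR
  activation gate m^3 but carries its own slow inactivation gate ``h_TS``.
  The ratio of TS to TR maximal conductance is gamma (default 0.8).

Rate functions are vectorised over membrane potential so that the same code
serves single-cell work, the dense reference stepper, and the construction
of the lookup tables used by the compiled lattice kernel.

Current conventions: the CM model is written in current-density form
(uA/uF); totals are converted to absolute currents (pA) via the membrane
capacitance (uA/uF == pA/pF).  The added CF sodium currents are absolute
(nS x mV = pA).  Outward currents are positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

FARADAY = 96485.332  # C/mol
R_GAS = 8.314462     # J/(mol K)

__all__ = [
    "CMParams", "CMState", "CFParams", "CFState",
    "cm_gate_kinetics", "cm_ionic_current",
    "cf_gate_kinetics", "cf_ionic_current", "cf_base_current_density",
    "i_na_tr", "i_na_ts", "ghk_voltage_factor",
    "rush_larsen_update", "settle_to_rest",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class CMParams:
    """Luo-Rudy 1991 parameters (conductances in mS/cm^2 == uA/uF per mV)."""

    g_Na: float = 23.0
    g_si: float = 0.09
    g_K: float = 0.282          # scaled by sqrt(K_o/5.4)
    g_K1: float = 0.6047        # scaled by sqrt(K_o/5.4)
    g_Kp: float = 0.0183
    g_b: float = 0.03921
    E_Na: float = 54.4          # mV
    E_K: float = -77.0          # mV
    E_b: float = -59.87         # mV
    K_o: float = 5.4            # mM
    K_i: float = 145.0          # mM
    T: float = 310.0            # K (Nernst for E_K1/E_Kp)
    C: float = 63.0             # pF, whole-cell capacitance

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("capacitance must be positive")
        if min(self.g_Na, self.g_si, self.g_K, self.g_K1, self.g_Kp, self.g_b) < 0:
            raise ValueError("conductances must be nonnegative")

    @property
    def E_K1(self) -> float:
        return R_GAS * self.T / FARADAY * 1e3 * np.log(self.K_o / self.K_i)

    @property
    def E_Kp(self) -> float:
        return self.E_K1

    @property
    def sqrt_Ko(self) -> float:
        return float(np.sqrt(self.K_o / 5.4))


@dataclass
class CMState:
    V: float = -84.5
    m: float = 0.0017
    h: float = 0.983
    j: float = 0.989
    d: float = 0.003
    f: float = 0.999
    X: float = 0.0057
    Ca_i: float = 1.8e-4  # mM

    GATES = ("m", "h", "j", "d", "f", "X")

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.m, self.h, self.j, self.d, self.f,
                         self.X, self.Ca_i])

    @classmethod
    def from_array(cls, a) -> "CMState":
        return cls(*[float(x) for x in a])

    def validate(self) -> None:
        a = self.as_array()
        if not np.all(np.isfinite(a)):
            raise FloatingPointError("non-finite CM state (integration blow-up?)")
        gates = a[1:7]
        if np.any(gates < 0) or np.any(gates > 1):
            raise ValueError("CM gates out of [0, 1]")
        if self.Ca_i <= 0:
            raise ValueError("Ca_i must be positive")


@dataclass
class CFParams:
    """MacCannell active fibroblast plus added sodium-current parameters.

    Base-model conductances are in nS/pF; the added sodium conductance
    ``g_Na`` is an absolute whole-cell conductance in nS and ``gamma`` the
    ratio of TS to TR maximal conductance.
    """

    g_Na: float = 0.0           # nS (I_Na,TR maximal conductance)
    gamma: float = 0.8          # I_Na,TS / I_Na,TR conductance ratio
    Na_o: float = 140.0         # mM (Tyrode: 140 NaCl)
    Na_i: float = 8.5547        # mM, fixed intracellular sodium
    K_o: float = 5.4            # mM
    T: float = 308.15           # K (35 C bath)
    g_Kv: float = 0.25          # nS/pF
    g_K1: float = 0.4822        # nS/pF
    g_bNa: float = 0.0095       # nS/pF
    I_NaK_max: float = 2.002    # pA/pF
    K_mK: float = 1.0           # mM
    K_mNa: float = 11.0         # mM
    V_rev: float = -150.0       # mV, Na/K pump linearisation
    B_NaK: float = -200.0       # mV
    vol: float = 1.37e-12       # L, cytosolic volume
    C: float = 6.3              # pF
    ts_prefactor: float = 40.0  # dimensionless GHK prefactor of I_Na,TS

    def __post_init__(self) -> None:
        if self.g_Na < 0 or self.gamma < 0:
            raise ValueError("g_Na and gamma must be nonnegative")
        if self.T <= 0 or self.Na_o <= 0:
            raise ValueError("T and Na_o must be positive")

    @property
    def rtf(self) -> float:
        """Thermal voltage RT/F in mV."""
        return R_GAS * self.T / FARADAY * 1e3

    @property
    def E_Na(self) -> float:
        """CF sodium reversal potential (mV), Nernst from Na_o/Na_i."""
        return self.rtf * np.log(self.Na_o / self.Na_i)

    def nak_scale(self) -> float:
        na15 = self.Na_i ** 1.5
        return (self.I_NaK_max * self.K_o / (self.K_o + self.K_mK)
                * na15 / (na15 + self.K_mNa ** 1.5))


@dataclass
class CFState:
    V: float = -49.6
    r: float = 0.06              # Kv activation
    s: float = 0.99              # Kv inactivation
    K_i: float = 129.4           # mM
    m_TR: float = 0.0
    h_TR: float = 1.0
    j_TR: float = 1.0
    h_TS: float = 1.0

    GATES = ("r", "s", "m_TR", "h_TR", "j_TR", "h_TS")

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.r, self.s, self.K_i, self.m_TR,
                         self.h_TR, self.j_TR, self.h_TS])

    @classmethod
    def from_array(cls, a) -> "CFState":
        return cls(*[float(x) for x in a])

    def validate(self) -> None:
        a = self.as_array()
        if not np.all(np.isfinite(a)):
            raise FloatingPointError("non-finite CF state (integration blow-up?)")
        gates = np.array([self.r, self.s, self.m_TR, self.h_TR, self.j_TR,
                          self.h_TS])
        if np.any(gates < 0) or np.any(gates > 1):
            raise ValueError("CF gates out of [0, 1]")
        if self.K_i <= 0:
            raise ValueError("K_i must be positive")


# ---------------------------------------------------------------------------
# Luo-Rudy 1991 kinetics
# ---------------------------------------------------------------------------

def _safe_ratio(num, den, limit):
    """num/den with a supplied analytic value where den ~ 0."""
    den = np.asarray(den, dtype=float)
    small = np.abs(den) < 1e-12
    out = np.where(small, limit, num / np.where(small, 1.0, den))
    return out


def lr_sodium_rates(V):
    """alpha/beta for the Luo-Rudy m, h, j gates; vectorised over V (mV)."""
    V = np.asarray(V, dtype=float)
    dvm = V + 47.13
    a_m = _safe_ratio(0.32 * dvm, 1.0 - np.exp(-0.1 * dvm), 3.2)
    b_m = 0.08 * np.exp(-V / 11.0)

    low = V < -40.0
    a_h = np.where(low, 0.135 * np.exp(-(80.0 + V) / 6.8), 0.0)
    b_h = np.where(
        low,
        3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V),
        1.0 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1))),
    )
    with np.errstate(over="ignore"):
        a_j_low = ((-1.2714e5 * np.exp(0.2444 * V)
                    - 3.474e-5 * np.exp(-0.04391 * V))
                   * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23))))
    a_j = np.where(low, a_j_low, 0.0)
    b_j = np.where(
        low,
        0.1212 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14))),
        0.3 * np.exp(-2.535e-7 * V) / (1.0 + np.exp(-0.1 * (V + 32.0))),
    )
    return (a_m, b_m), (a_h, b_h), (a_j, b_j)


def cm_gate_kinetics(V):
    """Steady states and time constants (ms) of the six LR91 gates.

    Returns two (6, ...) arrays, rows ordered (m, h, j, d, f, X).
    """
    V = np.asarray(V, dtype=float)
    (a_m, b_m), (a_h, b_h), (a_j, b_j) = lr_sodium_rates(V)

    a_d = 0.095 * np.exp(-0.01 * (V - 5.0)) / (1.0 + np.exp(-0.072 * (V - 5.0)))
    b_d = 0.07 * np.exp(-0.017 * (V + 44.0)) / (1.0 + np.exp(0.05 * (V + 44.0)))
    a_f = 0.012 * np.exp(-0.008 * (V + 28.0)) / (1.0 + np.exp(0.15 * (V + 28.0)))
    b_f = 0.0065 * np.exp(-0.02 * (V + 30.0)) / (1.0 + np.exp(-0.2 * (V + 30.0)))
    a_X = 0.0005 * np.exp(0.083 * (V + 50.0)) / (1.0 + np.exp(0.057 * (V + 50.0)))
    b_X = 0.0013 * np.exp(-0.06 * (V + 20.0)) / (1.0 + np.exp(-0.04 * (V + 20.0)))

    inf = []
    tau = []
    for a, b in ((a_m, b_m), (a_h, b_h), (a_j, b_j), (a_d, b_d), (a_f, b_f),
                 (a_X, b_X)):
        s = a + b
        inf.append(a / s)
        tau.append(1.0 / s)
    return np.stack(inf), np.stack(tau)


def lr_xi(V):
    """Rectification factor Xi of the LR91 time-dependent K current."""
    V = np.asarray(V, dtype=float)
    num = np.exp(0.04 * (V + 77.0)) - 1.0
    den = (V + 77.0) * np.exp(0.04 * (V + 35.0))
    near = np.abs(V + 77.0) < 1e-9
    xi = np.where(
        V > -100.0,
        2.837 * _safe_ratio(num, den, 0.0),
        1.0,
    )
    # analytic limit at V = -77
    xi = np.where(near, 2.837 * 0.04 / np.exp(0.04 * (-77.0 + 35.0)), xi)
    return xi


def lr_k1_open(V, E_K1):
    """Steady-state open probability of LR91 I_K1."""
    V = np.asarray(V, dtype=float)
    dv = V - E_K1
    a = 1.02 / (1.0 + np.exp(0.2385 * (dv - 59.215)))
    with np.errstate(over="ignore"):
        b = ((0.49124 * np.exp(0.08032 * (dv + 5.476))
              + np.exp(0.06175 * (dv - 594.31)))
             / (1.0 + np.exp(-0.5143 * (dv + 4.753))))
    return a / (a + b)


def cm_current_density(V, m, h, j, d, f, X, Ca_i, p: CMParams):
    """All LR91 current densities (uA/uF); returns dict of components."""
    V = np.asarray(V, dtype=float)
    E_si = 7.7 - 13.0287 * np.log(Ca_i)
    I_Na = p.g_Na * m ** 3 * h * j * (V - p.E_Na)
    I_si = p.g_si * d * f * (V - E_si)
    I_K = p.g_K * p.sqrt_Ko * X * lr_xi(V) * (V - p.E_K)
    I_K1 = p.g_K1 * p.sqrt_Ko * lr_k1_open(V, p.E_K1) * (V - p.E_K1)
    Kp = 1.0 / (1.0 + np.exp((7.488 - V) / 5.98))
    I_Kp = p.g_Kp * Kp * (V - p.E_Kp)
    I_b = p.g_b * (V - p.E_b)
    total = I_Na + I_si + I_K + I_K1 + I_Kp + I_b
    return {"I_Na": I_Na, "I_si": I_si, "I_K": I_K, "I_K1": I_K1,
            "I_Kp": I_Kp, "I_b": I_b, "total": total}


def cm_ionic_current(state: CMState, params: CMParams | None = None):
    """Total CM ionic current (pA, outward positive) plus gate kinetics.

    Returns ``(I_ion_pA, (gate_inf, gate_tau))`` with gates ordered
    (m, h, j, d, f, X), suitable for a Rush-Larsen update.
    """
    params = params or CMParams()
    state.validate()
    cur = cm_current_density(state.V, state.m, state.h, state.j, state.d,
                             state.f, state.X, state.Ca_i, params)
    inf, tau = cm_gate_kinetics(state.V)
    return float(cur["total"]) * params.C, (inf, tau)


def cm_ca_derivative(I_si, Ca_i):
    """LR91 calcium pool: dCa/dt (mM/ms)."""
    return -1e-4 * I_si + 0.07 * (1e-4 - Ca_i)


# ---------------------------------------------------------------------------
# MacCannell fibroblast kinetics + added sodium currents
# ---------------------------------------------------------------------------

def cf_kv_kinetics(V):
    """Steady states / time constants (ms) of the Kv gates r (act), s (inact)."""
    V = np.asarray(V, dtype=float)
    r_inf = 1.0 / (1.0 + np.exp(-(V + 20.0) / 11.0))
    s_inf = 1.0 / (1.0 + np.exp((V + 23.0) / 7.0))
    tau_r = 20.3 + 138.0 * np.exp(-(((V + 20.0) / 25.9) ** 2))
    tau_s = 1574.0 + 5268.0 * np.exp(-(((V + 23.0) / 22.7) ** 2))
    return (r_inf, tau_r), (s_inf, tau_s)


def cf_hts_kinetics(V):
    """Slow TTX-sensitive inactivation gate h_TS: steady state and tau (ms)."""
    V = np.asarray(V, dtype=float)
    h_inf = 1.0 / (1.0 + np.exp((V + 66.1) / 6.4))
    with np.errstate(over="ignore"):
        tau = (3.186e-5 * np.exp(-0.6219 * (V + 18.8))
               / (1.0 + 7.189e-5 * np.exp(-0.6683 * (V + 34.07)))) * 1e3 + 3.556
    return h_inf, np.minimum(tau, 1e5)


def cf_k1_open(x):
    """CF inward-rectifier open fraction as a function of x = V - E_K (mV)."""
    x = np.asarray(x, dtype=float)
    a = 0.1 / (1.0 + np.exp(0.06 * (x - 200.0)))
    with np.errstate(over="ignore"):
        b = ((3.0 * np.exp(0.0002 * (x + 100.0)) + np.exp(0.1 * (x - 10.0)))
             / (1.0 + np.exp(-0.5 * x)))
    return a / (a + b)


def cf_gate_kinetics(V):
    """Steady states and taus of all six CF gates: (r, s, m_TR, h_TR, j_TR, h_TS)."""
    (r_inf, tau_r), (s_inf, tau_s) = cf_kv_kinetics(V)
    (a_m, b_m), (a_h, b_h), (a_j, b_j) = lr_sodium_rates(V)
    hts_inf, hts_tau = cf_hts_kinetics(V)
    inf = np.stack([r_inf, s_inf, a_m / (a_m + b_m), a_h / (a_h + b_h),
                    a_j / (a_j + b_j), hts_inf])
    tau = np.stack([tau_r, tau_s, 1.0 / (a_m + b_m), 1.0 / (a_h + b_h),
                    1.0 / (a_j + b_j), hts_tau])
    return inf, tau


def ghk_voltage_factor(V, params: CFParams):
    """GHK driving-force factor xi(V) of I_Na,TS, in mV.

    xi(V) = V (e^(u(V-E_Na)) - 1) / (e^(uV) - 1), u = F/RT per mV.  The 0/0
    singularity at V = 0 is replaced by its analytic limit
    (e^(-u E_Na) - 1)/u on |V| < 1e-6 mV.  Zero exactly at V = E_Na.
    """
    V = np.asarray(V, dtype=float)
    u = 1.0 / params.rtf
    num = np.exp(u * (V - params.E_Na)) - 1.0
    den = np.exp(u * V) - 1.0
    limit = (np.exp(-u * params.E_Na) - 1.0) / u
    small = np.abs(V) < 1e-6
    out = np.where(small, limit,
                   V * num / np.where(small, 1.0, den))
    return out


def i_na_tr(V, m, h, j, params: CFParams):
    """TTX-resistant sodium current (pA): g_Na m^3 h j (V - E_Na,CF)."""
    gates = np.asarray([m, h, j], dtype=float)
    if np.any(gates < 0) or np.any(gates > 1):
        raise ValueError("gates out of [0, 1]")
    return params.g_Na * m ** 3 * h * j * (np.asarray(V, float) - params.E_Na)


def ts_ghk_prefactor(params: CFParams) -> float:
    """Dimensionless prefactor of the GHK-form I_Na,TS.

    The permeability form of the TS current carries a physical constant
    F^2 [Na]o / RT that has no unique value once the maximal "conductance"
    g_Na is expressed in nS: depending on the unit system chosen for
    [Na]o it spans three orders of magnitude.  The model therefore
    absorbs it into a single dimensionless prefactor (scaled by the
    relative extracellular sodium so the GHK concentration dependence is
    kept).  Its default, 40, is fixed by requiring the baseline CF-centre
    tissue to reproduce the published operating points of the added
    sodium conductance: conduction failure at g_Na = 0.1 nS and success
    at g_Na = 0.6 nS, which centres the conduction threshold within that
    bracket.  The TS current is g_Na*gamma*m^3*h_TS times this factor
    times the driving-force function xi(V) (mV), in pA for g_Na in nS.
    """
    return params.ts_prefactor * (params.Na_o / 140.0)


def i_na_ts(V, m, h_TS, params: CFParams):
    """TTX-sensitive sodium current (pA), GHK form sharing m_TR^3.

    I_TS = g_Na * gamma * F^2/RT * m^3 * h_TS * [Na]o
           * (e^((V-E_Na)F/RT) - 1)/(e^(VF/RT) - 1) * V,
    zero exactly at V = E_Na,CF, continuous through V = 0 via the analytic
    limit (see :func:`ghk_voltage_factor`).
    """
    gates = np.asarray([m, h_TS], dtype=float)
    if np.any(gates < 0) or np.any(gates > 1):
        raise ValueError("gates out of [0, 1]")
    return (params.g_Na * params.gamma * m ** 3 * h_TS
            * ts_ghk_prefactor(params) * ghk_voltage_factor(V, params))


def cf_base_current_density(V, r, s, K_i, p: CFParams):
    """MacCannell base-model current densities (pA/pF); dict of components."""
    V = np.asarray(V, dtype=float)
    E_K = p.rtf * np.log(p.K_o / K_i)
    I_Kv = p.g_Kv * r * s * (V - E_K)
    I_K1 = p.g_K1 * cf_k1_open(V - E_K) * (V - E_K)
    I_NaK = p.nak_scale() * (V - p.V_rev) / (V - p.B_NaK)
    I_bNa = p.g_bNa * (V - p.E_Na)
    total = I_Kv + I_K1 + I_NaK + I_bNa
    return {"I_Kv": I_Kv, "I_K1": I_K1, "I_NaK": I_NaK, "I_bNa": I_bNa,
            "total": total}


def cf_ionic_current(state: CFState, params: CFParams | None = None):
    """Total CF ionic current (pA, outward positive) plus gate kinetics.

    I_CF,total = I_Kv + I_K1 + I_NaK + I_bNa + I_Na,CF with
    I_Na,CF = I_Na,TR + I_Na,TS.  With g_Na = 0 the sum reduces exactly to
    the base fibroblast model.  Returns ``(I_pA, (gate_inf, gate_tau))``
    with gates ordered (r, s, m_TR, h_TR, j_TR, h_TS).
    """
    params = params or CFParams()
    state.validate()
    base = cf_base_current_density(state.V, state.r, state.s, state.K_i, params)
    i_na = (i_na_tr(state.V, state.m_TR, state.h_TR, state.j_TR, params)
            + i_na_ts(state.V, state.m_TR, state.h_TS, params))
    total = float(base["total"]) * params.C + float(i_na)
    inf, tau = cf_gate_kinetics(state.V)
    return total, (inf, tau)


def cf_ki_derivative(I_Kv, I_K1, I_NaK, p: CFParams):
    """dK_i/dt (mM/ms) from the K-carrying densities (pA/pF)."""
    i_k_pA = (I_Kv + I_K1 - 2.0 * I_NaK) * p.C
    # pA -> mol/s is 1e-12/F; /vol(L) gives M/s, numerically equal to mM/ms
    return -i_k_pA * 1e-12 / (FARADAY * p.vol)


# ---------------------------------------------------------------------------
# integration helpers
# ---------------------------------------------------------------------------

def rush_larsen_update(y, y_inf, tau, dt):
    """Exponential (Rush-Larsen) gate update.

    y' = y_inf - (y_inf - y) exp(-dt/tau).  Unconditionally stays within
    [min(y, y_inf), max(y, y_inf)], hence in [0, 1] for gating variables.
    """
    if np.any(np.asarray(tau) <= 0):
        raise ValueError("tau must be positive")
    if np.any(np.asarray(dt) <= 0):
        raise ValueError("dt must be positive")
    return y_inf - (y_inf - y) * np.exp(-dt / tau)


def _cm_rhs(t, y, p: CMParams, i_stim_density=0.0):
    V, m, h, j, d, f, X, Ca = y
    m, h, j, d, f, X = np.clip([m, h, j, d, f, X], 0.0, 1.0)
    Ca = max(Ca, 1e-8)
    cur = cm_current_density(V, m, h, j, d, f, X, Ca, p)
    inf, tau = cm_gate_kinetics(V)
    dV = -(cur["total"] - i_stim_density)
    dgates = (inf - np.array([m, h, j, d, f, X])) / tau
    dCa = cm_ca_derivative(cur["I_si"], Ca)
    return np.concatenate([[dV], dgates, [dCa]])


def _cf_rhs(t, y, p: CFParams, i_stim_density=0.0):
    V, r, s, K_i, m, hTR, jTR, hTS = y
    # implicit solvers may probe gates marginally outside [0, 1]
    r, s, m, hTR, jTR, hTS = np.clip([r, s, m, hTR, jTR, hTS], 0.0, 1.0)
    base = cf_base_current_density(V, r, s, K_i, p)
    i_na = i_na_tr(V, m, hTR, jTR, p) + i_na_ts(V, m, hTS, p)
    total_density = base["total"] + i_na / p.C
    dV = -(total_density - i_stim_density)
    inf, tau = cf_gate_kinetics(V)
    gates = np.array([r, s, m, hTR, jTR, hTS])
    dgates = (inf - gates) / tau
    dKi = cf_ki_derivative(base["I_Kv"], base["I_K1"], base["I_NaK"], p)
    return np.concatenate([[dV], dgates[:2], [dKi], dgates[2:]])


def settle_to_rest(model: str, params=None, duration: float = 10_000.0,
                   state=None, tol: float = 1e-3):
    """Integrate a single unstimulated cell to its resting state.

    Parameters
    ----------
    model : "CM" or "CF"
    duration : ms of unstimulated integration (default 10 s).
    tol : warn if max |dV/dt| at the end exceeds this (mV/ms).

    Returns the settled state (CMState or CFState).  Uses a stiff implicit
    solver; the endpoint is the same resting fixed point the explicit
    lattice scheme relaxes to.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    model = model.upper()
    if model == "CM":
        p = params or CMParams()
        y0 = (state or CMState()).as_array()
        sol = solve_ivp(_cm_rhs, (0.0, duration), y0, args=(p,),
                        method="BDF", rtol=1e-8, atol=1e-10)
        out = CMState.from_array(sol.y[:, -1])
        resid = abs(_cm_rhs(0.0, out.as_array(), p)[0])
    elif model == "CF":
        p = params or CFParams()
        y0 = (state or CFState()).as_array()
        sol = solve_ivp(_cf_rhs, (0.0, duration), y0, args=(p,),
                        method="BDF", rtol=1e-8, atol=1e-10)
        out = CFState.from_array(sol.y[:, -1])
        resid = abs(_cf_rhs(0.0, out.as_array(), p)[0])
    else:
        raise ValueError(f"unknown model {model!r}")
    if resid > tol:
        warnings.warn(
            f"{model} settle_to_rest residual |dV/dt| = {resid:.3g} mV/ms "
            f"after {duration} ms", stacklevel=2)
    return out
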