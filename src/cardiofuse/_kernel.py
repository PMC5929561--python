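"""Compiled monodomain stepping kernel.

Forward Euler on membrane potentials, Rush-Larsen on gates, synchronous
update over the whole lattice.  All voltage-dependent quantities (gate
steady states, Rush-Larsen decay factors, voltage-only current sums, the
GHK driving-force factor) are tabulated on a fine voltage grid (0.05 mV)
and linearly interpolated, which removes per-step transcendental calls.

Cells that have been voltage-quiet for a while are put to sleep: their
state is frozen and only their gap-junction input is monitored; a change
of that input beyond ``wake_tol`` (pA) wakes them.  This leaves wavefront
dynamics untouched (the scheme is synchronous and reads only old voltages)
while skipping the ionic evaluation of far-field resting tissue.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from . import ionic_models as im

VMIN, VMAX, DV = -150.0, 100.0, 0.05
XK1MIN, XK1MAX = -150.0, 300.0

# scalar-parameter vector layout (per cell type); see build_params
CMP_ENA, CMP_EK, CMP_GNA, CMP_GSI, CMP_GKXI_UNUSED, CMP_CAP = range(6)
(CFP_GNA, CFP_GAMMA, CFP_NASCALE, CFP_ENA, CFP_RTF, CFP_KO, CFP_GKV,
 CFP_GK1, CFP_GBNA, CFP_KNAK, CFP_VREV, CFP_BNAK, CFP_KICONV, CFP_CAP) = range(14)


def build_tables(dt_ms: float, cm_params: im.CMParams, cf_params: im.CFParams):
    """Voltage lookup tables for one time step size.

    Returns (cm_tab, cf_tab, k1_tab).  Gate columns hold A = inf*(1-rl) and
    B = rl = exp(-dt/tau) so the update is y' = A + B*y.
    """
    V = np.arange(VMIN, VMAX + DV / 2, DV)

    inf, tau = im.cm_gate_kinetics(V)
    rl = np.exp(-dt_ms / tau)
    cm_tab = np.empty((V.size, 14), dtype=np.float64)
    cm_tab[:, 0:12:2] = (inf * (1.0 - rl)).T
    cm_tab[:, 1:12:2] = rl.T
    p = cm_params
    k1 = p.g_K1 * p.sqrt_Ko * im.lr_k1_open(V, p.E_K1) * (V - p.E_K1)
    kp = p.g_Kp / (1.0 + np.exp((7.488 - V) / 5.98)) * (V - p.E_Kp)
    ib = p.g_b * (V - p.E_b)
    cm_tab[:, 12] = k1 + kp + ib
    cm_tab[:, 13] = p.g_K * p.sqrt_Ko * im.lr_xi(V)

    finf, ftau = im.cf_gate_kinetics(V)
    frl = np.exp(-dt_ms / ftau)
    cf_tab = np.empty((V.size, 14), dtype=np.float64)
    cf_tab[:, 0:12:2] = (finf * (1.0 - frl)).T
    cf_tab[:, 1:12:2] = frl.T
    cf_tab[:, 12] = im.ghk_voltage_factor(V, cf_params)
    cf_tab[:, 13] = 0.0

    x = np.arange(XK1MIN, XK1MAX + DV / 2, DV)
    k1_tab = im.cf_k1_open(x) * x
    return cm_tab, cf_tab, k1_tab


def build_params(cm_params: im.CMParams, cf_params: im.CFParams):
    cmp_ = np.zeros(6)
    cmp_[CMP_ENA] = cm_params.E_Na
    cmp_[CMP_EK] = cm_params.E_K
    cmp_[CMP_GNA] = cm_params.g_Na
    cmp_[CMP_GSI] = cm_params.g_si
    cmp_[CMP_CAP] = cm_params.C

    q = cf_params
    cfp = np.zeros(14)
    cfp[CFP_GNA] = q.g_Na
    cfp[CFP_GAMMA] = q.gamma
    cfp[CFP_NASCALE] = im.ts_ghk_prefactor(q)
    cfp[CFP_ENA] = q.E_Na
    cfp[CFP_RTF] = q.rtf
    cfp[CFP_KO] = q.K_o
    cfp[CFP_GKV] = q.g_Kv
    cfp[CFP_GK1] = q.g_K1
    cfp[CFP_GBNA] = q.g_bNa
    cfp[CFP_KNAK] = q.nak_scale()
    cfp[CFP_VREV] = q.V_rev
    cfp[CFP_BNAK] = q.B_NaK
    cfp[CFP_KICONV] = q.C * 1e-12 / (im.FARADAY * q.vol)
    cfp[CFP_CAP] = q.C
    return cmp_, cfp


@njit(cache=True)
def _interp(tab, col, idx, w):
    return tab[idx, col] * (1.0 - w) + tab[idx + 1, col] * w


@njit(cache=True)
def run_chunk(V, Vnew, G, aux, ct, cap, nbr_idx, nbr_g,
              cm_tab, cf_tab, k1_tab, cmp_, cfp,
              dt, step0, nsteps,
              stim_amp, stim_dur_steps, stim_period_steps, stim_count,
              act_phase, act_t, act_dvmax,
              quiet, asleep, sleep_gap, sleep_enabled, wake_tol,
              quiet_dv, quiet_steps,
              rec_idx, rec_buf, layer_of, layer_inv_cnt, layer_buf, rec_stride):
    """Advance ``nsteps`` steps from global step ``step0``.  Returns status
    (0 ok, 1 non-finite voltage) and the global step reached."""
    n = V.shape[0]
    inv_dv = 1.0 / DV
    nv_max = cm_tab.shape[0] - 2
    nx1_max = k1_tab.shape[0] - 2

    for s in range(nsteps):
        gstep = step0 + s
        # stimulus window
        ph = gstep % stim_period_steps
        pulse_no = gstep // stim_period_steps
        stim_on = (ph < stim_dur_steps) and (pulse_no < stim_count)
        t_next = (gstep + 1) * dt

        for i in range(n):
            v = V[i]
            gap = 0.0
            for b in range(6):
                k = nbr_idx[i, b]
                if k >= 0:
                    gap += nbr_g[i, b] * (V[k] - v)
            st = stim_amp[i] if stim_on else 0.0

            if sleep_enabled and asleep[i] == 1:
                if abs(gap - sleep_gap[i]) > wake_tol or st != 0.0:
                    asleep[i] = 0
                    quiet[i] = 0
                else:
                    Vnew[i] = v
                    continue

            vc = v
            if vc < VMIN:
                vc = VMIN
            elif vc > VMAX - DV:
                vc = VMAX - DV
            u = (vc - VMIN) * inv_dv
            i0 = int(u)
            if i0 > nv_max:
                i0 = nv_max
            w = u - i0

            if ct[i] == 0:
                # --- cardiomyocyte (Luo-Rudy 1991) ---
                # currents are evaluated at the old state; gates then take
                # their Rush-Larsen update (synchronous scheme)
                m = G[i, 0]
                h = G[i, 1]
                jj = G[i, 2]
                d = G[i, 3]
                f = G[i, 4]
                xg = G[i, 5]
                G[i, 0] = cm_tab[i0, 0] * (1.0 - w) + cm_tab[i0 + 1, 0] * w \
                    + (cm_tab[i0, 1] * (1.0 - w) + cm_tab[i0 + 1, 1] * w) * m
                G[i, 1] = cm_tab[i0, 2] * (1.0 - w) + cm_tab[i0 + 1, 2] * w \
                    + (cm_tab[i0, 3] * (1.0 - w) + cm_tab[i0 + 1, 3] * w) * h
                G[i, 2] = cm_tab[i0, 4] * (1.0 - w) + cm_tab[i0 + 1, 4] * w \
                    + (cm_tab[i0, 5] * (1.0 - w) + cm_tab[i0 + 1, 5] * w) * jj
                G[i, 3] = cm_tab[i0, 6] * (1.0 - w) + cm_tab[i0 + 1, 6] * w \
                    + (cm_tab[i0, 7] * (1.0 - w) + cm_tab[i0 + 1, 7] * w) * d
                G[i, 4] = cm_tab[i0, 8] * (1.0 - w) + cm_tab[i0 + 1, 8] * w \
                    + (cm_tab[i0, 9] * (1.0 - w) + cm_tab[i0 + 1, 9] * w) * f
                G[i, 5] = cm_tab[i0, 10] * (1.0 - w) + cm_tab[i0 + 1, 10] * w \
                    + (cm_tab[i0, 11] * (1.0 - w) + cm_tab[i0 + 1, 11] * w) * xg
                ca = aux[i]
                e_si = 7.7 - 13.0287 * np.log(ca)
                i_si = cmp_[CMP_GSI] * d * f * (v - e_si)
                i_na = cmp_[CMP_GNA] * m * m * m * h * jj * (v - cmp_[CMP_ENA])
                gkxi = cm_tab[i0, 13] * (1.0 - w) + cm_tab[i0 + 1, 13] * w
                i_k = gkxi * xg * (v - cmp_[CMP_EK])
                i_pass = cm_tab[i0, 12] * (1.0 - w) + cm_tab[i0 + 1, 12] * w
                dens = i_na + i_si + i_k + i_pass
                ca_new = ca + dt * (-1e-4 * i_si + 0.07 * (1e-4 - ca))
                aux[i] = ca_new if ca_new > 1e-8 else 1e-8
                i_ion = dens * cap[i]
            else:
                # --- fibroblast (MacCannell + I_Na,TR + I_Na,TS) ---
                r = G[i, 0]
                sg = G[i, 1]
                m = G[i, 2]
                h = G[i, 3]
                jj = G[i, 4]
                hts = G[i, 5]
                G[i, 0] = cf_tab[i0, 0] * (1.0 - w) + cf_tab[i0 + 1, 0] * w \
                    + (cf_tab[i0, 1] * (1.0 - w) + cf_tab[i0 + 1, 1] * w) * r
                G[i, 1] = cf_tab[i0, 2] * (1.0 - w) + cf_tab[i0 + 1, 2] * w \
                    + (cf_tab[i0, 3] * (1.0 - w) + cf_tab[i0 + 1, 3] * w) * sg
                G[i, 2] = cf_tab[i0, 4] * (1.0 - w) + cf_tab[i0 + 1, 4] * w \
                    + (cf_tab[i0, 5] * (1.0 - w) + cf_tab[i0 + 1, 5] * w) * m
                G[i, 3] = cf_tab[i0, 6] * (1.0 - w) + cf_tab[i0 + 1, 6] * w \
                    + (cf_tab[i0, 7] * (1.0 - w) + cf_tab[i0 + 1, 7] * w) * h
                G[i, 4] = cf_tab[i0, 8] * (1.0 - w) + cf_tab[i0 + 1, 8] * w \
                    + (cf_tab[i0, 9] * (1.0 - w) + cf_tab[i0 + 1, 9] * w) * jj
                G[i, 5] = cf_tab[i0, 10] * (1.0 - w) + cf_tab[i0 + 1, 10] * w \
                    + (cf_tab[i0, 11] * (1.0 - w) + cf_tab[i0 + 1, 11] * w) * hts
                ki = aux[i]
                e_k = cfp[CFP_RTF] * np.log(cfp[CFP_KO] / ki)
                x = v - e_k
                xc = x
                if xc < XK1MIN:
                    xc = XK1MIN
                elif xc > XK1MAX - DV:
                    xc = XK1MAX - DV
                ux = (xc - XK1MIN) * inv_dv
                j0 = int(ux)
                if j0 > nx1_max:
                    j0 = nx1_max
                wx = ux - j0
                i_k1 = cfp[CFP_GK1] * (k1_tab[j0] * (1.0 - wx) + k1_tab[j0 + 1] * wx)
                i_kv = cfp[CFP_GKV] * r * sg * x
                i_nak = cfp[CFP_KNAK] * (v - cfp[CFP_VREV]) / (v - cfp[CFP_BNAK])
                i_bna = cfp[CFP_GBNA] * (v - cfp[CFP_ENA])
                dens = i_kv + i_k1 + i_nak + i_bna
                ki_new = ki - dt * (i_kv + i_k1 - 2.0 * i_nak) * cfp[CFP_KICONV]
                aux[i] = ki_new if ki_new > 1.0 else 1.0
                m3 = m * m * m
                i_tr = cfp[CFP_GNA] * m3 * h * jj * (v - cfp[CFP_ENA])
                xi = cf_tab[i0, 12] * (1.0 - w) + cf_tab[i0 + 1, 12] * w
                i_ts = cfp[CFP_GNA] * cfp[CFP_GAMMA] * m3 * hts * cfp[CFP_NASCALE] * xi
                i_ion = dens * cfp[CFP_CAP] + i_tr + i_ts

            vn = v + dt * ((-i_ion + gap + st) / cap[i])
            Vnew[i] = vn

            # online activation detection: max dV/dt of the first upstroke
            # after the trace crosses -20 mV
            if act_phase[i] == 0:
                if vn >= -20.0:
                    act_phase[i] = 1
                    act_dvmax[i] = (vn - v) / dt
                    act_t[i] = t_next
            elif act_phase[i] == 1:
                dvdt = (vn - v) / dt
                if dvdt < 0.0:
                    act_phase[i] = 2
                elif dvdt > act_dvmax[i]:
                    act_dvmax[i] = dvdt
                    act_t[i] = t_next

            if sleep_enabled:
                # only diastolic cells may sleep (never the AP plateau)
                vgate = -75.0 if ct[i] == 0 else -40.0
                if abs(vn - v) < quiet_dv and vn < vgate:
                    quiet[i] += 1
                    if quiet[i] >= quiet_steps:
                        asleep[i] = 1
                        sleep_gap[i] = gap
                        quiet[i] = 0
                else:
                    quiet[i] = 0

        # swap buffers (copy: keeps caller's arrays authoritative)
        bad = False
        for i in range(n):
            v = Vnew[i]
            if not np.isfinite(v):
                bad = True
            V[i] = v
        if bad:
            return 1, gstep + 1

        nxt = gstep + 1
        if nxt % rec_stride == 0:
            row = nxt // rec_stride
            if row < rec_buf.shape[0]:
                for c in range(rec_idx.shape[0]):
                    rec_buf[row, c] = V[rec_idx[c]]
                for z in range(layer_buf.shape[1]):
                    layer_buf[row, z] = 0.0
                for i in range(n):
                    layer_buf[row, layer_of[i]] += V[i]
                for z in range(layer_buf.shape[1]):
                    layer_buf[row, z] *= layer_inv_cnt[z]
    return 0, step0 + nsteps
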