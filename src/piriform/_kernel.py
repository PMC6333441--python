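"""Compiled inner loop: implicit (backward-Euler) integration on the tree.

The branched cable system is stiff, so each time step solves the fully
coupled linear system

    (C/dt + G_membrane(t) + G_axial) V(t+dt) = C/dt V(t) + b(t)

by symmetric Gaussian elimination ordered along the tree (children before
parents), which is exact and O(n) per step.  Ionic and synaptic conductances
enter the diagonal implicitly; their gating states and the NMDA magnesium
factor are advanced with the previous step's voltage (staggered update),
which keeps the solve linear while those factors change slowly relative to
dt.

Everything here works in consistent units: mV, ms, µS, nF, nA.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from piriform.biophysics import kdr_rates, ks_steady_tau, na_rates


@njit(cache=True)
def _nmda_gate(v: float) -> float:
    return 1.0 / (1.0 + 0.25 * math.exp(-0.08 * v))


@njit(cache=True)
def run_kernel(
    n_steps: int,
    dt: float,
    parent,  # int64[n] parent compartment (-1 for root/soma)
    g_ax,  # float64[n] axial coupling to parent, µS
    cap,  # float64[n] nF
    g_leak,  # float64[n] µS
    e_rest: float,
    gbar_na,  # float64[n] µS
    gbar_kdr,
    gbar_ks,
    e_na: float,
    e_k: float,
    na_shift: float,
    kdr_shift: float,
    ks_vhalf: float,
    ks_slope: float,
    ks_tau: float,
    chan_comp,  # int64[nc] target compartment per synaptic channel
    chan_e,  # float64[nc] reversal potential
    chan_taur,  # float64[nc] rise time constant (0 = instant)
    chan_taud,  # float64[nc] decay time constant
    chan_norm,  # float64[nc] unit-peak normalization
    chan_is_nmda,  # uint8[nc]
    ev_step,  # int64[ne] event step indices, ascending
    ev_chan,  # int64[ne]
    ev_w,  # float64[ne] conductance weight, µS
    ohmic: bool,
    v_ohmic: float,
    clamp_comp: int,  # -1 = no voltage clamp
    clamp_hold: float,
    g_clamp: float,
    inj_comp: int,  # -1 = no current injection
    inj_amp: float,  # nA
    inj_start: int,  # step index
    inj_end: int,
    rec_idx,  # int64[nr] compartments to record
    v_init,  # float64[n]
):
    n = parent.shape[0]
    nc = chan_comp.shape[0]
    ne = ev_step.shape[0]
    nr = rec_idx.shape[0]

    v = v_init.copy()  # holds the previous step's voltage during assembly

    # gating state at steady state of the initial voltage
    m = np.zeros(n)
    h = np.zeros(n)
    ngate = np.zeros(n)
    s = np.zeros(n)
    for i in range(n):
        if gbar_na[i] > 0.0 or gbar_kdr[i] > 0.0 or gbar_ks[i] > 0.0:
            am, bm, ah, bh = na_rates(v[i], na_shift)
            an, bn = kdr_rates(v[i], kdr_shift)
            s_inf, _ = ks_steady_tau(v[i], ks_vhalf, ks_slope, ks_tau)
            m[i] = am / (am + bm)
            h[i] = ah / (ah + bh)
            ngate[i] = an / (an + bn)
            s[i] = s_inf

    # dual-exponential synaptic state: g = norm-scaled (B - A); single-exp
    # channels use B only
    A = np.zeros(nc)
    B = np.zeros(nc)
    dec_r = np.zeros(nc)
    dec_d = np.zeros(nc)
    for c in range(nc):
        dec_d[c] = math.exp(-dt / chan_taud[c])
        dec_r[c] = math.exp(-dt / chan_taur[c]) if chan_taur[c] > 0.0 else 0.0

    rec_v = np.empty((nr, n_steps + 1))
    clamp_i = np.zeros(n_steps + 1)
    for r in range(nr):
        rec_v[r, 0] = v[rec_idx[r]]
    if clamp_comp >= 0:
        clamp_i[0] = g_clamp * (clamp_hold - v[clamp_comp])

    d = np.empty(n)
    rhs = np.empty(n)
    ptr = 0
    # consume events scheduled for step 0 (active from the first solve)
    while ptr < ne and ev_step[ptr] <= 0:
        c = ev_chan[ptr]
        w = ev_w[ptr] * chan_norm[c]
        if chan_taur[c] > 0.0:
            A[c] += w
        B[c] += w
        ptr += 1

    for k in range(1, n_steps + 1):
        # ---- synaptic channel states -------------------------------------
        for c in range(nc):
            B[c] *= dec_d[c]
            if chan_taur[c] > 0.0:
                A[c] *= dec_r[c]
        while ptr < ne and ev_step[ptr] <= k:
            c = ev_chan[ptr]
            w = ev_w[ptr] * chan_norm[c]
            if chan_taur[c] > 0.0:
                A[c] += w
            B[c] += w
            ptr += 1

        # ---- assemble diagonal and rhs -----------------------------------
        for i in range(n):
            d[i] = cap[i] / dt + g_leak[i]
            rhs[i] = cap[i] / dt * v[i] + g_leak[i] * e_rest

        for c in range(nc):
            g = B[c] - A[c] if chan_taur[c] > 0.0 else B[c]
            if g <= 0.0:
                continue
            if chan_is_nmda[c] == 1:
                if ohmic:
                    g *= _nmda_gate(v_ohmic)
                else:
                    g *= _nmda_gate(v[chan_comp[c]])
            d[chan_comp[c]] += g
            rhs[chan_comp[c]] += g * chan_e[c]

        # ---- voltage-gated channels (staggered gating update) ------------
        for i in range(n):
            if gbar_na[i] > 0.0 or gbar_kdr[i] > 0.0 or gbar_ks[i] > 0.0:
                vi = v[i]
                am, bm, ah, bh = na_rates(vi, na_shift)
                an, bn = kdr_rates(vi, kdr_shift)
                s_inf, s_tau = ks_steady_tau(vi, ks_vhalf, ks_slope, ks_tau)
                inv = 1.0 / (am + bm)
                m[i] = am * inv + (m[i] - am * inv) * math.exp(-dt / inv)
                inv = 1.0 / (ah + bh)
                h[i] = ah * inv + (h[i] - ah * inv) * math.exp(-dt / inv)
                inv = 1.0 / (an + bn)
                ngate[i] = an * inv + (ngate[i] - an * inv) * math.exp(-dt / inv)
                s[i] = s_inf + (s[i] - s_inf) * math.exp(-dt / s_tau)
                g_na = gbar_na[i] * m[i] ** 3 * h[i]
                g_k = gbar_kdr[i] * ngate[i] ** 4 + gbar_ks[i] * s[i]
                d[i] += g_na + g_k
                rhs[i] += g_na * e_na + g_k * e_k

        # ---- clamp and injection -----------------------------------------
        if clamp_comp >= 0:
            d[clamp_comp] += g_clamp
            rhs[clamp_comp] += g_clamp * clamp_hold
        if inj_comp >= 0 and inj_start <= k < inj_end:
            rhs[inj_comp] += inj_amp

        # ---- axial terms and tree-ordered elimination --------------------
        for i in range(1, n):
            d[i] += g_ax[i]
            d[parent[i]] += g_ax[i]
        for i in range(n - 1, 0, -1):
            p = parent[i]
            f = g_ax[i] / d[i]
            d[p] -= f * g_ax[i]
            rhs[p] += f * rhs[i]
        v[0] = rhs[0] / d[0]
        for i in range(1, n):
            v[i] = (rhs[i] + g_ax[i] * v[parent[i]]) / d[i]

        for i in range(n):
            if not math.isfinite(v[i]):
                # divergence: report the step at which integration failed
                return rec_v, clamp_i, k

        for r in range(nr):
            rec_v[r, k] = v[rec_idx[r]]
        if clamp_comp >= 0:
            clamp_i[k] = g_clamp * (clamp_hold - v[clamp_comp])

    return rec_v, clamp_i, 0
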