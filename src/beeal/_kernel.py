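"""Fused fixed-step integration kernel for the AL network.

One compiled loop advances receptors, ORNs, PNs and LNs together over a
chunk of Euler steps.  Receptors are advanced with a precomputed per-step
matrix-exponential propagator (exact for the piecewise-constant
concentrations of a stimulus segment); neurons and synapses use forward
Euler at the global timestep.  Spikes emitted in step t reach postsynaptic
activations in step t+1.

The kernel is jitted with numba when available and falls back to plain
Python otherwise (identical semantics, far slower).  Equivalence with the
modular :mod:`beeal.neurons` step operations is covered by the test suite.

Lateral inhibition uses the circuit structure instead of edge lists: an LN
targets *all* cells outside its glomerulus, so the inhibitory drive onto a
cell in glomerulus g is ``total LN activation − activation of g's LNs``.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco

# per-population parameter vector layout
P_C, P_GL, P_VL, P_VTH, P_VRES, P_GA, P_VA, P_TAUA, P_JUMP, P_A_PA, P_K = range(11)


def pack_params(p) -> np.ndarray:
    """NeuronParams -> flat float64 vector (noise amplitude in pA)."""
    return np.array([
        p.C, p.g_leak, p.V_leak, p.V_th, p.V_reset, p.g_adapt, p.V_adapt,
        p.tau_adapt, p.adapt_jump, 1e3 * p.A, p.k,
    ])


@njit(cache=True)
def advance_chunk(
    n_steps, dt,
    # receptors: propagator (n_glo, m, m), state (n_glo, m), m = 2*n_od + 1
    P, rec_state, n_od,
    # populations: glomerulus labels, state, last-step spike flags
    orn_glo, V_orn, a_orn, s_orn, f_orn,
    pn_glo, V_pn, s_pn, f_pn, fanin_pn,
    ln_glo, V_ln, a_ln, s_ln, f_ln, fanin_ln,
    n_glo,
    # neuron parameter vectors (see pack_params)
    orn_p, pn_p, ln_p,
    # receptor-current calibration (pA per unit activation, before k)
    calib_pA,
    # synapse conductances (nS), reversals (mV), decay taus per pre-pop (s)
    g_op, v_op, g_ol, v_ol, g_pl, v_pl, g_lp, v_lp, g_ll, v_ll,
    tau_s_orn, tau_s_pn, tau_s_ln,
    # per-step standard-normal noise, layout [orn | pn | ln]
    noise,
    # outputs
    spikes_out,           # (n_steps, n_tot) uint8, pre-zeroed
    trace_idx, trace_V,   # global neuron ids; (n_idx, n_steps)
    rsum_out,             # (n_steps, n_glo) or (0, 0)
):
    n_orn = V_orn.shape[0]
    n_pn = V_pn.shape[0]
    n_ln = V_ln.shape[0]
    m = 2 * n_od + 1
    rsum = np.zeros(n_glo)
    S_pn = np.zeros(n_glo)
    S_ln = np.zeros(n_glo)
    tmp = np.zeros(m)
    fan_pn = fanin_pn.shape[1]
    fan_ln = fanin_ln.shape[1]
    store_rsum = rsum_out.shape[0] > 0

    d_orn = 1.0 - dt / tau_s_orn
    d_pn = 1.0 - dt / tau_s_pn
    d_ln = 1.0 - dt / tau_s_ln

    for t in range(n_steps):
        # --- synaptic activations: decay + spikes from previous step
        for i in range(n_orn):
            s_orn[i] = s_orn[i] * d_orn + f_orn[i]
        for i in range(n_pn):
            s_pn[i] = s_pn[i] * d_pn + f_pn[i]
        for i in range(n_ln):
            s_ln[i] = s_ln[i] * d_ln + f_ln[i]

        # --- per-glomerulus activation sums for structural connectivity
        for g in range(n_glo):
            S_pn[g] = 0.0
            S_ln[g] = 0.0
        for i in range(n_pn):
            S_pn[pn_glo[i]] += s_pn[i]
        S_ln_tot = 0.0
        for i in range(n_ln):
            S_ln[ln_glo[i]] += s_ln[i]
            S_ln_tot += s_ln[i]

        # --- receptors: exact propagation over one step
        if n_od > 0:
            for g in range(n_glo):
                for r in range(m):
                    acc = 0.0
                    for q in range(m):
                        acc += P[g, r, q] * rec_state[g, q]
                    tmp[r] = acc
                rs = 0.0
                for r in range(m):
                    rec_state[g, r] = tmp[r]
                    if r > n_od:
                        rs += tmp[r]
                rsum[g] = rs
        if store_rsum:
            for g in range(n_glo):
                rsum_out[t, g] = rsum[g]

        # --- ORNs (receptor current, adaptation, k scale)
        C = orn_p[P_C]; gl = orn_p[P_GL]; Vl = orn_p[P_VL]
        Vth = orn_p[P_VTH]; Vres = orn_p[P_VRES]
        ga = orn_p[P_GA]; Va = orn_p[P_VA]; taua = orn_p[P_TAUA]
        jump = orn_p[P_JUMP]; A_pA = orn_p[P_A_PA]; kk = orn_p[P_K]
        for i in range(n_orn):
            V = V_orn[i]
            a = a_orn[i]
            I = kk * calib_pA * rsum[orn_glo[i]]
            V += dt * (-gl * (V - Vl) - ga * a * (V - Va) + I + A_pA * noise[t, i]) / C
            a -= dt * a / taua
            if V >= Vth:
                V = Vres
                a += jump
                f_orn[i] = 1.0
                spikes_out[t, i] = 1
            else:
                f_orn[i] = 0.0
            V_orn[i] = V
            a_orn[i] = a

        # --- PNs (ORN fan-in excitation + lateral inhibition, no adaptation)
        C = pn_p[P_C]; gl = pn_p[P_GL]; Vl = pn_p[P_VL]
        Vth = pn_p[P_VTH]; Vres = pn_p[P_VRES]
        A_pA = pn_p[P_A_PA]; kk = pn_p[P_K]
        for i in range(n_pn):
            V = V_pn[i]
            ss = 0.0
            for q in range(fan_pn):
                ss += s_orn[fanin_pn[i, q]]
            g = pn_glo[i]
            I = g_op * ss * (v_op - V) + g_lp * (S_ln_tot - S_ln[g]) * (v_lp - V)
            V += dt * (-gl * (V - Vl) + kk * I + A_pA * noise[t, n_orn + i]) / C
            if V >= Vth:
                V = Vres
                f_pn[i] = 1.0
                spikes_out[t, n_orn + i] = 1
            else:
                f_pn[i] = 0.0
            V_pn[i] = V

        # --- LNs (ORN + own-glomerulus PN excitation, lateral inhibition)
        C = ln_p[P_C]; gl = ln_p[P_GL]; Vl = ln_p[P_VL]
        Vth = ln_p[P_VTH]; Vres = ln_p[P_VRES]
        ga = ln_p[P_GA]; Va = ln_p[P_VA]; taua = ln_p[P_TAUA]
        jump = ln_p[P_JUMP]; A_pA = ln_p[P_A_PA]; kk = ln_p[P_K]
        off = n_orn + n_pn
        for i in range(n_ln):
            V = V_ln[i]
            a = a_ln[i]
            ss = 0.0
            for q in range(fan_ln):
                ss += s_orn[fanin_ln[i, q]]
            g = ln_glo[i]
            I = (g_ol * ss * (v_ol - V)
                 + g_pl * S_pn[g] * (v_pl - V)
                 + g_ll * (S_ln_tot - S_ln[g]) * (v_ll - V))
            V += dt * (-gl * (V - Vl) - ga * a * (V - Va) + kk * I
                       + A_pA * noise[t, off + i]) / C
            a -= dt * a / taua
            if V >= Vth:
                V = Vres
                a += jump
                f_ln[i] = 1.0
                spikes_out[t, off + i] = 1
            else:
                f_ln[i] = 0.0
            V_ln[i] = V
            a_ln[i] = a

        # --- membrane-potential traces (post-update values)
        for q in range(trace_idx.shape[0]):
            gid = trace_idx[q]
            if gid < n_orn:
                trace_V[q, t] = V_orn[gid]
            elif gid < off:
                trace_V[q, t] = V_pn[gid - n_orn]
            else:
                trace_V[q, t] = V_ln[gid - off]
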