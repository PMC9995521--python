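"""Adaptive leaky integrate-and-fire neurons and exponential synapses.

Membrane equation (units: nF, nS, mV, nA, s)

    C dV/dt = -g_leak (V - V_leak) - g_adapt a (V - V_adapt) + k I_ext + A xi

with xi ~ N(0,1) drawn per step and held constant over the step (no
sqrt(dt) rescaling; see docs/methods.md for the alternative Euler-Maruyama
scaling).  On crossing threshold (V >= V_th, tested after the Euler update)
the neuron spikes, V resets and the adaptation variable jumps by 0.5;
between spikes a decays with time constant tau_adapt.  The current scale k
rescales the receptor current in ORNs (k=10, one model ORN standing in for
ten biological ones); PNs and LNs use k=1.

Synaptic activation s rises instantaneously by 1 per presynaptic spike and
decays exponentially; the conductance-based current into the postsynaptic
cell is I = g_syn * s * (V_rev - V).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "NeuronParams",
    "SynapseParams",
    "ORN_PARAMS",
    "PN_PARAMS",
    "LN_PARAMS",
    "step_neuron",
    "step_synapse",
    "synaptic_current",
    "rheobase",
    "lif_isi",
]


@dataclass(frozen=True)
class NeuronParams:
    """Adaptive LIF parameters.  Defaults are shared by all populations."""

    C: float = 1.0            # membrane capacitance, nF
    g_leak: float = 10.0      # leak conductance, nS
    V_leak: float = -60.0     # leak reversal, mV
    V_th: float = -40.0       # firing threshold, mV
    V_reset: float = -70.0    # reset potential, mV
    g_adapt: float = 0.0      # adaptation conductance, nS
    V_adapt: float = -70.0    # adaptation reversal, mV (unstated; hyperpolarizing)
    tau_adapt: float = 1.0    # adaptation time constant, s
    adapt_jump: float = 0.5   # increment of a per spike
    A: float = 1.4            # noise current amplitude, nA
    k: float = 1.0            # input-current scale factor

    def __post_init__(self) -> None:
        if self.C <= 0 or self.g_leak <= 0 or self.g_adapt < 0:
            raise ValueError("require C > 0, g_leak > 0, g_adapt >= 0")
        if self.V_reset >= self.V_th:
            raise ValueError("require V_reset < V_th")

    def without_noise(self) -> "NeuronParams":
        return replace(self, A=0.0)


#: Population presets: ORNs carry the k=10 current scale and strong
#: adaptation; LNs adapt weakly; PNs do not adapt.
ORN_PARAMS = NeuronParams(g_adapt=1.5, k=10.0)
PN_PARAMS = NeuronParams(g_adapt=0.0)
LN_PARAMS = NeuronParams(g_adapt=0.5)


@dataclass(frozen=True)
class SynapseParams:
    """Exponential conductance synapse: peak conductance (nS), decay time
    constant (s), reversal potential (mV)."""

    g_syn: float
    tau_syn: float
    V_rev: float

    def __post_init__(self) -> None:
        if self.g_syn < 0:
            raise ValueError("g_syn must be >= 0")
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be > 0")


def step_neuron(V, a, I_ext, params: NeuronParams, dt: float, noise_draw=0.0):
    """One Euler step of the adaptive LIF equation.

    Accepts scalars or aligned arrays for ``V``, ``a``, ``I_ext`` and
    ``noise_draw``; ``I_ext`` is in nA (before the ``k`` scale).  Returns
    ``(V', a', spiked)`` where ``spiked`` is boolean (elementwise for
    arrays).  Spikes are registered at the end-of-step time.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = params
    V = np.asarray(V, dtype=float)
    a = np.asarray(a, dtype=float)
    # currents in pA (nS * mV); expression order mirrors the fused kernel
    I_pA = p.k * (1e3 * np.asarray(I_ext, dtype=float))
    A_pA = 1e3 * p.A
    dV = dt * (-p.g_leak * (V - p.V_leak) - p.g_adapt * a * (V - p.V_adapt)
               + I_pA + A_pA * np.asarray(noise_draw)) / p.C
    V_new = V + dV
    a_new = a - dt * a / p.tau_adapt
    spiked = V_new >= p.V_th
    V_new = np.where(spiked, p.V_reset, V_new)
    a_new = np.where(spiked, a_new + p.adapt_jump, a_new)
    if V_new.ndim == 0:
        return float(V_new), float(a_new), bool(spiked)
    return V_new, a_new, spiked


def step_synapse(s, incoming_spikes, tau_syn: float, dt: float):
    """One Euler step of synaptic activation: exponential decay plus the
    number of presynaptic spikes arriving this step."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return np.asarray(s, dtype=float) * (1.0 - dt / tau_syn) + np.asarray(incoming_spikes)


def synaptic_current(s, V, params: SynapseParams):
    """Conductance-based synaptic current in nA: g_syn s (V_rev − V).

    g_syn in nS and V in mV give pA; converted to nA to match I_ext."""
    return 1e-3 * params.g_syn * np.asarray(s) * (params.V_rev - np.asarray(V))


def rheobase(params: NeuronParams) -> float:
    """Minimal constant current (nA, after the k scale) for repetitive
    firing of the non-adapting, noise-free LIF: g_leak (V_th − V_leak)."""
    return 1e-3 * params.g_leak * (params.V_th - params.V_leak)


def lif_isi(params: NeuronParams, I_ext: float) -> float:
    """Closed-form inter-spike interval (s) of the noise-free, non-adapting
    LIF under constant suprathreshold current I_ext (nA, before k)."""
    p = params
    V_inf = p.V_leak + 1e3 * p.k * I_ext / p.g_leak
    if V_inf <= p.V_th:
        return float("inf")
    tau_m = p.C / p.g_leak
    return tau_m * np.log((V_inf - p.V_reset) / (V_inf - p.V_th))
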