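"""Antennal-lobe network construction.

The honey-bee AL is modelled as ``n_glo`` glomeruli (one per receptor
type).  Each glomerulus contains ``n_orn_per_type`` ORNs (default 60, each
standing in for ~10 biological ORNs via the k=10 current scale), 5 PNs and
25 LNs.  Wiring rules:

* every PN and LN receives excitation from ``fan_in`` (12) ORNs drawn
  without replacement from its own receptor type;
* PNs excite all LNs of their own glomerulus;
* LNs inhibit all PNs and LNs of all *other* glomeruli (all-to-all lateral
  inhibition, never within their own glomerulus).

Synapse parameters (peak conductance nS / decay ms / reversal mV):
ORN->PN 8/10/0, ORN->LN 8/10/0, PN->LN 1/10/0, LN->PN 0.055/20/-80,
LN->LN 0.02/20/-80.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .neurons import LN_PARAMS, ORN_PARAMS, PN_PARAMS, NeuronParams, SynapseParams
from .receptors import ReceptorState

__all__ = ["NetworkSpec", "Network", "build_network", "orn_drive",
           "default_synapses", "CONNECTION_CLASSES"]

CONNECTION_CLASSES = ("orn_pn", "orn_ln", "pn_ln", "ln_pn", "ln_ln")


def default_synapses() -> dict[str, SynapseParams]:
    """Synapse parameter table for the five connection classes."""
    return {
        "orn_pn": SynapseParams(g_syn=8.0, tau_syn=0.010, V_rev=0.0),
        "orn_ln": SynapseParams(g_syn=8.0, tau_syn=0.010, V_rev=0.0),
        "pn_ln": SynapseParams(g_syn=1.0, tau_syn=0.010, V_rev=0.0),
        "ln_pn": SynapseParams(g_syn=0.055, tau_syn=0.020, V_rev=-80.0),
        "ln_ln": SynapseParams(g_syn=0.020, tau_syn=0.020, V_rev=-80.0),
    }


@dataclass(frozen=True)
class NetworkSpec:
    """Counts, wiring parameters and synapse/neuron tables of the AL model.

    ``calibration`` is the receptor-to-current conversion: nA of ORN input
    current per unit summed activated receptor fraction (the neuron-level
    k=10 scale then applies on top inside the ORN membrane equation).
    """

    n_glo: int = 160
    n_orn_per_type: int = 60
    n_pn_per_glo: int = 5
    n_ln_per_glo: int = 25
    fan_in: int = 12
    calibration: float = 1.0
    synapses: dict[str, SynapseParams] = field(default_factory=default_synapses)
    orn_params: NeuronParams = ORN_PARAMS
    pn_params: NeuronParams = PN_PARAMS
    ln_params: NeuronParams = LN_PARAMS
    wiring_seed: int | None = None

    def __post_init__(self) -> None:
        for f in ("n_glo", "n_orn_per_type", "n_pn_per_glo", "n_ln_per_glo", "fan_in"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")
        if self.fan_in > self.n_orn_per_type:
            raise ValueError(
                f"fan_in ({self.fan_in}) exceeds ORNs per type "
                f"({self.n_orn_per_type}); sampling is without replacement"
            )
        missing = [c for c in CONNECTION_CLASSES if c not in self.synapses]
        if missing:
            raise ValueError(f"missing synapse classes: {missing}")

    @property
    def n_orn(self) -> int:
        return self.n_glo * self.n_orn_per_type

    @property
    def n_pn(self) -> int:
        return self.n_glo * self.n_pn_per_glo

    @property
    def n_ln(self) -> int:
        return self.n_glo * self.n_ln_per_glo

    @property
    def n_neurons(self) -> int:
        return self.n_orn + self.n_pn + self.n_ln

    def scaled(self, scale: float, *, rescale_inhibition: bool = True) -> "NetworkSpec":
        """Reduced-size spec: glomerulus and per-glomerulus counts are
        multiplied by ``scale`` (floored at 1); ORN fan-in is capped at the
        available ORNs.

        With ``rescale_inhibition`` (default) the LN->PN / LN->LN
        conductances are multiplied by the per-glomerulus LN-count ratio
        (full over scaled) and PN->LN by the PN-count ratio.  Odour profile
        widths are defined in receptor-index units and therefore activate a
        fixed *number* of glomeruli irrespective of network size, so
        compensating only the per-glomerulus count reduction reproduces the
        full-size inhibition received by a PN under any localized
        activation pattern; fully-recruiting (very broad) odours receive
        proportionally less total inhibition than at full size, which is
        the unavoidable remainder of the reduction.  ORN fan-in is
        unchanged, so excitatory drive per cell is scale-invariant by
        construction.
        """
        if not 0 < scale <= 1:
            raise ValueError("scale must be in (0, 1]")
        counts = {
            f: max(1, round(getattr(self, f) * scale))
            for f in ("n_glo", "n_orn_per_type", "n_pn_per_glo", "n_ln_per_glo")
        }
        fan_in = min(self.fan_in, counts["n_orn_per_type"])
        syn = dict(self.synapses)
        if rescale_inhibition:
            inh = self.n_ln_per_glo / counts["n_ln_per_glo"]
            exc = self.n_pn_per_glo / counts["n_pn_per_glo"]
            for cls, factor in (("ln_pn", inh), ("ln_ln", inh), ("pn_ln", exc)):
                syn[cls] = replace(syn[cls], g_syn=syn[cls].g_syn * factor)
        return replace(self, fan_in=fan_in, synapses=syn, **counts)


class Network:
    """A wired AL network: glomerular assignments plus ORN fan-in tables.

    Lateral (LN->PN, LN->LN) and intra-glomerular (PN->LN) connectivity is
    structural ("all other glomeruli" / "all PNs of the glomerulus") and is
    represented by the glomerulus labels; only the random ORN fan-in needs
    explicit index tables.  ``synapse_table`` materialises any class as an
    explicit edge list when needed.
    """

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator | None = None):
        self.spec = spec
        seed = spec.wiring_seed
        rng = np.random.default_rng(seed if rng is None else rng)
        g = np.arange(spec.n_glo)
        self.orn_glo = np.repeat(g, spec.n_orn_per_type)
        self.pn_glo = np.repeat(g, spec.n_pn_per_glo)
        self.ln_glo = np.repeat(g, spec.n_ln_per_glo)
        self.fanin_pn = self._sample_fanin(rng, self.pn_glo)
        self.fanin_ln = self._sample_fanin(rng, self.ln_glo)

    def _sample_fanin(self, rng: np.random.Generator, post_glo: np.ndarray) -> np.ndarray:
        """fan_in ORN indices per postsynaptic cell, without replacement,
        all from the cell's own receptor type."""
        s = self.spec
        out = np.empty((post_glo.size, s.fan_in), dtype=np.intp)
        for i, g in enumerate(post_glo):
            pick = rng.choice(s.n_orn_per_type, size=s.fan_in, replace=False)
            out[i] = g * s.n_orn_per_type + pick
        return out

    # -- edge-list materialisation -----------------------------------------

    def synapse_table(self, cls: str) -> pd.DataFrame:
        """Explicit (pre, post, g_syn, tau_syn, V_rev) edge list for one
        connection class.  Indices are population-local."""
        s = self.spec
        p = s.synapses[cls]
        if cls == "orn_pn":
            pre, post = self.fanin_pn.ravel(), np.repeat(np.arange(s.n_pn), s.fan_in)
        elif cls == "orn_ln":
            pre, post = self.fanin_ln.ravel(), np.repeat(np.arange(s.n_ln), s.fan_in)
        elif cls == "pn_ln":
            pairs = [
                (pn, ln)
                for g in range(s.n_glo)
                for pn in np.flatnonzero(self.pn_glo == g)
                for ln in np.flatnonzero(self.ln_glo == g)
            ]
            pre, post = map(np.array, zip(*pairs)) if pairs else ((), ())
        elif cls in ("ln_pn", "ln_ln"):
            post_glo = self.pn_glo if cls == "ln_pn" else self.ln_glo
            pairs = [
                (ln, post)
                for ln in range(s.n_ln)
                for post in np.flatnonzero(post_glo != self.ln_glo[ln])
            ]
            pre, post = map(np.array, zip(*pairs)) if pairs else ((), ())
        else:
            raise KeyError(f"unknown connection class {cls!r}")
        return pd.DataFrame({
            "pre": np.asarray(pre, dtype=int), "post": np.asarray(post, dtype=int),
            "g_syn": p.g_syn, "tau_syn": p.tau_syn, "V_rev": p.V_rev,
        })

    def save_edge_lists(self, directory) -> None:
        from pathlib import Path
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for cls in CONNECTION_CLASSES:
            self.synapse_table(cls).to_csv(d / f"synapses_{cls}.csv", index=False)


def build_network(spec: NetworkSpec, rng: np.random.Generator | None = None) -> Network:
    """Wire the AL network described by `spec` (see :class:`Network`)."""
    return Network(spec, rng)


def orn_drive(
    receptor_state: ReceptorState,
    orn_glo: np.ndarray,
    calibration: float = 1.0,
) -> np.ndarray:
    """Per-ORN input current (nA): calibration x summed activated fraction
    of the ORN's receptor type.  The neuron-level k=10 scale is applied
    separately inside the membrane equation."""
    return calibration * receptor_state.activation[orn_glo]
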