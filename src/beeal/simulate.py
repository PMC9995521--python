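"""Stimulus protocols and the fixed-step network simulator.

A :class:`StimulusProtocol` is an ordered list of constant-concentration
segments over a small set of odorants (typically a 1 s baseline, a 3 s
odour step, and a post-stimulus tail).  :func:`run` integrates the receptor
kinetics and the spiking network through the protocol with a global 0.2 ms
Euler step (receptors use the exact per-segment propagator, see
:mod:`beeal.receptors`) and returns a :class:`SimulationRecord` of spike
times, optional membrane-potential traces and receptor activations.

Runs are deterministic given the wiring seed (in the network) and the noise
seed passed here; the noise stream advances every step for every neuron
regardless of what is recorded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import _kernel
from .network import Network
from .odours import OdourLibrary, OdourProfile
from .receptors import propagators

__all__ = [
    "Segment",
    "StimulusProtocol",
    "default_protocol",
    "run",
    "SimulationRecord",
    "NumericalInstabilityError",
]

DT_DEFAULT = 2e-4  # s (0.2 ms global timestep)

POPULATIONS = ("orn", "pn", "ln")


class NumericalInstabilityError(RuntimeError):
    """State became NaN/overflowed; message names population and step."""


@dataclass(frozen=True)
class Segment:
    """One constant-concentration stimulus segment."""

    duration: float                  # s
    concentrations: np.ndarray       # per odorant, dimensionless dilution units
    dilution: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "concentrations",
                           np.asarray(self.concentrations, dtype=float))
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")
        if np.any(self.concentrations < 0) or self.dilution < 0:
            raise ValueError("concentrations must be non-negative")

    @property
    def effective_concentrations(self) -> np.ndarray:
        return self.concentrations * self.dilution


@dataclass(frozen=True)
class StimulusProtocol:
    """Odorants plus the ordered concentration segments applied to them."""

    odours: tuple[OdourProfile, ...]
    segments: tuple[Segment, ...]
    hill_n: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "odours", tuple(self.odours))
        object.__setattr__(self, "segments", tuple(self.segments))
        for seg in self.segments:
            if seg.concentrations.shape != (len(self.odours),):
                raise ValueError("segment concentrations must align with odours")

    @property
    def duration(self) -> float:
        return sum(seg.duration for seg in self.segments)

    def stimulus_window(self) -> tuple[float, float]:
        """(t_on, t_off) of the first segment with non-zero concentration;
        falls back to the full interval for a pure-baseline protocol."""
        t = 0.0
        for seg in self.segments:
            if np.any(seg.effective_concentrations > 0):
                return t, t + seg.duration
            t += seg.duration
        return 0.0, self.duration

    def baseline_window(self) -> tuple[float, float]:
        """The zero-concentration interval preceding the stimulus."""
        t_on, _ = self.stimulus_window()
        return 0.0, t_on


def default_protocol(
    library: OdourLibrary | Sequence[OdourProfile],
    concentrations: Mapping[str, float],
    *,
    pre: float = 1.0,
    stimulus: float = 3.0,
    post: float = 2.0,
    hill_n: float = 1.0,
) -> StimulusProtocol:
    """Baseline / step / tail protocol: `pre` s at zero, `stimulus` s at the
    given constant concentrations (simultaneously for all named odours —
    a mixture if more than one), then `post` s back at zero.

    Unknown odour names raise ``KeyError``.  An empty mapping yields a
    pure-baseline protocol with no odorants.
    """
    if isinstance(library, OdourLibrary):
        odours = [library[name] for name in concentrations]
    else:
        by_name = {od.name: od for od in library}
        odours = [by_name[name] for name in concentrations]
    c = np.array([concentrations[od.name] for od in odours], dtype=float)
    zeros = np.zeros_like(c)
    segments = []
    if pre > 0:
        segments.append(Segment(pre, zeros))
    segments.append(Segment(stimulus, c))
    if post > 0:
        segments.append(Segment(post, zeros))
    return StimulusProtocol(odours=tuple(odours), segments=tuple(segments),
                            hill_n=hill_n)


@dataclass
class SimulationRecord:
    """Spikes (and optional traces) from one simulation run.

    Spike times are end-of-step times in seconds; ``spike_ids`` are global
    neuron indices with layout [ORN 0..n_orn-1 | PN | LN].
    """

    spike_times: np.ndarray
    spike_ids: np.ndarray
    n_orn: int
    n_pn: int
    n_ln: int
    glomeruli: np.ndarray          # per global neuron id
    dt: float
    duration: float
    protocol: StimulusProtocol | None = None
    seeds: dict = field(default_factory=dict)
    traces: dict = field(default_factory=dict)      # name -> (idx, V array)
    receptor_activation: np.ndarray | None = None   # (n_steps, n_glo)

    _slices: dict = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        self._slices = {
            "orn": slice(0, self.n_orn),
            "pn": slice(self.n_orn, self.n_orn + self.n_pn),
            "ln": slice(self.n_orn + self.n_pn, self.n_orn + self.n_pn + self.n_ln),
        }

    def population_of(self, gid: int) -> str:
        for pop, sl in self._slices.items():
            if sl.start <= gid < sl.stop:
                return pop
        raise IndexError(gid)

    def pop_slice(self, population: str) -> slice:
        return self._slices[population]

    def spikes(self, population: str | None = None,
               window: tuple[float, float] | None = None):
        """(times, global ids), optionally restricted to one population
        and/or a time window."""
        t, i = self.spike_times, self.spike_ids
        if population is not None:
            sl = self._slices[population]
            m = (i >= sl.start) & (i < sl.stop)
            t, i = t[m], i[m]
        if window is not None:
            m = (t >= window[0]) & (t < window[1])
            t, i = t[m], i[m]
        return t, i

    def spike_count(self, population: str | None = None,
                    window: tuple[float, float] | None = None) -> int:
        return int(self.spikes(population, window)[0].size)

    def spike_times_of(self, gid: int) -> np.ndarray:
        return np.sort(self.spike_times[self.spike_ids == gid])

    def to_dataframe(self) -> pd.DataFrame:
        pops = np.empty(self.spike_ids.size, dtype=object)
        local = self.spike_ids.copy()
        for pop, sl in self._slices.items():
            m = (self.spike_ids >= sl.start) & (self.spike_ids < sl.stop)
            pops[m] = pop
            local[m] -= sl.start
        return pd.DataFrame({
            "neuron_id": local,
            "population": pops,
            "glomerulus": self.glomeruli[self.spike_ids],
            "time_s": self.spike_times,
        })

    # -- plain-text persistence --------------------------------------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(d / "spikes.csv", index=False)
        meta = {
            "n_orn": self.n_orn, "n_pn": self.n_pn, "n_ln": self.n_ln,
            "dt": self.dt, "duration": self.duration, "seeds": self.seeds,
        }
        if self.protocol is not None:
            meta["odours"] = [od.name for od in self.protocol.odours]
            meta["segments"] = [
                {"duration": s.duration,
                 "concentrations": list(map(float, s.effective_concentrations))}
                for s in self.protocol.segments
            ]
        (d / "meta.json").write_text(json.dumps(meta, indent=1))
        np.savetxt(d / "glomeruli.csv", self.glomeruli, fmt="%d")
        for name, (idx, V) in self.traces.items():
            pd.DataFrame(V.T, columns=[f"n{g}" for g in idx]).to_csv(
                d / f"trace_{name}.csv", index=False)


def _segment_steps(duration: float, dt: float) -> int:
    n = round(duration / dt)
    if abs(n * dt - duration) > 1e-9:
        raise ValueError(f"dt={dt} does not divide segment duration {duration}")
    return n


def run(
    network: Network,
    protocol: StimulusProtocol,
    noise_seed: int | None = None,
    *,
    dt: float = DT_DEFAULT,
    record_traces: Iterable[int] = (),
    record_receptors: bool = False,
    chunk_steps: int = 2000,
) -> SimulationRecord:
    """Integrate `protocol` through `network` and record spikes.

    `record_traces` lists global neuron ids whose membrane potential is
    sampled every step; `record_receptors` stores the per-type summed
    activated receptor fraction.  Identical arguments (and seeds) give
    bitwise-identical records.
    """
    spec = network.spec
    odours = list(protocol.odours)
    n_od = len(odours)
    n_glo = spec.n_glo
    if n_od and odours[0].n_glo != n_glo:
        raise ValueError("odour profiles and network disagree on n_glo")
    rng = np.random.default_rng(noise_seed)

    syn = spec.synapses
    if syn["orn_pn"].tau_syn != syn["orn_ln"].tau_syn:
        raise ValueError("ORN->PN and ORN->LN must share tau_syn "
                         "(one activation trace per ORN)")
    if syn["ln_pn"].tau_syn != syn["ln_ln"].tau_syn:
        raise ValueError("LN->PN and LN->LN must share tau_syn")

    n_orn, n_pn, n_ln = spec.n_orn, spec.n_pn, spec.n_ln
    n_tot = n_orn + n_pn + n_ln
    m = 2 * n_od + 1
    rec_state = np.zeros((n_glo, m))
    rec_state[:, 0] = 1.0

    V_orn = np.full(n_orn, spec.orn_params.V_leak)
    a_orn = np.zeros(n_orn)
    s_orn = np.zeros(n_orn)
    f_orn = np.zeros(n_orn)
    V_pn = np.full(n_pn, spec.pn_params.V_leak)
    s_pn = np.zeros(n_pn)
    f_pn = np.zeros(n_pn)
    V_ln = np.full(n_ln, spec.ln_params.V_leak)
    a_ln = np.zeros(n_ln)
    s_ln = np.zeros(n_ln)
    f_ln = np.zeros(n_ln)

    orn_p = _kernel.pack_params(spec.orn_params)
    pn_p = _kernel.pack_params(spec.pn_params)
    ln_p = _kernel.pack_params(spec.ln_params)

    total_steps = sum(_segment_steps(s.duration, dt) for s in protocol.segments)
    trace_idx = np.asarray(sorted(record_traces), dtype=np.intp)
    trace_V = np.zeros((trace_idx.size, total_steps))
    rsum_out = np.zeros((total_steps if record_receptors else 0,
                         n_glo if record_receptors else 0))

    spike_steps: list[np.ndarray] = []
    spike_ids: list[np.ndarray] = []
    buf = np.zeros((min(chunk_steps, total_steps), n_tot), dtype=np.uint8)

    step0 = 0
    for seg in protocol.segments:
        n_seg = _segment_steps(seg.duration, dt)
        if n_od:
            P = propagators(odours, seg.effective_concentrations, dt,
                            protocol.hill_n)
        else:
            P = np.ones((n_glo, 1, 1))
        done = 0
        while done < n_seg:
            n = min(chunk_steps, n_seg - done)
            noise = rng.standard_normal((n, n_tot))
            sbuf = buf[:n]
            sbuf[:] = 0
            tr = trace_V[:, step0:step0 + n]
            rs = rsum_out[step0:step0 + n] if record_receptors else rsum_out[:0]
            _kernel.advance_chunk(
                n, dt, P, rec_state, n_od,
                network.orn_glo, V_orn, a_orn, s_orn, f_orn,
                network.pn_glo, V_pn, s_pn, f_pn, network.fanin_pn,
                network.ln_glo, V_ln, a_ln, s_ln, f_ln, network.fanin_ln,
                n_glo, orn_p, pn_p, ln_p,
                1e3 * spec.calibration,
                syn["orn_pn"].g_syn, syn["orn_pn"].V_rev,
                syn["orn_ln"].g_syn, syn["orn_ln"].V_rev,
                syn["pn_ln"].g_syn, syn["pn_ln"].V_rev,
                syn["ln_pn"].g_syn, syn["ln_pn"].V_rev,
                syn["ln_ln"].g_syn, syn["ln_ln"].V_rev,
                syn["orn_pn"].tau_syn, syn["pn_ln"].tau_syn,
                syn["ln_pn"].tau_syn,
                noise, sbuf, trace_idx, tr, rs,
            )
            for pop, V in (("orn", V_orn), ("pn", V_pn), ("ln", V_ln)):
                if not np.all(np.isfinite(V)):
                    raise NumericalInstabilityError(
                        f"non-finite membrane potential in population "
                        f"'{pop}' at step {step0 + n}")
            st, ids = np.nonzero(sbuf)
            spike_steps.append(st + step0)
            spike_ids.append(ids)
            step0 += n
            done += n

    steps = np.concatenate(spike_steps) if spike_steps else np.empty(0, dtype=int)
    ids = np.concatenate(spike_ids) if spike_ids else np.empty(0, dtype=int)
    glomeruli = np.concatenate([network.orn_glo, network.pn_glo, network.ln_glo])
    record = SimulationRecord(
        spike_times=(steps + 1) * dt,
        spike_ids=ids,
        n_orn=n_orn, n_pn=n_pn, n_ln=n_ln,
        glomeruli=glomeruli,
        dt=dt,
        duration=total_steps * dt,
        protocol=protocol,
        seeds={"wiring": spec.wiring_seed, "noise": noise_seed},
    )
    if trace_idx.size:
        record.traces["V"] = (trace_idx, trace_V)
    if record_receptors:
        record.receptor_activation = rsum_out
    return record
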