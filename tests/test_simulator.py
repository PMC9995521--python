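"""Network simulator: protocols, determinism, event ordering, and
equivalence of the fused kernel with the modular step operations."""

import dataclasses

import numpy as np
import pytest

from beeal.network import NetworkSpec, build_network
from beeal.neurons import SynapseParams, step_neuron
from beeal.odours import OdourLibrary
from beeal.simulate import (Segment, StimulusProtocol, default_protocol, run)

from conftest import narrow_odour


def noiseless(spec):
    return dataclasses.replace(
        spec,
        orn_params=spec.orn_params.without_noise(),
        pn_params=spec.pn_params.without_noise(),
        ln_params=spec.ln_params.without_noise(),
    )


def strong_odour(n_glo):
    """Saturating broad odorant: activates every receptor type hard."""
    return narrow_odour(n_glo, n_glo // 2, name="strong", eta=2.0,
                        sigma=1e3, k2=0.1)


@pytest.fixture(scope="module")
def quiet_net(tiny_spec):
    return build_network(noiseless(tiny_spec))


class TestProtocol:
    def test_default_protocol_shape(self):
        lib = OdourLibrary.generate(n_glo=40, n_random=0, seed=0)
        p = default_protocol(lib, {"Geosmin": 1e-6})
        assert [s.duration for s in p.segments] == [1.0, 3.0, 2.0]
        assert p.segments[1].effective_concentrations == pytest.approx([1e-6])
        assert p.stimulus_window() == (1.0, 4.0)
        assert p.baseline_window() == (0.0, 1.0)

    def test_mixture_protocol_steps_both_odours_simultaneously(self):
        lib = OdourLibrary.generate(n_glo=40, n_random=0, seed=0)
        p = default_protocol(lib, {"IAA": 1e-1, "Geosmin": 1e-3})
        assert sorted(od.name for od in p.odours) == ["Geosmin", "IAA"]
        assert set(p.segments[1].effective_concentrations) == {1e-1, 1e-3}

    def test_empty_odour_list_gives_pure_baseline(self):
        p = default_protocol([], {}, pre=0.5, stimulus=1.0, post=0.5)
        assert len(p.odours) == 0 and p.duration == 2.0

    def test_unknown_odour_name_rejected(self):
        lib = OdourLibrary.generate(n_glo=40, n_random=0, seed=0)
        with pytest.raises(KeyError):
            default_protocol(lib, {"linalool": 1e-3})

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            Segment(1.0, np.array([-1e-3]))

    def test_misaligned_concentrations_rejected(self, tiny_spec):
        od = strong_odour(tiny_spec.n_glo)
        with pytest.raises(ValueError, match="align"):
            StimulusProtocol(odours=(od,), segments=(Segment(1.0, np.zeros(2)),))


class TestRun:
    def test_no_drive_no_noise_means_no_spikes(self, quiet_net):
        p = default_protocol([], {}, pre=0.2, stimulus=0.2, post=0.1)
        rec = run(quiet_net, p, noise_seed=0)
        assert rec.spike_times.size == 0

    def test_identical_seeds_give_bitwise_identical_spikes(self, tiny_net):
        od = strong_odour(tiny_net.spec.n_glo)
        p = default_protocol([od], {"strong": 1e-2}, pre=0.2, stimulus=0.5,
                             post=0.1)
        a = run(tiny_net, p, noise_seed=99)
        b = run(tiny_net, p, noise_seed=99)
        assert np.array_equal(a.spike_times, b.spike_times)
        assert np.array_equal(a.spike_ids, b.spike_ids)
        c = run(tiny_net, p, noise_seed=100)
        assert not (c.spike_times.size == a.spike_times.size
                    and np.array_equal(a.spike_times, c.spike_times))

    def test_chunking_does_not_change_results(self, tiny_net):
        od = strong_odour(tiny_net.spec.n_glo)
        p = default_protocol([od], {"strong": 1e-2}, pre=0.2, stimulus=0.3,
                             post=0.1)
        a = run(tiny_net, p, noise_seed=5, chunk_steps=2000)
        b = run(tiny_net, p, noise_seed=5, chunk_steps=2000)
        assert np.array_equal(a.spike_times, b.spike_times)

    def test_trace_recording_never_alters_dynamics(self, tiny_net):
        od = strong_odour(tiny_net.spec.n_glo)
        p = default_protocol([od], {"strong": 1e-2}, pre=0.1, stimulus=0.3,
                             post=0.1)
        a = run(tiny_net, p, noise_seed=7)
        b = run(tiny_net, p, noise_seed=7, record_traces=[0, tiny_net.spec.n_orn],
                record_receptors=True)
        assert np.array_equal(a.spike_times, b.spike_times)
        assert b.traces["V"][1].shape == (2, round(p.duration / b.dt))
        assert b.receptor_activation.shape[1] == tiny_net.spec.n_glo

    def test_excitation_leads_inhibition(self, quiet_net):
        od = strong_odour(quiet_net.spec.n_glo)
        p = default_protocol([od], {"strong": 1e-1}, pre=0.1, stimulus=0.5,
                             post=0.1)
        rec = run(quiet_net, p, noise_seed=0)
        t_orn = rec.spikes("orn")[0].min()
        t_pn = rec.spikes("pn")[0].min()
        t_ln = rec.spikes("ln")[0].min()
        assert t_orn < t_pn and t_orn < t_ln
        # synaptic latency is one step: PN drive cannot precede ORN spike + dt
        assert t_pn >= t_orn + rec.dt

    def test_spike_times_strictly_increasing_and_in_range(self, tiny_net):
        od = strong_odour(tiny_net.spec.n_glo)
        p = default_protocol([od], {"strong": 1e-2}, pre=0.1, stimulus=0.4,
                             post=0.1)
        rec = run(tiny_net, p, noise_seed=3)
        assert rec.spike_times.min() > 0
        assert rec.spike_times.max() <= rec.duration + 1e-12
        for gid in np.unique(rec.spike_ids)[:20]:
            assert np.all(np.diff(rec.spike_times_of(gid)) > 0)

    def test_halving_dt_changes_pn_activity_less_than_5pct(self, quiet_net):
        from beeal.analysis import windowed_mean_sdf
        od = strong_odour(quiet_net.spec.n_glo)
        p = default_protocol([od], {"strong": 3e-3}, pre=0.2, stimulus=1.0,
                             post=0.2)
        acts = []
        for dt in (2e-4, 1e-4):
            rec = run(quiet_net, p, noise_seed=0, dt=dt)
            acts.append(windowed_mean_sdf(rec.spikes("pn")[0], (0.2, 1.2)))
        assert acts[0] > 0
        assert abs(acts[1] - acts[0]) / acts[0] < 0.05

    def test_dt_must_divide_segments(self, tiny_net):
        od = strong_odour(tiny_net.spec.n_glo)
        p = default_protocol([od], {"strong": 1e-3}, pre=0.1001, stimulus=0.2,
                             post=0.1)
        with pytest.raises(ValueError, match="divide"):
            run(tiny_net, p, noise_seed=0)

    def test_mismatched_network_and_odour_size_rejected(self, tiny_net):
        od = strong_odour(tiny_net.spec.n_glo + 1)
        p = default_protocol([od], {"strong": 1e-3}, pre=0.1, stimulus=0.2,
                             post=0.1)
        with pytest.raises(ValueError, match="n_glo"):
            run(tiny_net, p, noise_seed=0)


class TestKernelEquivalence:
    """With all synapses silenced, every neuron is an isolated noisy LIF:
    the fused kernel must reproduce the modular step_neuron trajectory
    driven by the same noise draws, spike for spike."""

    def test_disconnected_network_matches_single_neuron_updates(self, tiny_spec):
        silent = {cls: SynapseParams(0.0, p.tau_syn, p.V_rev)
                  for cls, p in tiny_spec.synapses.items()}
        spec = dataclasses.replace(tiny_spec, synapses=silent)
        net = build_network(spec)
        p = default_protocol([], {}, pre=0.2, stimulus=0.2, post=0.0)
        n_steps = round(p.duration / 2e-4)
        seed = 2024
        probes = {"orn": 0, "pn": spec.n_orn, "ln": spec.n_orn + spec.n_pn}
        rec = run(net, p, noise_seed=seed, record_traces=list(probes.values()),
                  chunk_steps=10**6)
        idx, V_tr = rec.traces["V"]
        noise = np.random.default_rng(seed).standard_normal(
            (n_steps, spec.n_neurons))
        params = {"orn": spec.orn_params, "pn": spec.pn_params,
                  "ln": spec.ln_params}
        for pop, gid in probes.items():
            V, a = params[pop].V_leak, 0.0
            V_ref, spikes_ref = np.empty(n_steps), []
            for t in range(n_steps):
                V, a, spk = step_neuron(V, a, 0.0, params[pop], 2e-4,
                                        noise[t, gid])
                V_ref[t] = V
                if spk:
                    spikes_ref.append((t + 1) * 2e-4)
            row = V_tr[list(idx).index(gid)]
            assert np.array_equal(row, V_ref), pop
            assert np.allclose(rec.spike_times_of(gid), spikes_ref), pop


class TestRecordIO:
    def test_dataframe_and_save_roundtrip(self, tiny_net, tmp_path):
        od = strong_odour(tiny_net.spec.n_glo)
        p = default_protocol([od], {"strong": 1e-2}, pre=0.1, stimulus=0.3,
                             post=0.1)
        rec = run(tiny_net, p, noise_seed=1, record_traces=[0])
        df = rec.to_dataframe()
        assert set(df.columns) == {"neuron_id", "population", "glomerulus",
                                   "time_s"}
        assert set(df.population) <= {"orn", "pn", "ln"}
        rec.save(tmp_path)
        assert (tmp_path / "spikes.csv").exists()
        assert (tmp_path / "meta.json").exists()
        assert (tmp_path / "trace_V.csv").exists()
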