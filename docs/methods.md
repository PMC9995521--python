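# Methods notes

This note records the modelling assumptions, parameter choices and
numerical decisions behind `beeal`, in the spirit of the methods sections
that accompany simulation packages.  Nothing here states an empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## Model summary and assumptions

The model is a feed-forward-plus-lateral-inhibition abstraction of the bee
early olfactory system:

* **Transduction** is a two-stage binding/activation scheme per receptor
  type.  All odorants present compete for one shared pool of unbound
  receptors (syntopic competition); there is no allosteric interaction,
  no receptor adaptation, and no channel noise at the receptor level.
  The mapping of summed activated fraction to ORN input current is a
  single calibration constant (below).
* **Neurons** are adaptive leaky integrate-and-fire units with white
  current noise; there is no refractory period, no conduction delay
  beyond the one-step synaptic latency, and no morphology.
* **Circuit** wiring is structural: ORN→PN/LN fan-in is the only random
  element; PN→LN is all-to-all within a glomerulus and LN→PN/LN is
  all-to-all across (never within) glomeruli with uniform weights.
  Heterogeneous or learned inhibition is out of scope.

## Parameters

| parameter | value | notes |
|---|---|---|
| membrane C, g_leak, V_leak | 1 nF, 10 nS, −60 mV | all populations; τ_m = 100 ms |
| threshold / reset | −40 / −70 mV | spike registered at end-of-step |
| noise amplitude A | 1.4 nA | per-step N(0,1) draw, see below |
| adaptation g_adapt | ORN 1.5, LN 0.5, PN 0 nS | jump 0.5 per spike, τ = 1 s |
| adaptation reversal V_adapt | −70 mV | value not constrained by the model sources; chosen hyperpolarising, equal to reset; configurable |
| ORN current scale k | 10 | one model ORN stands in for ten biological ones |
| synapses (g nS / τ ms / V_rev mV) | ORN→PN 8/10/0, ORN→LN 8/10/0, PN→LN 1/10/0, LN→PN 0.055/20/−80, LN→LN 0.02/20/−80 | |
| receptor off-rates k₋₁ = k₋₂ | 0.025 kHz | all odours and types |
| calibration (r*→current) | 1 nA per unit summed activated fraction | unconstrained by the sources; 1 nA makes maximal drive k·1 nA = 10 nA ≫ the 0.2 nA rheobase, giving concentration-graded ORN rates; configurable |
| Hill exponent n | 1 | simplest standard choice; configurable |
| integration step dt | 0.2 ms | global |
| SDF kernel σ | 100 ms | |
| concentration grid | 7 log-spaced points 10⁻⁷..10⁻¹ | range over which m is defined |

Two published values exist for the "Geosmin" activation rate k₂ —
0.003 kHz in the transduction parameterisation and 0.03 kHz in the
mixture/EAG analysis (a ~1:3 ratio to IAA's 0.1 kHz).  Both are exposed
as named presets (`"methods"`, `"results"`); concentration sweeps and PN
maps default to the former, the ORN mixture experiment to the latter, and
every experiment manifest records which was used.

The width σ acts on the receptor-type *index* axis (it is sometimes
quoted in kHz in the sources, but only an index-distance interpretation
is dimensionally coherent); profiles are truncated at the index bounds —
no ring topology.  The literal one-sided dialect of the profile formula
(peak adjacent to index 0, offset d = j+1) is available via
`gaussian_k1_profile(..., one_sided=True)`; the default centered form is
required so two profiles can sit a defined peak distance apart.

## Random odour generator

The generator *is* the study condition: 98 random odours (plus the
designated pair) with truncated-normal η, σ, k₂ as listed in the README,
each scrambled by its own uniform permutation (the designated pair share
one).  Truncated normals are drawn by rejection from the parent normal —
simple and exact.  Two independent child streams derive from the library
seed, one for parameters and one for permutations, so either can be
varied in isolation.  The generator emulates smooth unimodal tuning of
odorants across a receptor repertoire; it does not emulate chemical
similarity structure, correlated tuning between odorants, multimodal
profiles, or concentration-dependent profile shape.  Passing tests
therefore demonstrate circuit-level consequences of profile breadth, not
predictions for any particular real odorant.

## Numerical choices

* **Receptor integration.**  For piecewise-constant concentrations the
  receptor system is linear in its state (the Hill power applies to a
  constant), so the simulator advances it with the exact matrix-exponential
  propagator `expm(A·dt)`, rebuilt per stimulus segment.  This matters:
  for a broad, high-sensitivity odorant (η = 4.4) at concentration 10⁻¹
  the binding rate reaches ~2.5·10³ kHz and an explicit 0.2 ms Euler step
  diverges (dt·rate ≈ 500).  The forward-Euler update `step_receptors`
  remains available with an explicit stability check
  (`dt · max total outflow rate < 1`) and is verified against the
  analytic steady state in the non-stiff regime.
* **Noise discretisation.**  Per neuron and step one N(0,1) draw is added
  as a constant current A·ξ over the step, without √dt rescaling — the
  common fixed-step practice; with dt fixed at 0.2 ms the dialect is
  reproducible.  The noise stream advances every step for every neuron
  regardless of recording, so trace subsampling never alters dynamics.
* **Synaptic latency.**  Spikes emitted in step t increment postsynaptic
  activations in step t+1, avoiding within-step ordering ambiguity and
  realising, at minimal scale, the property that lateral inhibition
  arrives after direct excitation.
* **Threshold convention.**  V ≥ V_th tested after the Euler update;
  fan-in sampling is without replacement.
* **Conservation.**  Euler receptor updates are applied as explicit
  redistributions between compartments, keeping r0 + Σr + Σr* = 1 to
  floating-point accumulation (≲10⁻¹² over 10⁶ steps); the propagator
  conserves mass by construction of the rate matrix (columns sum to 0).
* **Degenerate inputs.**  All-zero rate systems, all-zero response
  curves (undefined m), constant-σ correlation inputs, negative
  concentrations, non-dividing dt and mismatched network/odour sizes all
  raise typed errors rather than producing silent numbers.

## Reduced-scale networks

A scale factor s multiplies the glomerulus count and the per-glomerulus
ORN/PN/LN counts (floored at 1); ORN fan-in stays at 12 (capped at the
available ORNs), so the excitatory drive of each PN/LN is
scale-invariant.  Because σ is an index-space width, an odour activates a
fixed *number* of glomeruli at any network size; lateral-inhibition
conductances are therefore multiplied by the per-glomerulus count ratios
only (LN→PN and LN→LN by 25/n_ln_scaled, PN→LN by 5/n_pn_scaled), which
exactly preserves the full-size inhibition a PN receives under any
localized activation pattern.  Odours broad enough to recruit the whole
reduced array receive proportionally less total inhibition than at full
size — the unavoidable remainder of the reduction, which biases reduced
networks *against* the suppression phenomenon rather than toward it.
An alternative factor that additionally compensates the glomerulus-count
ratio (preserving whole-array inhibition instead) was rejected because it
makes narrow odours at reduced scale behave like broad odours at full
scale, erasing the very contrast under study.

Problem sizes used by the test and acceptance runs (package defaults, not
claims about the full model): unit tests use 1–6 glomeruli; the 100-odour
monotonicity suite runs at scale 0.1 (16 glomeruli, 144 neurons); the
qualitative reproduction suite and the acceptance script run at scale
0.25 (40 glomeruli, 880 neurons) with 3 s stimuli and 0.3/0.2 s
pre/post windows.  Full-scale experiments (160 glomeruli, 14,400 neurons)
are run through the CLI.

## Known limitations

* The r*→current calibration and V_adapt are not constrained by the
  model's sources; results that depend on their absolute values (e.g.
  absolute firing rates) should be read qualitatively.
* The EAG proxy (total ORN spike count) ignores the biophysics of field
  potentials; only comparative statements across conditions are
  meaningful.
* At reduced scale, PN-level statistics rest on as few as one PN per
  glomerulus and are correspondingly noisy; monotonicity values are
  reported per seed, not averaged over noise realisations.
* Pre/post-stimulus durations around the 3 s pulse are configuration, not
  claims; the EAG baseline subtraction assumes stationary spontaneous
  activity.
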