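# pfcmicro

A conductance-based model of a layer-V prefrontal-cortex (PFC) microcircuit
for studying **persistent activity** — the delay-period firing considered the
cellular correlate of working memory — and how the three main interneuron
classes shape it.

The package is aimed at computational neuroscientists who want a small,
fully-scripted, deterministic testbed for excitation/inhibition-balance
questions: which interneuron class gates the *induction* of persistent
activity, which paces its *firing frequency*, and what happens to network
rhythms when fast-spiking input is deleted, thinned, or rewired.

## The model

Twenty compartmental Hodgkin–Huxley neurons: 16 pyramidal cells (soma,
basal, proximal and distal apical dendrites) and 4 interneurons — 2
fast-spiking (FS, parvalbumin-like, soma-targeting), 1 regular-spiking (RS,
calbindin-like, distal-dendrite-targeting) and 1 irregular-spiking (IS,
calretinin-like, dendrite- and interneuron-targeting). Interneuron channel
densities and passive properties follow published tables (e.g. FS soma
g̅_Na = 0.135 S/cm², C_m = 1.2 µF/cm², R_A = 150 Ω·cm, R_M = 10 kΩ·cm²);
gating kinetics and compartment dimensions are calibrated so each cell
reproduces its published validation numbers:

| cell | input resistance | current-step response |
|------|-----------------|------------------------|
| PYR  | 91.3 MΩ          | regular spiking with adaptation |
| FS   | 250.2 MΩ         | 6 spikes @ 0.05 nA, 100 Hz @ 0.2 nA |
| RS   | 487.8 MΩ         | 15 spikes @ 0.05 nA, 60 Hz @ 0.2 nA |
| IS   | ~545 MΩ          | initial 2–6-spike cluster, then irregular firing |

Synapses are peak-normalised bi-exponential conductances: AMPA and NMDA
(with the standard sigmoidal Mg²⁺ unblock,
B(V) = 1/(1 + 0.28·e^(−0.062·V)), and receptor saturation) for excitation,
GABA_A and slow GABA_B for inhibition. The control state uses
NMDA/AMPA = 1.25 on pyramidal cells (0.5 on FS, 0.8 on RS) and
GABA_B/GABA_A = 0.2; the unitary pyramidal AMPA conductance is calibrated to
a 0.1 mV somatic EPSP. Wiring follows the anatomical table: full recurrent
pyramid–pyramid connectivity (24 synapses/pair on basal dendrites, 8
autaptic), FS→soma (15/pair), RS→distal (12/pair), IS→distal (10/pair) and
IS→RS disinhibition, with Gaussian latencies (1.7 ± 0.9 ms).

Persistent activity is induced by 120 thalamocortical AMPA+NMDA synapses on
every pyramidal proximal dendrite, driven as 10 volleys at 20 Hz. In the
control network the delay state is a ~20 Hz network rhythm in which
pyramidal cells fire every second cycle (ISIs of 60–120 ms) — basal-dendrite
NMDA plateaus carry the activity across the inhibitory phase of each cycle
while FS somatic volleys pace it. Removing the FS cells releases the
pacemaker: the network still ignites on every trial, but fires at ~70 Hz
(ISIs near 15 ms) and loses all sensitivity to the receptor-ratio grid.

## Worked example

```python
from pfcmicro.cells import build_cell, f_i_point, measure_input_resistance
from pfcmicro.network import NetworkSpec, build_network
from pfcmicro.protocols import StimulusSpec, persistent_mean_isi, run_induction_trial
from pfcmicro.analysis import synaptic_current_spectrum

fs = build_cell("FS")
print(f"FS input resistance: {measure_input_resistance(fs):.1f} MOhm")
print(f"FS rate at 0.2 nA:   {f_i_point(fs, 0.2):.0f} Hz")

net = build_network(NetworkSpec(seed=1))
stim = StimulusSpec()
induced, spikes, traces = run_induction_trial(net, stim, seed=1)
isi = persistent_mean_isi(spikes, net.pyramidal, stim.end)
print(f"persistent activity induced: {induced}")
print(f"mean pyramidal ISI in the delay period: {isi:.1f} ms")

w0 = stim.end + 3000.0
spectrum = synaptic_current_spectrum([traces], (w0, w0 + 1000.0))
print(f"dominant frequency of summed synaptic currents: "
      f"{spectrum.dominant_frequency():.0f} Hz")
```

prints

```
FS input resistance: 251.0 MOhm
FS rate at 0.2 nA:   100 Hz
persistent activity induced: True
mean pyramidal ISI in the delay period: 98.1 ms
dominant frequency of summed synaptic currents: 21 Hz
```

— the FS cell sits at its target excitability, one seeded trial of the
control circuit ignites a delay state firing at ~10 Hz per pyramidal cell,
and the summed AMPA+NMDA+GABA_A currents oscillate near 20 Hz.

A `pfcmicro` console command exposes the same machinery:
`pfcmicro validate-cells`, `validate-synapses`, `run` (YAML experiment
manifests → reproducible bundles), `sweep` (receptor-ratio probability
maps), `analyze` and `report`.

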