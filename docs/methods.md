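# Methods

## Model overview

The microcircuit holds 20 multicompartment conductance-based neurons: 16
pyramidal cells (PYR; soma, basal, proximal-apical and distal-apical
cylinders) and 4 interneurons — 2 fast-spiking (FS), 1 regular-spiking (RS)
and 1 irregular-spiking (IS), each a soma plus dendritic and axonal
cylinders (the IS cell carries two dendrites, as a bipolar cell). Membrane
dynamics follow the cable equation with Hodgkin–Huxley-style channels; all
state advances with a fixed step of dt = 0.025 ms.

## Ionic mechanisms and their calibration

Nine channel families are shared across cell types: fast Na, delayed-
rectifier K (Kdr), A-type K (KA), slow non-inactivating K (Kslow), slowly
inactivating D-type K (KD), N- and T-type Ca (CaN, CaT), the
hyperpolarization-activated cation current (H), and a fast Ca-activated K
current (fAHP) driven by a first-order somatic calcium pool
(dCa/dt = −φ·I_Ca − (Ca − Ca_rest)/τ_Ca). Every gate is a Boltzmann steady
state with a constant or bell-shaped voltage-dependent time constant.

Interneuron channel *densities*, passive properties and channel *placement*
are fixed to the published tables (for example FS: somatic Na 0.135 S/cm²
with 10× that density on the axon, Kdr 0.036, N-type Ca 3×10⁻⁴, D-type K
7.25×10⁻⁵, H 10⁻⁵, A-type 3.2×10⁻³, fAHP 10⁻⁴; C_m = 1.2 µF/cm²,
R_A = 150 Ω·cm, R_M = 10/40/20 kΩ·cm² for FS/RS/IS). Gating constants and
compartment dimensions are **calibration parameters**: they were pinned by
requiring each assembled cell to reproduce its published behavioural
anchors —

* FS: resting potential −73 mV, input resistance 250.2 MΩ, 6 spikes for a
  0.05 nA/500 ms step, 100 Hz for 0.2 nA, spike threshold near −53 mV;
* RS: rest −64 mV, 487.8 MΩ, 15 spikes at 0.05 nA, 60 Hz at 0.2 nA;
* IS: rest −70 mV, ~530 MΩ, an initial cluster of 2–6 spikes followed by
  irregular firing (post-cluster ISI CV > 0.2), rates increasing with
  stimulus intensity;
* PYR: input resistance 91.3 MΩ and regular spiking with adaptation.

Compartment dimensions and (for the pyramidal cell, whose table values are
not published) R_M were chosen so total membrane area reproduces the input
resistances; the leak reversal of each compartment is solved analytically at
build time so the cell rests exactly at its target potential. Measured
against a −5 pA somatic step, the shipped cells give 91.1 / 251.0 / 488.4 /
530.7 MΩ (PYR/FS/RS/IS), preserving the published ordering
PYR < FS < RS < IS.

Two calibration compromises are documented rather than hidden: the RS
spike-threshold voltage measures ≈ −58 mV (published −51 mV) because the
shallow Na-activation slope that fixes the 15-spike/60 Hz pair lowers the
dV/dt-based threshold estimate; and the IS input resistance sits ~3% below
its published value, inside the ±5% band used for all input resistances.

## Synapses

Receptor conductances are peak-normalised differences of exponentials
(rise/decay: AMPA 0.5/3 ms, NMDA 5/150 ms, GABA_A 0.5/8 ms, GABA_B
50/150 ms; reversals 0, 0, −75, −90 mV). NMDA carries the standard
sigmoidal magnesium unblock (η = 0.28, γ = 0.062/mV at 1 mM Mg²⁺, half
unblock at −20.5 mV). The slow NMDA decay is at the GluN2B-rich end of the
cortical range; it is what lets delay-period activity bridge the inhibited
phase of each network cycle.

**Receptor saturation.** Closely spaced activations cannot drive one
synapse's open conductance above a ceiling of 3.25× its unitary peak; the
ceiling is applied per target compartment as a concave soft cap
g_eff = S·(1 − e^(−g/S)) with S the summed ceiling of the impinging NMDA
synapses. Without saturation the recurrent NMDA drive grows linearly with
rate and the only attractors are runaway (~100 Hz) firing or silence; the
ceiling is what creates a low-rate delay state.

**Strength conventions.** The unitary pyramidal AMPA conductance is
calibrated by bisection to a 0.1 mV somatic EPSP from one basal synapse
(7.38×10⁻⁵ µS) and is used at all pyramid–pyramid synapses. NMDA-to-AMPA
ratios are peak-conductance ratios (control: 1.25 pyramidal, 0.5 FS, 0.8
RS; IS set to 1.0, the smallest grid value at which the IS cell fires
during the stimulus). The GABA_B-to-GABA_A ratio is defined on **unitary
somatic IPSP amplitudes**: because the slow conductance is not attenuated
by membrane filtering, a GABA_B conductance of 0.085× the GABA_A peak
already produces an equal-amplitude IPSP, and weights are scaled
accordingly. (Defining the ratio on peak conductances instead gives the
slow current ~18× the GABA_A charge and makes the delay state impossible at
the control ratio — the convention is a modelling choice the source text
does not pin down, and the IPSP-amplitude reading matches how such pairs
are measured.) Inhibitory weights follow the published chain: RS→PYR is
1/10 of FS→PYR, IS→PYR 1/10 of RS→PYR. Each FS cell carries one somatic
GABA_A autapse whose single-event IPSC is 0.35 nA at a −55 mV holding
potential (the source prints "0.35 mA", which is dimensionally implausible
for one synapse and is read as nA).

Voltage-clamp validation clamps every compartment of a passive copy of the
postsynaptic cell (the model analogue of pharmacological isolation) while
the presynaptic cell fires once; peak currents at −70 mV and +60 mV,
corrected for driving force and magnesium unblock, recover the configured
ratios to three decimals, and the NMDA share of the −70 mV EPSC is ~5%.

## Network assembly and manipulations

Connectivity is generated from per-pair synapse-count rules (pyramid
recurrent 24, pyramidal autapse 8, PYR→FS 12, PYR→RS 14, PYR→IS 7, FS→PYR
15 on the soma, RS→PYR 12 and IS→PYR 10 on the distal dendrite, IS→RS 2, FS
autapse 1), with every latency drawn from a Gaussian (1.7 ± 0.9 ms)
truncated at 0.1 ms for causality. Inhibitory synapses onto each pyramidal
cell are audited to stay below 13% of its excitatory count (thalamocortical
inputs included). Manipulations are pure functions of a control network:
knock-outs delete a population and all its synapses; `fs_scale` keeps
round(f·15) FS→PYR synapses per pair, drawn uniformly per pair with a
seeded generator; `fs_retarget` moves the FS projection to the basal (D0),
proximal (D1) or distal (D2) compartment with counts unchanged; the reverse
networks put two RS (or IS) cells on the somatic role with the 15/pair
count and one FS cell on the distal role with the 12/pair count, each
interneuron keeping its own unitary conductance.

Background noise injects brief somatic current transients (0.05 nA, 2 ms
decay) at Poisson times. The published rate constant (0.02; 0.035 for the
IS cell) is interpreted as events/ms by default — at the printed unit (Hz)
the mechanism would fire ~0.1 times per trial and generate no membrane
fluctuations, defeating its stated purpose; the printed-unit reading
remains selectable in the noise config.

## The persistent-activity protocol

Each trial delivers 120 AMPA+NMDA synapses to every pyramidal proximal
dendrite as 10 volleys at 20 Hz (onset 200 ms; unitary stimulus weight
1.5×10⁻⁴ µS, a free parameter calibrated for reliable ignition), then runs
to 5.2 s. A trial counts as induced when ≥75% of pyramidal cells fire above
2 Hz during the window 1–4 s after stimulus end — an operational criterion
chosen so that delay firing at 8–17 Hz outlasting the stimulus by seconds
classifies as induced and a silent network does not. Per-trial entropy
(noise event times, stimulus latency jitter) derives from the trial seed;
the network wiring derives from the network seed; both reproduce exactly.

**Delay-state mechanism.** The control delay state is a limit cycle near
20 Hz: a pyramidal volley recruits the FS pair, whose somatic GABA_A+GABA_B
volley silences the somata for tens of milliseconds, while NMDA plateaus in
the thin (2.5 µm) basal dendrites — electrically semi-decoupled from the
soma — hold the excitation across the silent phase; as inhibition decays
the somata fire again. Pyramidal cells participate in roughly every second
cycle (mean delay ISI ≈ 97 ms over 10 seeds), and the summed synaptic
currents oscillate at 20 Hz. Removing the FS population leaves the
saturated recurrent drive unopposed at the soma: the network then ignites
on every trial at every tested ratio and fires with ISIs near 14 ms. The
receptor-ratio maps reproduce the published structure — induction
probability increases with NMDA/AMPA, decreases with GABA_B/GABA_A, and the
ratio sensitivity disappears entirely in the FS knock-out. Below
NMDA/AMPA ≈ 0.9 the recurrent drive cannot sustain activity in any variant,
so knock-out claims are evaluated over the inducible span [0.875, 2.0].

## Analysis definitions

* **Binned ISI/CV**: intervals are assigned to the 500 ms bin containing
  their terminating spike; bins with fewer than two intervals are missing
  (NaN), not zero.
* **Desynchronization index**: the time-averaged multivariate
  SPIKE-distance, computed exactly — the pairwise profile is piecewise
  linear between merged spike times (with auxiliary edge spikes), so
  trapezoids over the corners integrate it without discretization error;
  the multivariate value is the mean over pairs. Zero for identical trains;
  larger for asynchronous firing.
* **Discrete-time rate**: population spike counts in 1 ms bins.
* **Spectrum**: the summed AMPA+NMDA+GABA_A current over the pyramidal
  population, taken from a 1 s window starting 3 s after stimulus end,
  mean-subtracted, FIR-decimated to 1 kHz, transformed with a plain
  (untapered) periodogram and averaged over 10 trials; the headline
  quantity is the frequency of the global maximum above 5 Hz.

## Numerical scheme

Gates advance by their exact exponential update at the held voltage (hence
the two-half-steps-equal-one-step identity holds to machine precision); the
calcium pool advances analytically; ionic and synaptic conductances are
then frozen and the linear cable system is solved per cell by Hines
elimination (parents ordered before children), giving an unconditionally
stable semi-implicit step. Synaptic events propagate through a ring buffer
with spike times quantized to the step grid — determinism is preferred over
sub-step interpolation. Spikes are upward 0 mV crossings with a 2 ms
lockout, linearly interpolated in time. Voltage clamp is a stiff series
conductance (20 µS) rather than an algebraic constraint, keeping a single
integrator path. Halving dt moves subthreshold traces by ≪0.5 mV RMS and
spike times by well under 1 ms.

## Problem sizes

The shipped defaults are desk-scale: network statistics (delay ISI,
knock-out ISI, spectra) use 10 seeded trials of 5.2 s; probability maps use
reduced grids (3×3) at 2–10 trials per point, with Wilson intervals
reported per point. The trial counts and grid extents are configuration
parameters; nothing in the code depends on them.

## Known limitations

* **Firing-variability ordering.** In the source study the ISI coefficient
  of variation is higher during persistent activity than during the
  stimulus. This implementation inverts that ordering: the delay state is a
  paced limit cycle (CV ≈ 0.1–0.15) while the stimulus response is
  burst-locked to the 20 Hz drive (CV ≈ 0.5–0.7). An asynchronous-irregular
  delay state that would raise the delay CV could not be reconciled with
  the hard ISI band, the knock-out ISI and the 20 Hz spectral peak under
  this cell calibration; the corresponding test documents the deviation by
  failing.
* The IS cell fires only a single spike during the standard stimulus at
  its default NMDA ratio — enough to satisfy the letter of its constraint,
  but its disinhibitory influence on the RS pathway is weak.
* Reverse-network and retargeting phenotypes are reproduced at trend level
  (probability 1.0, shortened ISIs, in the directions reported), not as
  quantitative matches; the same applies to the knock-out networks of RS
  and IS, whose delay statistics stay inside the control band.
* No short-term plasticity, receptor desensitization, stochastic gating or
  temperature corrections; trial-to-trial variability comes only from the
  seeded noise and latency draws.
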