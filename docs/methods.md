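# Methods

This note documents the models, the operational definitions behind each
measurement, the synthetic-data generator's assumptions, and the numeric
choices that were genuinely open. Units throughout: mV, pA, ms, pF, MΩ;
charge in pA·ms (1 pA·s = 1000 pA·ms); conductances in nS, so
I = g·(V−E) is in pA and dV/dt = I/C in mV/ms.

## Feature extraction

**Spike detection.** AP threshold is the first sample of a rising
excursion where the centred-difference dV/dt reaches 15 mV/ms; the peak is
the subsequent voltage maximum, and no new spike is accepted until the
trace falls back below the previous threshold voltage. The derivative is
taken on the raw trace: at 10 kHz sampling and the voltage noise levels
considered here (≤1 mV), centred differences stay well below the
criterion between spikes, so no pre-smoothing is applied.

**Passive properties.** R_in and C_m come from the averaged −5 mV
seal-test response: R_in = |ΔV/ΔI_ss| with the steady state taken over
the final 20 % of the step, and C_m = |Q/ΔV| with Q the integral of the
leak-subtracted transient over the first 20 % of the step. Charge
integration was chosen over a single-exponential fit because it does not
require the clamp time constant to be resolvable at the acquisition rate;
the short integration window keeps the baseline/plateau estimation error
(which multiplies by the window length) out of the charge. Both
estimates are accurate to ≲5 % over R_in ∈ [100, 600] MΩ,
C_m ∈ [5, 25] pF with 1 MΩ access resistance (verified in the acceptance
suite).

**AP waveform.** Amplitude is peak − threshold; AHP amplitude is trough −
threshold (negative by convention, e.g. −19 mV); rise is the time from
the upward threshold crossing to the peak; base width is the time spent
above the threshold voltage (sub-sample interpolated); the AHP trough is
searched from the peak to the next spike, the end of the step, or 200 ms
after threshold, whichever comes first (the cap avoids step-offset
artifacts). The threshold *value* is conventionally taken from the
rheobase response while the waveform comes from the first AP at
rheobase + 40 pA.

**Discharge metrics.** Adaptation = last / first instantaneous frequency;
attenuation = last / first AP amplitude × 100 %. Both are undefined (and
flagged) with fewer than two spikes. Mean frequency is the spike count
over the 1 s step.

**Spontaneous activity.** Over ≥60 s of passive recording: *none* with no
spikes; *bursting* with ≥2 clusters of ≥3 spikes (intra-burst ISI
< 100 ms) separated by >1 s silences; *tonic* if the ISI coefficient of
variation is < 0.5; otherwise *irregular*. The burst thresholds are
declared constants — the taxonomy in the literature is qualitative.

## Discharge classification

The classifier reads the rheobase + 40 pA response and applies rules
most-specific first: RF → SS → GF → IB → P → DF → TF. Operational
thresholds (all module constants, overridable):

- **RF**: no spikes at any step, but the step family repeated from a
  depolarised holding potential (−50 mV, inactivating the resting A-type
  conductance) does fire.
- **SS**: exactly one spike at the evaluation step and never more than
  one at any suprathreshold step.
- **GF**: first spike within 50 ms of onset, ≥2 later spikes, and a first
  ISI more than 3× the median of the later ISIs.
- **IB**: ≥2 spikes within the first 100 ms with mean intra-burst ISI
  < 40 ms and no spikes in the final half of the step.
- **P**: ≥2 discharge episodes separated by silent gaps >3× the median
  ISI, excluding the single onset-gap geometry already claimed by GF.
- **DF**: first-spike latency >100 ms with a positive (depolarising) ramp
  slope fitted to the pre-spike voltage.
- **TF**: discharge duration ≥80 % of the step. TF also serves as the
  residual class when nothing more specific matches (flagged in the
  evidence), so every spiking cell receives exactly one label.

**AHP profiles.** On the segment from the AP peak to the AHP trough:
*ADP* if a local voltage maximum with ≥0.5 mV prominence appears after
the fall crosses threshold; *slowed* if, without such a maximum, dV/dt
has a prominent local maximum (a shoulder) in the falling phase;
*monophasic* otherwise. An ADP whose trough continues ≥0.5 mV below the
pre-bump minimum is flagged as riding on a slow hyperpolarisation.

**Depolarising hump.** On the spike-clipped rheobase response (clip 1 ms
before to 6 ms after each threshold, gaps interpolated), a hump is called
when the early-half envelope maximum exceeds the late-step envelope
maximum by ≥2 mV. Maxima are compared against the *late envelope
maximum* rather than a mean plateau so the pre-spike approach of a
tonically firing cell (which reaches the same level early and late) does
not register.

## Subthreshold currents

P/N subtraction (P/4 by default — the protocol description does not fix
N) references the test sweep and each 1/4-scaled subsweep to their
pre-step baselines, so any linear component cancels identically. On the
corrected −40 mV response the dominant transient is located on a 5 ms
boxcar-smoothed copy (the extreme of ~2000 raw samples would otherwise be
noise-dominated), then the peak index is refined on the raw trace within
± one smoothing window, which removes the argmax bias smoothing induces
on asymmetric peaks. Classification: outward with latency < 15 ms →
fast A-type; outward at ≥ 15 ms → slow A-type (the boundary is strict,
so exactly 15.0 ms is slow); inward → T-type-like; |peak| below 4× the
baseline sd (estimated on the raw 50 ms pre-step window and rescaled by
√w for the smoothed trace) → NC. H-current sag is measured on the *raw*
hyperpolarising response — the P/N subsweeps partially activate the sag
themselves and would cancel it — as the early plateau (20–100 ms) minus
the end-of-step mean, present when a monotone inward development exceeds
3 baseline sd.

## Synaptic event detection

The sliding-template scan fits `scale·template + offset` at every offset
by least squares (rolling sums via convolution, O(n log n)) and forms the
criterion scale/SE(scale). The template is an inward difference of
exponentials (rise 0.5 ms, decay 4 ms) truncated at three decay
constants so the fit stays local. Detections are criterion local maxima
above threshold with a dead time of half the template length and a
prominence requirement equal to the threshold, which rejects secondary
maxima on the criterion shoulder of an already-found event. Two guards
handle degenerate geometry: a detection must be consistent with the
actual inward deflection of the (1 ms-smoothed) trace — scale within
[0.2, 2.5]× the deflection depth — which excludes outward waveforms whose
flanks correlate with the template tail at near-zero residual; and a
second pass subtracts fitted events and rescans only the criterion
shadow of existing detections (1 ms to 0.9 template lengths), recovering
events hidden by a larger neighbour's dead time or prominence shadow
while refusing subtraction residuals (whose scales fall far below the
detected population).

The default criterion threshold is 4.5. On Gaussian noise the criterion
is approximately standard normal per sample, so a 300 000-sample sweep at
the commonly quoted 3.5 produces tens of false crossings; 4.5 keeps the
expected count below about one per 30 s, which is what the detection
precision targets require. With these settings, planted Poisson trains
(1–10 Hz, −20 ± 5 pA, noise sd ≤ 5 pA) are recovered with ≥97 % recall
and precision, and noiseless planted events are found exactly.

Event statistics are measured on the onset-aligned average: baseline =
mean of the 2 ms before onset; amplitude = baseline to peak; rise =
10–90 %; decay τ by log-linear least squares over the 10–90 % decay
span; charge = |area| between average and baseline; drive = charge ×
frequency (an identity by construction).

## Clustering

Features are min–max normalised before Euclidean distances — matching
the heatmap convention and preventing unit dominance — and Ward linkage
is computed on the normalised matrix (singleton-pair height = Euclidean
distance; the tree is verified against a brute-force SSE-greedy oracle).
The cluster number is the deepest cut k such that no per-sample
silhouette is negative at any cut ≤ k while the k+1 cut contains one;
if no negative appears up to kmax = 8, the mean-silhouette maximiser is
reported with an explicit fallback flag, and a negative already at k = 2
reports a single supported cluster. The default 20-feature panel covers
passive, AP-waveform, discharge and synaptic measures; categorical calls
(discharge pattern, AHP profile) are annotations, not distance features.
Dendrograms serialise to Newick with ultrametric midpoint branch lengths
(node at half its merge height).

## The synthetic generator

A single-compartment conductance model supplies every input with ground
truth: leak; Na⁺/K⁺ spike currents; fast and slow inactivating A-type K⁺
currents; a transient low-threshold Ca²⁺ current; an H current; and a
slow activity-dependent suppression current (K⁺-reversal, activating
during spikes with a 50 ms rise and a preset-specific decay). All gates
relax to Boltzmann steady states with fixed time constants; integration
is fixed-step RK4 at 0.01 ms internally, decimated to the 0.1 ms output
grid, with seeded Ornstein–Uhlenbeck current noise (τ 20 ms) calibrated
so the quasi-static voltage sd matches the requested noise level. In
voltage clamp the command is piecewise constant, so gate trajectories
and currents are evaluated in closed form; capacitive transients are
confined to the step-edge sample.

The seven discharge presets realise their qualitative definitions
through the expected mechanisms — slow A-type activation for the gap,
fast A-type inactivation for the delay, the Ca²⁺ transient for the onset
burst, strong non-recovering suppression for single spiking, weak
oscillatory suppression for phasic episodes, and a large A-type
conductance (relieved at depolarised holding) for reluctant firing. No
quantitative channel data constrain these presets; they are tuned only
until each cell expresses its definition robustly across seeds, and the
classifier recovers every preset in ≥90 % of seeds at 0.5 mV noise.

The seal-test generator is an analytic RC response behind a 1 MΩ access
resistance whose samples are *bin averages* of the continuous current,
emulating the anti-alias filtering of an acquisition chain and making
the capacitive charge exactly integrable at 10 kHz. EPSC traces are
Poisson trains of difference-of-exponential events with Gaussian
amplitudes and additive white noise. Feature tables plant Gaussian
clusters whose centroids sit on a binary tree (offsets along orthogonal
sign patterns spanning all features, halving with depth; the closest
pair exactly `separation` apart): coarser cuts of the planted partition
are then themselves cohesive, the nested group/cluster structure typical
of cell-type cohorts, and the silhouette rule recovers k ∈ {2, 3, 4}
with a perfect partition in ≥95 % of seeds at separation 8× the
within-cluster sd in 10 features.

What the generator does *not* emulate: electrode series-resistance and
bridge artifacts, dendritic filtering, correlated (non-white) recording
noise, channel stochasticity, and biological covariance between features
(cluster tables are isotropic Gaussians). Passing the validation suite
therefore demonstrates that the measurement definitions are implemented
correctly and are robust at realistic noise levels — not that the
classifier thresholds would transfer unchanged to recordings with
qualitatively different artifacts.

## Statistics and junction potential

Student's pooled-variance t is the default (Welch by flag); χ² is
Pearson's without continuity correction, warning when an expected count
falls below 5; ANOVA is the standard one-way F with Tukey HSD pairwise
p values; no further multiplicity correction is applied. Percentages
round to integer or one decimal per the caller.

The junction potential uses the generalised Henderson equation with
limiting equivalent conductivities (25 °C values from standard
compilations; gluconate, HEPES, EGTA and nucleotides from the
junction-potential literature — gluconate dominates the result) bundled
as a user-overridable CSV. Recipes dissociate through a small salt
dictionary; HEPES contributes its pH 7.3 anionic fraction (pKa 7.5),
EGTA enters as a divalent anion, Mg-ATP as Mg²⁺ + ATP²⁻, Na-GTP as
3 Na⁺ + GTP³⁻, and a KOH entry adds the K⁺ required for
electroneutrality (checked to 5 %, slack for the CO₂/bicarbonate
system). Only RT/F varies with temperature; mobility ratios are treated
as temperature-independent. For the potassium-gluconate internal against
the recording ACSF this yields +15.1 mV at 295.15 K (bath positive, the
sign in which the correction is conventionally quoted), within 1 mV of
the commonly calculated value for these solutions; residual spread of
this size is expected across mobility-table choices.

## Problem sizes

The validation battery uses 20 seeds per discharge phenotype (11-step
families at 1 s per step), 20 seeds per subthreshold class, 60 planted
feature tables of 80–160 cells, 5 × 30 s synaptic traces, a 5 × 4 grid
of seal-test cells, and 100 random Ward instances of up to 8 points —
sizes at which every recovery statistic stabilises while the whole suite
runs in a few minutes on one core.
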