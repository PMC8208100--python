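# spinephys

Patch-clamp analysis for spinal dorsal horn projection neurons: trace-level
feature extraction, rule-based firing-pattern classification, and
unsupervised clustering of electrophysiological phenotypes.

Projection neurons — in particular spinoparabrachial neurons (SPBNs) of
lamina I and the deeper laminae III–V — are the output stage of the spinal
pain circuit. Characterising them in whole-cell recordings means reducing
each cell to a reproducible panel of numbers (passive membrane properties,
action-potential waveform metrics, discharge statistics, subthreshold
voltage-activated currents, spontaneous synaptic input) and then asking
whether the population splits into discrete classes. `spinephys`
implements that entire reduction as a tested, scriptable pipeline, plus a
synthetic data generator with known ground truth so every stage can be
validated end-to-end.

## What it computes

**Membrane and AP features** (current clamp, 1 s depolarising steps in
20 pA increments from −70 mV):

- spike detection at the dV/dt = 15 mV/ms threshold criterion;
- R_in and C_m from averaged −5 mV seal-test responses (Ohm's law on the
  steady state; charge integration of the capacitive transient);
- resting potential from ≥30 s of passive recording, spike windows masked;
- rheobase; first-spike latency; ISIs and instantaneous frequencies;
  discharge duration; adaptation (last/first instantaneous frequency) and
  attenuation (last/first AP amplitude, %);
- AP threshold, peak amplitude, rise time, base width, AHP amplitude and
  latency, measured on the first AP of the rheobase + 40 pA response.

**Discharge classification.** Seven patterns assigned from the
rheobase + 40 pA response by explicit rules, most-specific first:
reluctant (RF, requires a retest from depolarised holding), single
spiking (SS), gap firing (GF), initial bursting (IB), phasic (P), delayed
(DF), tonic (TF). AHP profiles (monophasic / afterdepolarisation /
slowed repolarisation) and the subthreshold depolarising hump are called
from the same sweeps.

**Subthreshold currents** (voltage clamp, −70 → −100 mV for 1 s then
−40 mV for 200 ms, P/N leak subtraction): the dominant transient is
classified as fast A-type (outward, latency to peak < 15 ms), slow A-type
(outward, ≥ 15 ms), T-type-like (inward) or no current, with peak,
latency and half-decay measurements; H-current sag is detected on the
hyperpolarising step.

**Spontaneous EPSCs**: sliding-template detection (optimally scaled
template, criterion = scale / SE) over ≥30 s at −70 mV; averaged-event
amplitude, 10–90 % rise, decay τ, charge (pA·ms) and excitatory drive
(charge × frequency).

**Clustering**: per-cell feature matrix (default 20-feature panel,
median-imputed), min–max normalisation, Euclidean/Ward hierarchical
clustering with the silhouette rule for the cluster number (deepest cut
before a per-sample silhouette goes negative), Newick dendrogram export
and per-cluster identity purity.

**Statistics**: unpaired t tests (pooled or Welch), Pearson χ², one-way
ANOVA with Tukey HSD, count-to-percentage reporting.

**Liquid junction potential**: generalised Henderson equation

V = (RT/F) · [Σᵢ sgn(zᵢ) λᵢ Δcᵢ / Σᵢ |zᵢ| λᵢ Δcᵢ] · ln(Σᵢ |zᵢ| λᵢ cᵢᵖ / Σᵢ |zᵢ| λᵢ cᵢᵇ)

with bundled limiting equivalent conductivities λᵢ, recipe dissociation
(K-gluconate internals, bicarbonate ACSF) and per-ion breakdown.

## Worked example

```python
from spinephys.pipeline import make_synthetic_cell, extract_cell_features

record, truth = make_synthetic_cell(
    "demo", phenotype="GF", current_class="KA_slow", seed=4)
features, calls = extract_cell_features(record)

print("discharge pattern :", calls["discharge"])
print("subthreshold class:", calls["subthreshold"])
print("Rin  = %.1f MOhm" % features["rin_mohm"])
print("Cm   = %.1f pF" % features["cm_pf"])
print("RMP  = %.1f mV" % features["rmp_mv"])
print("rheobase = %.0f pA" % features["rheobase_pa"])
```

prints

```
discharge pattern : GF
subthreshold class: KA_slow
Rin  = 301.0 MOhm
Cm   = 12.9 pF
RMP  = -65.4 mV
rheobase = 100 pA
```

The generator planted a gap-firing neuron (a slow A-type conductance
holds the cell silent after its onset spike until the current
inactivates) with a slow A-type subthreshold profile, 300 MΩ input
resistance and 13 pF capacitance; the extraction recovers all of it from
the raw sweeps alone. `truth` carries the planted labels and spike times
for validation.

The same pipeline runs from the shell:

```
spinephys simulate --phenotype cohort --n 5 --seed 1 --out bundles/
spinephys extract bundles/* --out features.json
spinephys cluster features.json --out-prefix clusters
spinephys report features.json --out report.md
spinephys ljp --temperature-c 22
```

Cell bundles are plain directories: one `metadata.json` (identity,
lamina, slice plane, per-group units/dt/epochs) plus one CSV matrix per
protocol group (rows = samples, columns = sweeps), written with
round-trip-exact float formatting. Protocol groups: `step_family`,
`step_family_retest`, `passive_neg5mV`, `passive_60s`, `subthreshold_VC`,
`subthreshold_VC_leak`, `sepsc_VC`. Files in the NWB 2 HDF5 layout can be
ingested via `spinephys.core.ingest_nwb`.

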