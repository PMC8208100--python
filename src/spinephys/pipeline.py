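"""End-to-end per-cell analysis and synthetic cohort assembly.

``extract_cell_features`` runs every extraction stage a cell's protocol
groups support and returns the flat feature record used by the clustering
panel, together with the categorical calls (discharge pattern, AHP
profile, subthreshold current class, spontaneous activity).
``make_synthetic_cell`` assembles a full synthetic recording session for
one model neuron, which is how cohorts with known ground truth are built.
"""

from __future__ import annotations

import numpy as np

from . import discharge as disc
from . import membrane as mem
from . import sepsc as sep
from . import subthreshold as sub
from . import synthetic as syn
from .core import CellRecord

__all__ = ["extract_cell_features", "make_synthetic_cell", "generate_cohort"]


def extract_cell_features(record: CellRecord) -> tuple[dict, dict]:
    """Extract the full feature record and categorical calls for one cell.

    Stages whose protocol group is absent are skipped; their features stay
    NaN and are later median-imputed by the feature-table assembly.
    """
    feats: dict[str, float] = {}
    calls: dict[str, str] = {}

    if "passive_neg5mV" in record.sweeps:
        rin, cm = mem.measure_passive(record.sweeps["passive_neg5mV"])
        feats["rin_mohm"], feats["cm_pf"] = rin, cm

    spont_spikes = None
    if "passive_60s" in record.sweeps:
        sw = record.sweeps["passive_60s"][0]
        train = mem.detect_spikes(sw)
        spont_spikes = train
        feats["rmp_mv"] = mem.measure_rmp(sw, train)
        calls["spontaneous"] = mem.classify_spontaneous(
            train.threshold_times, sw.duration_ms
        )

    if "step_family" in record.sweeps:
        sweeps = record.sweeps["step_family"]
        trains = [mem.detect_spikes(sw) for sw in sweeps]
        rheo = mem.find_rheobase(sweeps, trains)
        retest_train = None
        if "step_family_retest" in record.sweeps:
            retest_train = mem.detect_spikes(record.sweeps["step_family_retest"][0])
        call = disc.classify_discharge(sweeps, trains, rheo.index, retest_train)
        calls["discharge"] = call.pattern
        if rheo.index is not None:
            feats["rheobase_pa"] = rheo.rheobase_pa
            ev = rheo.index + 2
            if ev < len(sweeps) and len(trains[ev]) >= 1:
                sweep, train = sweeps[ev], trains[ev]
                thr = float(trains[rheo.index].threshold_voltages[0])
                wf = mem.ap_waveform_features(sweep, train, 0, threshold_mv=thr)
                feats["ap_threshold_mv"] = wf.threshold_mv
                feats["ap_peak_amplitude_mv"] = wf.peak_amplitude_mv
                feats["ap_rise_ms"] = wf.rise_time_ms
                feats["ap_base_width_ms"] = wf.base_width_ms
                feats["ahp_amplitude_mv"] = wf.ahp_amplitude_mv
                feats["ahp_latency_ms"] = wf.ahp_latency_ms
                m = mem.discharge_metrics(train, sweep.step_epoch())
                feats["first_spike_latency_ms"] = m.first_spike_latency_ms
                feats["mean_frequency_hz"] = m.mean_frequency_hz
                if m.instantaneous_freqs_hz.size:
                    feats["mean_inst_frequency_hz"] = float(
                        np.mean(m.instantaneous_freqs_hz))
                feats["adaptation"] = m.adaptation
                feats["attenuation_pct"] = m.attenuation_pct
                feats["discharge_duration_ms"] = m.discharge_duration_ms
                ahp_label, _ = disc.classify_ahp_profile(sweep, train, 0)
                calls["ahp_profile"] = ahp_label
            calls["hump"] = str(disc.detect_depolarizing_hump(
                sweeps[rheo.index], trains[rheo.index]))

    if "subthreshold_VC" in record.sweeps:
        test = record.sweeps["subthreshold_VC"][0]
        subs = record.sweeps.get("subthreshold_VC_leak", [])
        corrected = sub.pn_leak_subtract(test, subs) if subs else test
        prof = sub.classify_subthreshold(corrected)
        calls["subthreshold"] = prof.current_class
        feats["subthreshold_peak_pa"] = prof.peak_amplitude_pa
        try:
            # Ih is read from the raw hyperpolarising response: P/N
            # subsweeps activate part of the sag themselves and would
            # cancel it from the corrected trace
            present, amp = sub.detect_ih(test)
            calls["ih"] = str(present)
            if present:
                feats["ih_amplitude_pa"] = amp
        except Exception:
            pass

    if "sepsc_VC" in record.sweeps:
        sw = record.sweeps["sepsc_VC"][0]
        times = sep.sliding_template_detect(sw)
        st = sep.event_statistics(times, sw)
        feats["sepsc_frequency_hz"] = st.frequency_hz
        feats["sepsc_amplitude_pa"] = st.mean_amplitude_pa
        feats["sepsc_tau_ms"] = st.decay_tau_ms
        feats["sepsc_charge_pa_ms"] = st.charge_pa_ms
        feats["sepsc_drive_pa_ms_hz"] = st.drive_pa_ms_hz

    return feats, calls


def make_synthetic_cell(
    cell_id: str,
    phenotype: str = "TF",
    current_class: str | None = None,
    identity: str = "SPBN",
    lamina: str = "LI",
    seed: int = 0,
    sepsc_duration_s: float = 30.0,
    passive_duration_s: float = 30.0,
    event_spec: syn.EventTrainSpec | None = None,
) -> tuple[CellRecord, dict]:
    """Assemble a full synthetic recording session for one model neuron."""
    rng = np.random.default_rng(seed)
    spec = syn.preset(phenotype)
    record = CellRecord(cell_id=cell_id, identity=identity, lamina=lamina)
    truth: dict = {"discharge_class": phenotype}

    sweeps, gt = syn.simulate_current_clamp(spec, seed=int(rng.integers(2**31)))
    record.add_sweeps("step_family", sweeps)
    truth["spike_times"] = gt.spike_times
    record.add_sweeps("step_family_retest",
                      [syn.simulate_retest(spec, seed=int(rng.integers(2**31)))])

    record.add_sweeps("passive_neg5mV", syn.simulate_seal_test(
        cm_pf=spec.cm_pf, rin_mohm=spec.rin_mohm, seed=int(rng.integers(2**31))))
    record.add_sweeps("passive_60s", [syn.simulate_passive_cc(
        spec, duration_s=passive_duration_s, seed=int(rng.integers(2**31)))])

    if current_class is not None:
        vc_spec = syn.CURRENT_CLASS_PRESETS[current_class]
        test, subs, vgt = syn.simulate_voltage_clamp(
            vc_spec, seed=int(rng.integers(2**31)), current_class=current_class)
        record.add_sweeps("subthreshold_VC", [test])
        record.add_sweeps("subthreshold_VC_leak", subs)
        truth["current_class"] = current_class

    espec = event_spec or syn.EventTrainSpec(duration_s=sepsc_duration_s)
    esweep, egt = syn.synthesize_epsc_trace(espec, seed=int(rng.integers(2**31)))
    record.add_sweeps("sepsc_VC", [esweep])
    truth["event_times_ms"] = egt.event_times_ms
    truth["event_amplitudes_pa"] = egt.event_amplitudes_pa
    return record, truth


def generate_cohort(
    composition: dict[str, int],
    seed: int = 0,
    **cell_kwargs,
) -> tuple[list[CellRecord], list[dict]]:
    """Generate a cohort: ``composition`` maps phenotype name -> cell count."""
    rng = np.random.default_rng(seed)
    records, truths = [], []
    i = 0
    for phenotype, count in composition.items():
        for _ in range(count):
            rec, truth = make_synthetic_cell(
                f"{phenotype}_{i:03d}", phenotype=phenotype,
                seed=int(rng.integers(2**31)), **cell_kwargs)
            records.append(rec)
            truths.append(truth)
            i += 1
    return records, truths
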