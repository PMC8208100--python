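"""Rule-based classification of AP discharge patterns and AHP profiles.

Seven discharge patterns are assigned from the step-family response
evaluated two steps above rheobase (rheobase + 40 pA): tonic (TF), delayed
(DF), gap (GF), initial bursting (IB), single spiking (SS), phasic (P) and
reluctant firing (RF).  The published definitions are qualitative; the
numeric thresholds used to operationalise them are module constants,
declared below and surfaced through keyword arguments.  Rules are applied
most-specific first: RF, SS, GF, IB, P, DF, TF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .core import ProtocolError, Sweep
from .membrane import SpikeTrain, detect_spikes, find_rheobase

__all__ = [
    "DischargeCall",
    "classify_discharge",
    "classify_ahp_profile",
    "detect_depolarizing_hump",
]

# operational thresholds (the source definitions are qualitative)
DF_MIN_LATENCY_MS = 100.0     # delayed firing: first spike later than this
GF_ONSET_MS = 50.0            # gap firing: first spike within this of onset
GF_GAP_RATIO = 3.0            # first ISI exceeds this multiple of later ISIs
IB_BURST_WINDOW_MS = 100.0    # initial burst confined to this onset window
IB_MAX_BURST_ISI_MS = 40.0
TF_MIN_DURATION_FRAC = 0.80   # tonic: discharge spans this fraction of step
P_GAP_RATIO = 3.0             # phasic: silent gaps exceed this multiple of the median ISI
HUMP_MIN_MV = 2.0             # depolarising hump criterion above late plateau


@dataclass
class DischargeCall:
    pattern: str
    evidence: dict = field(default_factory=dict)


def _episodes(isis: np.ndarray, gap_ratio: float) -> tuple[int, np.ndarray]:
    med = float(np.median(isis))
    big = isis > gap_ratio * med
    return int(np.sum(big)) + 1, big


def classify_discharge(
    step_sweeps: list[Sweep],
    spike_trains: list[SpikeTrain] | None = None,
    rheobase_index: int | None = None,
    retest_train: SpikeTrain | None = None,
) -> DischargeCall:
    """Assign one of the seven discharge patterns.

    ``step_sweeps`` must be ordered by step amplitude; the evaluation sweep
    is two steps above rheobase.  ``retest_train`` are the spikes of the
    step protocol repeated from a depolarised holding potential, required
    to call reluctant firing.  Deterministic given the sweeps.
    """
    if spike_trains is None:
        spike_trains = [detect_spikes(sw) for sw in step_sweeps]
    if rheobase_index is None:
        rheo = find_rheobase(step_sweeps, spike_trains)
        rheobase_index = rheo.index
    counts = [len(tr) for tr in spike_trains]

    # RF: no discharge anywhere despite sustained depolarisation, but the
    # retest from a depolarised holding potential does fire
    if rheobase_index is None:
        if retest_train is not None and len(retest_train) >= 1:
            return DischargeCall("RF", {"retest_spikes": len(retest_train)})
        raise ProtocolError(
            "cell never fired and no depolarised-holding retest was provided"
        )

    eval_index = rheobase_index + 2
    if eval_index >= len(step_sweeps):
        raise ProtocolError("rheobase + 40 pA evaluation sweep missing from the family")
    sweep = step_sweeps[eval_index]
    train = spike_trains[eval_index]
    step = sweep.step_epoch()
    ev: dict = {"eval_index": eval_index, "n_spikes": len(train)}

    if len(train) == 0:
        # fired at rheobase but not two steps above: treat as reluctant if the
        # retest fired, otherwise single spiking at threshold only
        if retest_train is not None and len(retest_train) >= 1:
            return DischargeCall("RF", {**ev, "retest_spikes": len(retest_train)})
        return DischargeCall("SS", {**ev, "note": "no spikes at evaluation step"})

    rel = train.threshold_times - step.start_ms
    latency = float(rel[0])
    ev["first_spike_latency_ms"] = latency

    # SS: exactly one spike at the evaluation step and never more than one
    # spike at any suprathreshold step
    if len(train) == 1 and all(c <= 1 for c in counts[rheobase_index:]):
        return DischargeCall("SS", ev)

    if len(train) == 1:
        # single spike here but multiple elsewhere: fall through on latency
        if latency > DF_MIN_LATENCY_MS:
            return DischargeCall("DF", ev)
        return DischargeCall("SS", {**ev, "note": "single spike at evaluation step"})

    isis = np.diff(train.peak_times)
    dur = float(train.peak_times[-1] - train.peak_times[0])
    ev["discharge_duration_frac"] = dur / step.duration_ms

    # GF: onset spike, long first gap, then resumed discharge
    if latency <= GF_ONSET_MS and isis.size >= 3:
        later = isis[1:]
        ev["first_isi_ratio"] = float(isis[0] / np.median(later))
        if isis[0] > GF_GAP_RATIO * np.median(later):
            return DischargeCall("GF", ev)

    # IB: burst at onset then silence over the late half of the step
    onset = rel[rel <= IB_BURST_WINDOW_MS]
    late_half = rel[rel > step.duration_ms * 0.5]
    if onset.size >= 2 and late_half.size == 0:
        burst_isis = np.diff(onset)
        ev["burst_mean_isi_ms"] = float(np.mean(burst_isis))
        if np.mean(burst_isis) < IB_MAX_BURST_ISI_MS:
            return DischargeCall("IB", ev)

    # P: two or more discharge episodes separated by long silent gaps,
    # excluding the single onset-gap geometry of GF
    n_ep, big = _episodes(isis, P_GAP_RATIO)
    ev["n_episodes"] = n_ep
    if n_ep >= 2:
        only_onset_gap = big.sum() == 1 and big[0]
        if not only_onset_gap:
            return DischargeCall("P", ev)

    # DF: long latency with a monotone depolarising ramp before the first spike
    if latency > DF_MIN_LATENCY_MS:
        i0 = int((step.start_ms + 10.0) / sweep.dt)
        i1 = int(train.threshold_times[0] / sweep.dt) - int(2.0 / sweep.dt)
        if i1 - i0 > 10:
            t = np.arange(i0, i1) * sweep.dt
            slope = float(np.polyfit(t, sweep.samples[i0:i1], 1)[0])
            ev["ramp_slope_mv_per_ms"] = slope
            if slope > 0:
                return DischargeCall("DF", ev)

    # TF: sustained discharge spanning most of the step
    if dur >= TF_MIN_DURATION_FRAC * step.duration_ms:
        return DischargeCall("TF", ev)
    ev["note"] = "residual assignment"
    return DischargeCall("TF", ev)


def classify_ahp_profile(
    sweep: Sweep,
    train: SpikeTrain | None = None,
    which: int = 0,
    min_window_ms: float = 50.0,
    adp_prominence_mv: float = 0.5,
    slowed_prominence: float = 1.0,
) -> tuple[str, dict]:
    """Classify the repolarisation/AHP profile of one AP.

    ADP when a local depolarising maximum lies between the fast
    repolarisation and the AHP trough; slowed when the falling phase has a
    shoulder (a prominent local maximum of dV/dt without a voltage maximum);
    monophasic otherwise.  Returns ``(label, evidence)``.
    """
    if train is None:
        train = detect_spikes(sweep)
    if len(train) == 0:
        raise ValueError("no spike to classify")
    dt = sweep.dt
    v = sweep.samples
    i_pk = int(round(train.peak_times[which] / dt))
    limits = [sweep.duration_ms]
    if which + 1 < len(train):
        limits.append(train.threshold_times[which + 1])
    limits.append(train.threshold_times[which] + 200.0)
    i_end = min(int(min(limits) / dt), v.size)
    if (i_end - i_pk) * dt < min_window_ms and which + 1 >= len(train):
        return "undefined", {"flag": "truncated post-peak window"}
    seg = v[i_pk:i_end]
    i_tr = int(np.argmin(seg))
    ev: dict = {"trough_latency_ms": i_tr * dt}
    fall = seg[: i_tr + 1]
    thr_v = train.threshold_voltages[which]
    # consider only the stretch after the fast repolarisation (below threshold)
    below = np.flatnonzero(fall < thr_v)
    start = int(below[0]) if below.size else 0
    peaks, props = find_peaks(fall[start:], prominence=adp_prominence_mv)
    if peaks.size:
        i_adp = start + int(peaks[np.argmax(props["prominences"])])
        ev["adp_time_ms"] = i_adp * dt
        ev["adp_voltage_mv"] = float(fall[i_adp])
        # an ADP riding on a continuing slow hyperpolarisation: the trough
        # lies clearly below the voltage from which the bump departed
        pre_min = float(np.min(fall[start:i_adp])) if i_adp > start else float(fall[start])
        ev["on_slow_ahp"] = bool(fall[i_tr] < pre_min - 0.5)
        return "ADP", ev
    dvdt_fall = np.gradient(fall, dt)
    sp, _ = find_peaks(dvdt_fall[1:-1], prominence=slowed_prominence)
    if sp.size:
        ev["shoulder_time_ms"] = float((sp[0] + 1) * dt)
        return "slowed", ev
    return "monophasic", ev


def detect_depolarizing_hump(
    sweep: Sweep,
    train: SpikeTrain | None = None,
    min_hump_mv: float = HUMP_MIN_MV,
    clip_pre_ms: float = 1.0,
    clip_post_ms: float = 6.0,
) -> bool:
    """True when the spike-clipped subthreshold envelope of the rheobase
    response shows an early maximum at least 2 mV above the late-step
    envelope.

    Spikes are clipped asymmetrically (1 ms before threshold to 6 ms after,
    covering the spike and fast repolarisation) and the gap interpolated.
    Comparing the early envelope maximum against the *late* envelope
    maximum (rather than a mean plateau) keeps the pre-spike approach of a
    tonically firing cell from masquerading as an onset hump: that approach
    reaches the same level early and late, whereas a genuine hump rides
    only on the step onset.
    """
    if train is None:
        train = detect_spikes(sweep)
    step = sweep.step_epoch()
    dt = sweep.dt
    v = sweep.samples.copy()
    keep = np.ones(v.size, dtype=bool)
    for t in train.threshold_times:
        i0 = max(0, int((t - clip_pre_ms) / dt))
        i1 = min(v.size, int((t + clip_post_ms) / dt) + 1)
        keep[i0:i1] = False
    idx = np.arange(v.size)
    if not keep.all():
        v = np.interp(idx, idx[keep], v[keep])
    i_on = int(step.start_ms / dt)
    i_off = int(step.end_ms / dt)
    early = v[i_on: i_on + (i_off - i_on) // 2]
    late = v[i_off - max(1, (i_off - i_on) * 3 // 10): i_off]
    return bool(np.max(early) - np.max(late) >= min_hump_mv)
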