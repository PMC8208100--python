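"""Passive properties, spike detection and discharge metrics from
current-clamp sweeps.

Conventions: spike threshold is the first sample of a rising excursion
where the centred-difference dV/dt reaches 15 mV/ms; AP amplitude is
peak minus threshold; AHP amplitude is trough minus threshold (negative);
adaptation is last over first instantaneous frequency; attenuation is the
last over first AP amplitude expressed as a percentage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import ProtocolError, Sweep, require_units

__all__ = [
    "SpikeTrain",
    "PassiveProperties",
    "APWaveformFeatures",
    "DischargeMetrics",
    "RheobaseResult",
    "detect_spikes",
    "measure_passive",
    "measure_rmp",
    "classify_spontaneous",
    "find_rheobase",
    "discharge_metrics",
    "ap_waveform_features",
]

#: dV/dt criterion for AP threshold, mV/ms
DVDT_THRESHOLD = 15.0

#: AHP trough search window after threshold, ms (avoids step-offset artifacts)
AHP_WINDOW_MS = 200.0


@dataclass
class SpikeTrain:
    """Detected spikes of one sweep; times in ms, voltages in mV."""

    threshold_times: np.ndarray
    threshold_voltages: np.ndarray
    peak_times: np.ndarray
    peak_voltages: np.ndarray
    step_amplitude_pa: float = np.nan

    def __post_init__(self) -> None:
        for name in ("threshold_times", "threshold_voltages", "peak_times", "peak_voltages"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if np.any(np.diff(self.threshold_times) <= 0):
            raise ValueError("spike times must be strictly increasing")
        if np.any(self.peak_times < self.threshold_times):
            raise ValueError("each threshold must precede its peak")

    def __len__(self) -> int:
        return int(self.threshold_times.size)

    @property
    def amplitudes(self) -> np.ndarray:
        """Per-spike AP amplitude: peak minus threshold, mV."""
        return self.peak_voltages - self.threshold_voltages


@dataclass
class PassiveProperties:
    rin_mohm: float = np.nan
    cm_pf: float = np.nan
    rmp_mv: float = np.nan
    rheobase_pa: float = np.nan
    spontaneous: str = "none"


@dataclass
class APWaveformFeatures:
    threshold_mv: float = np.nan
    peak_amplitude_mv: float = np.nan
    rise_time_ms: float = np.nan
    base_width_ms: float = np.nan
    ahp_amplitude_mv: float = np.nan   # trough - threshold, negative
    ahp_latency_ms: float = np.nan     # threshold time -> trough time
    flags: list[str] = field(default_factory=list)


@dataclass
class DischargeMetrics:
    first_spike_latency_ms: float = np.nan
    isis_ms: np.ndarray = field(default_factory=lambda: np.array([]))
    instantaneous_freqs_hz: np.ndarray = field(default_factory=lambda: np.array([]))
    mean_frequency_hz: float = np.nan
    discharge_duration_ms: float = np.nan
    adaptation: float = np.nan
    attenuation_pct: float = np.nan
    n_spikes: int = 0
    flags: list[str] = field(default_factory=list)


@dataclass
class RheobaseResult:
    rheobase_pa: float | None
    index: int | None
    reluctant_candidate: bool = False
    boundary_warning: bool = False


def dvdt(sweep: Sweep) -> np.ndarray:
    """Centred-difference dV/dt in mV/ms (one-sided at the ends)."""
    return np.gradient(sweep.samples, sweep.dt)


def detect_spikes(sweep: Sweep, dvdt_threshold: float = DVDT_THRESHOLD) -> SpikeTrain:
    """Detect APs: threshold where centred dV/dt first reaches the criterion
    within a rising excursion; peak at the subsequent voltage maximum; a new
    spike is accepted only after the trace falls back below the previous
    threshold voltage."""
    require_units(sweep, "mV")
    v = sweep.samples
    dv = dvdt(sweep)
    cand = np.flatnonzero(dv >= dvdt_threshold)
    thr_idx: list[int] = []
    peak_idx: list[int] = []
    i = 0
    n = v.size
    while i < cand.size:
        k = int(cand[i])
        thr_v = v[k]
        # peak: maximum until the trace falls back below the threshold voltage
        j = k + 1
        while j < n - 1 and not (v[j] < thr_v and v[j] <= v[j - 1]):
            j += 1
        seg_end = j
        pk = k + int(np.argmax(v[k:seg_end + 1]))
        if pk > k or v[k] == v[pk]:
            thr_idx.append(k)
            peak_idx.append(pk)
        # lockout: skip candidates until the trace has returned below threshold
        while i < cand.size and cand[i] <= seg_end:
            i += 1
    thr_idx_a = np.array(thr_idx, dtype=int)
    peak_idx_a = np.array(peak_idx, dtype=int)
    return SpikeTrain(
        threshold_times=thr_idx_a * sweep.dt,
        threshold_voltages=v[thr_idx_a] if thr_idx_a.size else np.array([]),
        peak_times=peak_idx_a * sweep.dt,
        peak_voltages=v[peak_idx_a] if peak_idx_a.size else np.array([]),
    )


def measure_passive(sweeps: list[Sweep]) -> tuple[float, float]:
    """Input resistance (MOhm) and capacitance (pF) from averaged -5 mV
    seal-test responses.

    Rin from the steady-state plateau (last 20 % of the step) via Ohm's law;
    Cm by integrating the leak-subtracted capacitive transient charge and
    dividing by the step amplitude.
    """
    if not sweeps:
        raise ProtocolError("no seal-test sweeps")
    for sw in sweeps:
        require_units(sw, "pA")
    avg = np.mean([sw.samples for sw in sweeps], axis=0)
    sw0 = sweeps[0]
    ep = sw0.step_epoch()
    if ep.duration_ms <= 0:
        raise ProtocolError("zero-length step epoch")
    dv = ep.command_level
    if dv == 0:
        raise ProtocolError("seal-test step amplitude is zero")
    dt = sw0.dt
    i_on = int(round(ep.start_ms / dt))
    i_off = int(round(ep.end_ms / dt))
    baseline = float(np.mean(avg[:i_on])) if i_on > 0 else 0.0
    ss_start = i_off - max(1, int(0.2 * (i_off - i_on)))
    i_ss = float(np.mean(avg[ss_start:i_off])) - baseline
    if i_ss == 0:
        raise ProtocolError("no steady-state current deflection")
    rin = abs(dv / i_ss) * 1e3                      # mV/pA -> GOhm -> MOhm
    # integrate the capacitive transient over the first 20 % of the step:
    # the clamp time constant is far shorter, and a short window keeps the
    # baseline/plateau estimation error from accumulating into the charge
    i_tr = i_on + max(1, int(0.2 * (i_off - i_on)))
    charge = float(np.sum(avg[i_on:i_tr] - baseline - i_ss)) * dt  # pA*ms
    cm = abs(charge / dv)                           # pA*ms/mV = pF
    return rin, cm


def measure_rmp(sweep: Sweep, spikes: SpikeTrain | None = None,
                exclusion_ms: float = 5.0) -> float:
    """Resting membrane potential: mean of spike-free samples of a long
    passive recording (windows of +-5 ms around each spike excluded)."""
    require_units(sweep, "mV")
    if sweep.duration_ms < 30_000.0:
        warnings.warn("passive recording shorter than 30 s; RMP computed on available length")
    if spikes is None:
        spikes = detect_spikes(sweep)
    mask = np.ones(sweep.n_samples, dtype=bool)
    for t in spikes.threshold_times:
        i0 = max(0, int((t - exclusion_ms) / sweep.dt))
        i1 = min(sweep.n_samples, int((t + exclusion_ms) / sweep.dt) + 1)
        mask[i0:i1] = False
    return float(np.mean(sweep.samples[mask]))


def classify_spontaneous(
    spike_times_ms: np.ndarray,
    duration_ms: float,
    cv_tonic: float = 0.5,
    burst_isi_ms: float = 100.0,
    burst_min_spikes: int = 3,
    silence_ms: float = 1000.0,
) -> str:
    """Spontaneous-activity class from spike times over a passive recording.

    none if no spikes; bursting if at least two clusters of >= 3 spikes with
    intra-burst ISIs < 100 ms separated by > 1 s silences; tonic if the ISI
    coefficient of variation is < 0.5; otherwise irregular.
    """
    t = np.sort(np.asarray(spike_times_ms, dtype=float))
    if t.size == 0:
        return "none"
    if t.size >= 2 * burst_min_spikes:
        gaps = np.flatnonzero(np.diff(t) > silence_ms)
        bounds = np.concatenate([[0], gaps + 1, [t.size]])
        n_bursts = 0
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg = t[a:b]
            if seg.size >= burst_min_spikes and np.all(np.diff(seg) < burst_isi_ms):
                n_bursts += 1
        if n_bursts >= 2:
            return "bursting"
    if t.size < 2:
        return "irregular"
    isis = np.diff(t)
    cv = float(np.std(isis) / np.mean(isis))
    return "tonic" if cv < cv_tonic else "irregular"


def find_rheobase(step_sweeps: list[Sweep],
                  spike_trains: list[SpikeTrain] | None = None) -> RheobaseResult:
    """Smallest step amplitude whose response contains at least one spike.

    Sweeps must be ordered by step amplitude.  A cell with no spikes at any
    step is flagged as a reluctant-firing candidate (not an error)."""
    if spike_trains is None:
        spike_trains = [detect_spikes(sw) for sw in step_sweeps]
    amps = [sw.step_epoch().command_level for sw in step_sweeps]
    if any(b < a for a, b in zip(amps, amps[1:])):
        raise ProtocolError("step sweeps must be ordered by amplitude")
    for i, train in enumerate(spike_trains):
        if len(train) >= 1:
            return RheobaseResult(amps[i], i, boundary_warning=(i == 0))
    return RheobaseResult(None, None, reluctant_candidate=True)


def discharge_metrics(train: SpikeTrain, step: "ProtocolEpoch") -> DischargeMetrics:
    """Latency, ISIs, frequencies, duration, adaptation and attenuation of a
    spike train within a current step (evaluated at rheobase + 40 pA)."""
    m = DischargeMetrics(n_spikes=len(train))
    if len(train) >= 1:
        m.first_spike_latency_ms = float(train.threshold_times[0] - step.start_ms)
    if len(train) < 2:
        m.flags.append("undefined: fewer than 2 spikes")
        return m
    isis = np.diff(train.peak_times)
    m.isis_ms = isis
    m.instantaneous_freqs_hz = 1000.0 / isis
    m.mean_frequency_hz = len(train) / (step.duration_ms / 1000.0)
    m.discharge_duration_ms = float(train.peak_times[-1] - train.peak_times[0])
    m.adaptation = float(m.instantaneous_freqs_hz[-1] / m.instantaneous_freqs_hz[0])
    m.attenuation_pct = float(train.amplitudes[-1] / train.amplitudes[0] * 100.0)
    return m


def _cross_time(t0: float, v0: float, t1: float, v1: float, level: float) -> float:
    if v1 == v0:
        return t0
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def ap_waveform_features(
    sweep: Sweep,
    train: SpikeTrain | None = None,
    which: int = 0,
    threshold_mv: float | None = None,
    window_end_ms: float | None = None,
) -> APWaveformFeatures:
    """Six AP waveform features of one spike.

    ``threshold_mv`` defaults to the spike's own dV/dt threshold voltage;
    passing the rheobase-response threshold follows the convention that the
    threshold value comes from the rheobase sweep while the waveform comes
    from the first AP of the rheobase + 40 pA response.  The AHP trough is
    searched from the peak to the next spike, the end of the step, or 200 ms
    after threshold, whichever is first.
    """
    require_units(sweep, "mV")
    if train is None:
        train = detect_spikes(sweep)
    if len(train) == 0:
        raise ValueError("sweep contains no spikes")
    out = APWaveformFeatures()
    v = sweep.samples
    dt = sweep.dt
    t_thr = train.threshold_times[which]
    thr = float(train.threshold_voltages[which]) if threshold_mv is None else float(threshold_mv)
    out.threshold_mv = thr
    i_pk = int(round(train.peak_times[which] / dt))
    out.peak_amplitude_mv = float(v[i_pk] - thr)

    # rise: last upward crossing of the threshold level before the peak
    i_thr = int(round(t_thr / dt))
    i_up = i_pk
    for i in range(i_pk, max(i_thr - int(2.0 / dt), 0), -1):
        if v[i - 1] < thr <= v[i]:
            i_up = i
            break
    t_up = _cross_time((i_up - 1) * dt, v[i_up - 1], i_up * dt, v[i_up], thr)
    out.rise_time_ms = float(i_pk * dt - t_up)

    # trough search window
    limits = [sweep.duration_ms, t_thr + AHP_WINDOW_MS]
    if which + 1 < len(train):
        limits.append(train.threshold_times[which + 1])
    try:
        ep = sweep.step_epoch()
        limits.append(ep.end_ms)
    except ProtocolError:
        pass
    i_end = min(int(min(limits) / dt), v.size)
    if i_end <= i_pk + 1:
        out.flags.append("no post-peak window for AHP")
        return out
    seg = v[i_pk:i_end]
    i_tr = i_pk + int(np.argmin(seg))
    if i_tr >= i_end - 1:
        out.flags.append("no trough before window end")
    else:
        out.ahp_amplitude_mv = float(v[i_tr] - thr)
        out.ahp_latency_ms = float(i_tr * dt - t_up)

    # base width: time above the threshold level around the peak
    i_dn = None
    for i in range(i_pk, i_end - 1):
        if v[i] >= thr > v[i + 1]:
            i_dn = i + 1
            break
    if i_dn is None:
        out.flags.append("no downward threshold crossing; width undefined")
    else:
        t_dn = _cross_time((i_dn - 1) * dt, v[i_dn - 1], i_dn * dt, v[i_dn], thr)
        out.base_width_ms = float(t_dn - t_up)
    return out
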