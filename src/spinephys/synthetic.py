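"""Synthetic patch-clamp data with ground truth.

This module generates every input the analysis pipeline consumes:

* current-clamp step families from a single-compartment conductance model
  (leak + Na/K spike mechanism + fast/slow A-type K + T-type Ca + H current
  + a slow activity-dependent suppression current), integrated with a
  fixed-step 4th-order Runge-Kutta scheme at 0.01 ms internally;
* the voltage-clamp subthreshold protocol (-70 -> -100 mV for 1 s, then
  -40 mV for 200 ms) with P/N leak subsweeps;
* seal-test (-5 mV step) current responses of an RC cell with access
  resistance;
* spontaneous EPSC traces (Poisson events, difference-of-exponential
  kinetics, Gaussian noise);
* Gaussian feature tables with planted cluster structure;
* piecewise-analytic action-potential waveforms with exact geometry.

The model is not biophysically calibrated: channel kinetics and the seven
discharge presets are tuned only so each preset expresses the qualitative
firing-pattern definition it is named after (tonic, delayed, gap, initial
burst, single spike, phasic, reluctant).  Every generator is deterministic
given its spec and seed, and returns the ground truth used as test oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.signal import lfilter

from .core import DEFAULT_DT, ProtocolEpoch, Sweep

__all__ = [
    "PhenotypeSpec",
    "EventTrainSpec",
    "GroundTruth",
    "PHENOTYPE_PRESETS",
    "CURRENT_CLASS_PRESETS",
    "DISCHARGE_CLASSES",
    "simulate_current_clamp",
    "simulate_retest",
    "simulate_voltage_clamp",
    "simulate_seal_test",
    "simulate_passive_cc",
    "synthesize_epsc_trace",
    "synthesize_feature_table",
    "synthesize_ap_waveform",
]

DISCHARGE_CLASSES = ("TF", "DF", "GF", "IB", "SS", "P", "RF")

# reversal potentials, mV
E_NA, E_K, E_CA, E_H = 55.0, -90.0, 120.0, -35.0

#: internal integration step, ms
DT_INT = 0.01


@dataclass
class PhenotypeSpec:
    """Channel densities (nS), passive properties and noise for one model cell."""

    discharge_class: str = "TF"
    ahp_profile: str = "monophasic"   # {monophasic, ADP, slowed}
    g_na: float = 120.0
    g_k: float = 36.0
    g_ka_fast: float = 0.0
    g_ka_slow: float = 0.0
    g_cat: float = 0.0
    g_h: float = 0.0
    g_adapt: float = 0.0
    tau_adapt_decay: float = 300.0    # ms
    cm_pf: float = 13.0
    rin_mohm: float = 300.0
    rmp_mv: float = -65.0             # leak reversal
    noise_sd: float = 0.5             # target voltage noise, mV

    def __post_init__(self) -> None:
        if self.discharge_class not in DISCHARGE_CLASSES:
            raise ValueError(f"unknown discharge class {self.discharge_class!r}")
        if self.ahp_profile not in ("monophasic", "ADP", "slowed"):
            raise ValueError(f"unknown AHP profile {self.ahp_profile!r}")
        for name in ("g_na", "g_k", "g_ka_fast", "g_ka_slow", "g_cat", "g_h", "g_adapt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cm_pf <= 0 or self.rin_mohm <= 0:
            raise ValueError("Cm and Rin must be positive")

    @property
    def g_leak(self) -> float:
        """Leak conductance in nS (1000 / Rin[MOhm])."""
        return 1000.0 / self.rin_mohm

    def params(self) -> np.ndarray:
        return np.array(
            [self.cm_pf, self.g_leak, self.rmp_mv, self.g_na, self.g_k,
             self.g_ka_fast, self.g_ka_slow, self.g_cat, self.g_h,
             self.g_adapt, self.tau_adapt_decay],
            dtype=np.float64,
        )


@dataclass
class EventTrainSpec:
    """Poisson sEPSC train parameters."""

    rate_hz: float = 5.0
    amp_mean_pa: float = -20.0        # inward, negative
    amp_sd_pa: float = 4.0
    rise_tau_ms: float = 0.5
    decay_tau_ms: float = 4.0
    duration_s: float = 30.0
    noise_sd_pa: float = 2.0

    def __post_init__(self) -> None:
        if self.rate_hz < 0:
            raise ValueError("rate must be >= 0")
        if not self.decay_tau_ms > self.rise_tau_ms > 0:
            raise ValueError("need decay_tau > rise_tau > 0")


@dataclass
class GroundTruth:
    """Generator-side labels used as test oracles."""

    spike_times: list | None = None          # list of arrays, ms, per sweep
    discharge_class: str | None = None
    current_class: str | None = None
    ih_present: bool | None = None
    event_times_ms: np.ndarray | None = None
    event_amplitudes_pa: np.ndarray | None = None
    cluster_labels: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# gating kinetics (shared by the CC integrator and the analytic VC solver)
#
# Each gate relaxes to a Boltzmann steady state with a fixed time constant.
# Rows: half-activation (mV), slope (mV, sign gives act/inact), tau (ms).

GATES = {
    "m": (-35.0, 5.0, 0.1),
    "h": (-48.0, -6.0, 4.0),
    "n": (-37.0, 6.0, 4.0),
    "af": (-55.0, 7.0, 1.5),    # fast A-type activation
    "bf": (-68.0, -6.0, 150.0), # fast A-type inactivation
    "as": (-55.0, 7.0, 15.0),   # slow A-type activation
    "bs": (-68.0, -6.0, 400.0), # slow A-type inactivation
    "p": (-52.0, 5.0, 2.0),     # T-type activation
    "q": (-80.0, -5.0, 60.0),   # T-type inactivation
    "r": (-85.0, -6.0, 300.0),  # H-current activation
    "w": (-20.0, 4.0, 50.0),    # suppression current; decay tau from the spec
}

GATE_ORDER = ["m", "h", "n", "af", "bf", "as", "bs", "p", "q", "r", "w"]


def gate_inf(name: str, v: float | np.ndarray) -> float | np.ndarray:
    vh, k, _ = GATES[name]
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - vh) / k))


def steady_state(v: float) -> np.ndarray:
    """Full state vector [V, gates...] at a clamped potential."""
    return np.array([v] + [float(gate_inf(g, v)) for g in GATE_ORDER])


def ionic_current(y: np.ndarray, par: np.ndarray) -> float:
    """Total ionic current (pA, outward positive) for a state vector."""
    v, m, h, n, af, bf, as_, bs, p, q, r, w = y
    _, g_l, e_l, g_na, g_k, g_af, g_as, g_cat, g_h, g_ad, _ = par
    i = g_l * (v - e_l)
    i += g_na * m ** 3 * h * (v - E_NA)
    i += g_k * n ** 4 * (v - E_K)
    i += g_af * af ** 3 * bf * (v - E_K)
    i += g_as * as_ ** 3 * bs * (v - E_K)
    i += g_cat * p ** 2 * q * (v - E_CA)
    i += g_h * r * (v - E_H)
    i += g_ad * w * (v - E_K)
    return float(i)


def holding_current(spec: PhenotypeSpec, v_hold: float) -> float:
    """Bias current (pA) that makes ``v_hold`` a stationary point."""
    return ionic_current(steady_state(v_hold), spec.params())


#: gate constants as an array shared with the compiled kernel
_GATE_TABLE = np.array([GATES[g] for g in GATE_ORDER], dtype=np.float64)


@njit(cache=True)
def _deriv(y, i_inj, par, gt, dy):
    v = y[0]
    i_ion = par[1] * (v - par[2])
    i_ion += par[3] * y[1] ** 3 * y[2] * (v - 55.0)
    i_ion += par[4] * y[3] ** 4 * (v + 90.0)
    i_ion += par[5] * y[4] ** 3 * y[5] * (v + 90.0)
    i_ion += par[6] * y[6] ** 3 * y[7] * (v + 90.0)
    i_ion += par[7] * y[8] ** 2 * y[9] * (v - 120.0)
    i_ion += par[8] * y[10] * (v + 35.0)
    i_ion += par[9] * y[11] * (v + 90.0)
    dy[0] = (i_inj - i_ion) / par[0]
    for i in range(11):
        inf = 1.0 / (1.0 + math.exp(-(v - gt[i, 0]) / gt[i, 1]))
        tau = gt[i, 2]
        if i == 10 and inf <= y[i + 1]:
            tau = par[10]  # suppression current decays on its own timescale
        dy[i + 1] = (inf - y[i + 1]) / tau


@njit(cache=True)
def _integrate_cc(i_stim, noise, dt, par, gt, y0, stride):
    n_rec = i_stim.shape[0] // stride
    v_out = np.empty(n_rec, dtype=np.float64)
    y = y0.copy()
    yt = np.empty(12)
    k1 = np.empty(12); k2 = np.empty(12); k3 = np.empty(12); k4 = np.empty(12)
    for k in range(i_stim.shape[0]):
        if k % stride == 0:
            v_out[k // stride] = y[0]
        i_inj = i_stim[k] + noise[k]
        _deriv(y, i_inj, par, gt, k1)
        for i in range(12):
            yt[i] = y[i] + 0.5 * dt * k1[i]
        _deriv(yt, i_inj, par, gt, k2)
        for i in range(12):
            yt[i] = y[i] + 0.5 * dt * k2[i]
        _deriv(yt, i_inj, par, gt, k3)
        for i in range(12):
            yt[i] = y[i] + dt * k3[i]
        _deriv(yt, i_inj, par, gt, k4)
        c = dt / 6.0
        for i in range(12):
            y[i] += c * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        if not math.isfinite(y[0]) or abs(y[0]) > 500.0:
            raise FloatingPointError("membrane-potential integration blew up")
    return v_out


def _ou_noise(n: int, sd: float, dt: float, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Ornstein-Uhlenbeck current noise with stationary sd (pA) and tau (ms)."""
    if sd == 0:
        return np.zeros(n)
    a = math.exp(-dt / tau)
    xi = rng.standard_normal(n)
    return lfilter([sd * math.sqrt(1.0 - a * a)], [1.0, -a], xi)


def _true_spike_times(v: np.ndarray, dt: float, level: float = -20.0) -> np.ndarray:
    """Upward crossings of the model's spiking threshold, in ms."""
    up = np.flatnonzero((v[1:] >= level) & (v[:-1] < level)) + 1
    return up * dt


def _run_cc_sweep(spec: PhenotypeSpec, amplitude_pa: float, rng: np.random.Generator,
                  v_hold: float = -70.0, pre_ms: float = 100.0, step_ms: float = 1000.0,
                  post_ms: float = 200.0, dt_out: float = DEFAULT_DT) -> Sweep:
    stride = max(1, int(round(dt_out / DT_INT)))
    n_int = int(round((pre_ms + step_ms + post_ms) / DT_INT))
    i_stim = np.full(n_int, holding_current(spec, v_hold))
    i0 = int(round(pre_ms / DT_INT))
    i1 = int(round((pre_ms + step_ms) / DT_INT))
    i_stim[i0:i1] += amplitude_pa
    # noise current calibrated so the quasi-static voltage sd matches the spec
    sd_i = spec.noise_sd / (spec.rin_mohm / 1000.0)
    noise = _ou_noise(n_int, sd_i, DT_INT, 20.0, rng)
    v = _integrate_cc(i_stim, noise, DT_INT, spec.params(), _GATE_TABLE,
                      steady_state(v_hold), stride)
    epochs = [
        ProtocolEpoch(0.0, pre_ms, 0.0, "holding"),
        ProtocolEpoch(pre_ms, step_ms, amplitude_pa, "step"),
        ProtocolEpoch(pre_ms + step_ms, post_ms, 0.0, "holding"),
    ]
    return Sweep(v, dt=dt_out, units="mV", epochs=epochs)


def simulate_current_clamp(
    spec: PhenotypeSpec,
    amplitudes_pa: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[list[Sweep], GroundTruth]:
    """Simulate the depolarising current-step family (20 pA increments, 1 s)
    from a -70 mV holding potential.  Returns one sweep per step amplitude
    and the ground-truth spike times and discharge label."""
    if amplitudes_pa is None:
        amplitudes_pa = np.arange(-20.0, 181.0, 20.0)
    rng = np.random.default_rng(seed)
    sweeps, spikes = [], []
    for amp in amplitudes_pa:
        sw = _run_cc_sweep(spec, float(amp), rng)
        sweeps.append(sw)
        spikes.append(_true_spike_times(sw.samples, sw.dt))
    truth = GroundTruth(spike_times=spikes, discharge_class=spec.discharge_class,
                        extras={"amplitudes_pa": np.asarray(amplitudes_pa, dtype=float)})
    return sweeps, truth


def simulate_retest(spec: PhenotypeSpec, amplitude_pa: float = 180.0,
                    seed: int = 0, v_hold: float = -50.0) -> Sweep:
    """Repeat one step from a depolarised holding potential (reluctant-firing
    retest): inactivating the resting A-type conductance lets the cell fire."""
    rng = np.random.default_rng(seed)
    return _run_cc_sweep(spec, amplitude_pa, rng, v_hold=v_hold)


# ---------------------------------------------------------------------------
# voltage clamp

VC_PROTOCOL = (
    ("holding", -70.0, 100.0),
    ("step", -100.0, 1000.0),
    ("step", -40.0, 200.0),
    ("holding", -70.0, 100.0),
)


def _vc_currents(spec: PhenotypeSpec, command: list[tuple[str, float, float]],
                 dt: float) -> tuple[np.ndarray, list[ProtocolEpoch]]:
    """Analytic channel currents under a piecewise-constant command waveform.

    With the command constant inside each epoch, every gate relaxes
    exponentially and is evaluated in closed form, so no ODE stepping is
    needed in voltage clamp."""
    par = spec.params()
    x = {g: float(gate_inf(g, command[0][1])) for g in GATE_ORDER}
    segs, epochs = [], []
    t0 = 0.0
    prev_v = command[0][1]
    for kind, v_cmd, dur in command:
        n = int(round(dur / dt))
        t = (np.arange(n) + 0.5) * dt
        gates = {}
        for g in GATE_ORDER:
            inf, tau = float(gate_inf(g, v_cmd)), GATES[g][2]
            gates[g] = inf + (x[g] - inf) * np.exp(-t / tau)
            x[g] = inf + (x[g] - inf) * math.exp(-dur / tau)
        i = par[1] * (v_cmd - par[2])
        i = i + par[3] * gates["m"] ** 3 * gates["h"] * (v_cmd - E_NA)
        i = i + par[4] * gates["n"] ** 4 * (v_cmd - E_K)
        i = i + par[5] * gates["af"] ** 3 * gates["bf"] * (v_cmd - E_K)
        i = i + par[6] * gates["as"] ** 3 * gates["bs"] * (v_cmd - E_K)
        i = i + par[7] * gates["p"] ** 2 * gates["q"] * (v_cmd - E_CA)
        i = i + par[8] * gates["r"] * (v_cmd - E_H)
        # capacitive transient of the command step, confined to one sample
        if abs(v_cmd - prev_v) > 0:
            i[0] += par[0] * (v_cmd - prev_v) / dt
        segs.append(i)
        epochs.append(ProtocolEpoch(t0, dur, v_cmd, kind))
        t0 += dur
        prev_v = v_cmd
    return np.concatenate(segs), epochs


CURRENT_CLASS_PRESETS: dict[str, PhenotypeSpec] = {
    "KA_fast": PhenotypeSpec(g_na=0, g_k=0, g_ka_fast=8.0),
    "KA_slow": PhenotypeSpec(g_na=0, g_k=0, g_ka_slow=8.0),
    "CaT_like": PhenotypeSpec(g_na=0, g_k=0, g_cat=6.0),
    "NC": PhenotypeSpec(g_na=0, g_k=0),
}


def simulate_voltage_clamp(
    spec: PhenotypeSpec,
    seed: int = 0,
    noise_sd_pa: float = 2.0,
    n_pn: int = 4,
    protocol: tuple = VC_PROTOCOL,
    current_class: str | None = None,
) -> tuple[Sweep, list[Sweep], GroundTruth]:
    """Voltage-clamp subthreshold protocol with P/N leak subsweeps.

    Returns ``(test_sweep, pn_subsweeps, truth)``; subsweeps are responses
    to the command scaled down 1/n around the holding level."""
    rng = np.random.default_rng(seed)
    dt = DEFAULT_DT
    i, epochs = _vc_currents(spec, list(protocol), dt)
    test = Sweep(i + rng.standard_normal(i.size) * noise_sd_pa, dt=dt,
                 units="pA", epochs=epochs)
    hold = protocol[0][1]
    scaled = [(kind, hold + (v - hold) / n_pn, dur) for kind, v, dur in protocol]
    subs = []
    for _ in range(n_pn):
        i_s, eps = _vc_currents(spec, scaled, dt)
        subs.append(Sweep(i_s + rng.standard_normal(i_s.size) * noise_sd_pa,
                          dt=dt, units="pA", epochs=eps))
    truth = GroundTruth(current_class=current_class, ih_present=spec.g_h > 0)
    return test, subs, truth


# ---------------------------------------------------------------------------
# seal test and long passive recording

def simulate_seal_test(
    cm_pf: float = 13.0,
    rin_mohm: float = 300.0,
    rs_mohm: float = 1.0,
    n_trials: int = 30,
    dv_mv: float = -5.0,
    noise_sd_pa: float = 1.0,
    seed: int = 0,
    pre_ms: float = 20.0,
    step_ms: float = 100.0,
    post_ms: float = 30.0,
    dt: float = DEFAULT_DT,
) -> list[Sweep]:
    """Current responses of an RC cell (Rin || Cm behind access resistance
    Rs) to a -5 mV seal-test step under voltage clamp.

    Samples are bin averages of the analytic continuous response, emulating
    the acquisition chain's anti-alias filtering, so the capacitive charge
    is preserved even when the clamp time constant is shorter than dt.
    """
    rng = np.random.default_rng(seed)
    tau = cm_pf * (rs_mohm * rin_mohm) / (rs_mohm + rin_mohm) * 1e-3  # ms
    i_peak = dv_mv / rs_mohm * 1e3        # pA at t = 0+
    i_ss = dv_mv / (rs_mohm + rin_mohm) * 1e3
    n = int(round((pre_ms + step_ms + post_ms) / dt))
    t = np.arange(n) * dt

    def transient(t_on: float, sign: float) -> np.ndarray:
        # bin-averaged (i_peak - i_ss) * exp(-(t - t_on)/tau) for t >= t_on
        rel0 = np.clip(t - t_on, 0.0, None)
        rel1 = np.clip(t + dt - t_on, 0.0, None)
        return sign * (i_peak - i_ss) * (tau / dt) * (np.exp(-rel0 / tau) - np.exp(-rel1 / tau))

    def plateau(t_on: float, t_off: float) -> np.ndarray:
        frac = (np.clip(t + dt, t_on, t_off) - np.clip(t, t_on, t_off)) / dt
        return i_ss * frac

    base = plateau(pre_ms, pre_ms + step_ms) + transient(pre_ms, 1.0) \
        + transient(pre_ms + step_ms, -1.0)
    epochs = [
        ProtocolEpoch(0.0, pre_ms, 0.0, "holding"),
        ProtocolEpoch(pre_ms, step_ms, dv_mv, "step"),
        ProtocolEpoch(pre_ms + step_ms, post_ms, 0.0, "holding"),
    ]
    return [
        Sweep(base + rng.standard_normal(n) * noise_sd_pa, dt=dt, units="pA",
              epochs=epochs)
        for _ in range(n_trials)
    ]


def simulate_passive_cc(spec: PhenotypeSpec, duration_s: float = 60.0,
                        seed: int = 0, dt_out: float = DEFAULT_DT) -> Sweep:
    """Long passive current-clamp recording at zero bias current."""
    rng = np.random.default_rng(seed)
    stride = max(1, int(round(dt_out / DT_INT)))
    n_int = int(round(duration_s * 1000.0 / DT_INT))
    sd_i = spec.noise_sd / (spec.rin_mohm / 1000.0)
    noise = _ou_noise(n_int, sd_i, DT_INT, 20.0, rng)
    # settle to the model's own resting potential first
    from scipy.optimize import brentq

    def f(v):
        return ionic_current(steady_state(v), spec.params())

    v_rest = brentq(f, -95.0, -35.0)
    v = _integrate_cc(np.zeros(n_int), noise, DT_INT, spec.params(), _GATE_TABLE,
                      steady_state(v_rest), stride)
    return Sweep(v, dt=dt_out, units="mV",
                 epochs=[ProtocolEpoch(0.0, duration_s * 1000.0, 0.0, "holding")])


# ---------------------------------------------------------------------------
# sEPSC traces

def epsc_kernel(rise_tau: float, decay_tau: float, dt: float) -> np.ndarray:
    """Unit-peak difference-of-exponentials kernel (positive-valued)."""
    t = np.arange(0.0, rise_tau + 6.0 * decay_tau, dt)
    k = np.exp(-t / decay_tau) - np.exp(-t / rise_tau)
    return k / k.max()


def synthesize_epsc_trace(spec: EventTrainSpec, seed: int = 0,
                          dt: float = DEFAULT_DT) -> tuple[Sweep, GroundTruth]:
    """Poisson sEPSC train: each event is a difference of exponentials with
    the spec kinetics; additive Gaussian baseline noise."""
    rng = np.random.default_rng(seed)
    dur_ms = spec.duration_s * 1000.0
    n = int(round(dur_ms / dt))
    n_ev = rng.poisson(spec.rate_hz * spec.duration_s)
    times = np.sort(rng.uniform(0.0, dur_ms, n_ev))
    amps = rng.normal(spec.amp_mean_pa, spec.amp_sd_pa, n_ev)
    trace = np.zeros(n)
    if n_ev:
        kern = epsc_kernel(spec.rise_tau_ms, spec.decay_tau_ms, dt)
        impulses = np.zeros(n)
        idx = np.minimum((times / dt).astype(int), n - 1)
        np.add.at(impulses, idx, amps)
        full = np.convolve(impulses, kern)[:n]
        trace += full
    trace += rng.standard_normal(n) * spec.noise_sd_pa
    sweep = Sweep(trace, dt=dt, units="pA",
                  epochs=[ProtocolEpoch(0.0, dur_ms, -70.0, "holding")])
    return sweep, GroundTruth(event_times_ms=times, event_amplitudes_pa=amps)


# ---------------------------------------------------------------------------
# feature tables with planted clusters

def synthesize_feature_table(
    k: int,
    n_per_cluster: int,
    separation: float,
    within_sd: float,
    n_features: int = 20,
    seed: int = 0,
):
    """Gaussian clusters with hierarchically arranged centroids.

    Centroids sit on a binary tree (recursive bisection with offsets that
    halve at each depth), so coarser cuts of the planted partition are
    themselves cohesive -- the nested group/cluster structure typical of
    cell-type cohorts.  ``separation`` is the distance between the closest
    pair of centroids.  Returns ``(FeatureTable, GroundTruth)``.
    """
    from .core import FeatureTable

    if k < 1:
        raise ValueError("k must be >= 1")
    if n_features < max(int(np.ceil(np.log2(max(k, 2)))), 1):
        raise ValueError("need n_features >= log2(k) axes to place centroids")
    rng = np.random.default_rng(seed)
    centroids = np.zeros((k, n_features))
    j = np.arange(n_features)

    def walsh(level: int) -> np.ndarray:
        # orthogonal sign patterns spread every split across all features,
        # so no single feature dominates after per-feature normalisation
        u = np.where((j >> level) & 1, -1.0, 1.0)
        return u / np.linalg.norm(u)

    def place(rows: np.ndarray, level: int, scale: float) -> None:
        if rows.size <= 1:
            return
        half = (rows.size + 1) // 2
        centroids[rows[:half]] += scale * walsh(level)
        centroids[rows[half:]] -= scale * walsh(level)
        place(rows[:half], level + 1, scale / 2.0)
        place(rows[half:], level + 1, scale / 2.0)

    depth = int(np.ceil(np.log2(k))) if k > 1 else 0
    if depth:
        # deepest sibling offset is +-separation/2 -> closest pair exactly
        # `separation` apart
        place(np.arange(k), 0, separation * 2.0 ** (depth - 2))
    labels = np.repeat(np.arange(k), n_per_cluster)
    x = centroids[labels] + rng.standard_normal((k * n_per_cluster, n_features)) * within_sd
    table = FeatureTable(
        cell_ids=[f"cell_{i:03d}" for i in range(x.shape[0])],
        feature_names=[f"f{j:02d}" for j in range(n_features)],
        values=x,
    )
    return table, GroundTruth(cluster_labels=labels)


# ---------------------------------------------------------------------------
# analytic AP waveforms

def synthesize_ap_waveform(
    threshold_mv: float = -40.0,
    peak_mv: float = 20.0,
    rise_ms: float = 1.0,
    ahp_depth_mv: float = -5.0,
    ahp_latency_ms: float = 5.0,
    profile: str = "monophasic",
    dt: float = DEFAULT_DT,
    plateau_offset_mv: float = 3.0,
) -> Sweep:
    """Piecewise-analytic action potential with exact requested geometry.

    The spike sits on a depolarised plateau (threshold - plateau_offset)
    reached by a slow ramp from a -70 mV baseline, so the post-spike trough
    at ``threshold + ahp_depth`` is the genuine minimum of the analysis
    window.  ``profile`` shapes the falling phase: a monophasic return, an
    afterdepolarising bump before the trough (ADP), or a monotone fall with
    a slowed shoulder (slowed).
    """
    if peak_mv <= threshold_mv:
        raise ValueError("peak must exceed threshold")
    if ahp_depth_mv >= 0:
        raise ValueError("AHP depth must be negative")
    fall_ms = ahp_latency_ms - rise_ms
    if fall_ms <= 0:
        raise ValueError("ahp_latency must exceed rise time")
    if profile in ("ADP", "slowed") and fall_ms < 6.0:
        raise ValueError(
            f"inconsistent geometry: a {profile} falling phase needs >= 6 ms "
            "between peak and trough to be resolvable"
        )
    plateau = threshold_mv - plateau_offset_mv
    trough = threshold_mv + ahp_depth_mv
    base, ramp, hold_ms = -70.0, 40.0, 20.0

    segs: list[np.ndarray] = []

    def cos_seg(v0: float, v1: float, dur: float) -> np.ndarray:
        nn = max(2, int(round(dur / dt)))
        s = np.linspace(0.0, 1.0, nn, endpoint=False)
        return v1 + (v0 - v1) * 0.5 * (1.0 + np.cos(np.pi * s))

    segs.append(np.full(int(hold_ms / dt), base))
    segs.append(cos_seg(base, plateau, ramp))
    segs.append(np.full(int(10.0 / dt), plateau))
    # upstroke: plateau -> threshold fast but below the dV/dt criterion,
    # then threshold -> peak linearly over rise_ms
    segs.append(np.linspace(plateau, threshold_mv, max(2, int(1.0 / dt)), endpoint=False))
    n_rise = max(2, int(round(rise_ms / dt)))
    segs.append(np.linspace(threshold_mv, peak_mv, n_rise, endpoint=False))

    n_fall = max(4, int(round(fall_ms / dt)))
    s = np.linspace(0.0, 1.0, n_fall, endpoint=False)
    if profile == "monophasic":
        fall = trough + (peak_mv - trough) * 0.5 * (1.0 + np.cos(np.pi * s))
    elif profile == "ADP":
        fall = trough + (peak_mv - trough) * 0.5 * (1.0 + np.cos(np.pi * s))
        # depolarising bump after the fast repolarisation (once the fall is
        # below threshold), before the trough; kept subthreshold
        x = (threshold_mv - trough) / (peak_mv - trough)
        s_cross = math.acos(2.0 * x - 1.0) / math.pi
        centre = s_cross + 0.55 * (1.0 - s_cross)
        width = 0.18 * (1.0 - s_cross)
        i_c = min(n_fall - 1, int(centre * n_fall))
        bump = min(0.45 * abs(ahp_depth_mv) + 1.0,
                   (threshold_mv - 0.5) - fall[i_c])
        fall = fall + bump * np.exp(-0.5 * ((s - centre) / width) ** 2) \
            * (s > s_cross)
        fall[-1] = trough  # geometry contract: trough at the stated latency
    elif profile == "slowed":
        # fast fall, slow shoulder, final fall: monotone with two inflections
        m1 = threshold_mv - 0.35 * (threshold_mv - trough)
        m2 = threshold_mv - 0.55 * (threshold_mv - trough)
        n1, n2 = int(0.3 * n_fall), int(0.4 * n_fall)
        n3 = n_fall - n1 - n2
        f1 = cos_seg(peak_mv, m1, n1 * dt)[:n1]
        f2 = np.linspace(m1, m2, n2, endpoint=False)
        f3 = cos_seg(m2, trough, n3 * dt)[:n3]
        fall = np.concatenate([f1, f2, f3])
    else:
        raise ValueError(f"unknown profile {profile!r}")
    segs.append(fall)
    segs.append(np.array([trough]))
    segs.append(cos_seg(trough, plateau, 40.0)[1:])
    segs.append(np.full(int(60.0 / dt), plateau))
    v = np.concatenate(segs)
    return Sweep(v, dt=dt, units="mV",
                 epochs=[ProtocolEpoch(0.0, v.size * dt, 0.0, "holding")])


# ---------------------------------------------------------------------------
# discharge phenotype presets
#
# Tuned so each preset expresses the qualitative definition of its firing
# class at the evaluation step (rheobase + 40 pA); they are not calibrated
# to any measured channel densities.

PHENOTYPE_PRESETS: dict[str, PhenotypeSpec] = {
    "TF": PhenotypeSpec(discharge_class="TF"),
    "DF": PhenotypeSpec(discharge_class="DF", g_ka_fast=30.0),
    "GF": PhenotypeSpec(discharge_class="GF", g_ka_slow=20.0),
    "IB": PhenotypeSpec(discharge_class="IB", g_cat=25.0, g_adapt=4.0,
                        tau_adapt_decay=5000.0),
    "SS": PhenotypeSpec(discharge_class="SS", g_adapt=60.0,
                        tau_adapt_decay=5000.0),
    "P": PhenotypeSpec(discharge_class="P", g_adapt=1.3,
                       tau_adapt_decay=2000.0),
    "RF": PhenotypeSpec(discharge_class="RF", g_ka_fast=40.0, g_ka_slow=40.0),
}


def preset(name: str, **overrides) -> PhenotypeSpec:
    """A copy of a named discharge preset, optionally with field overrides."""
    return replace(PHENOTYPE_PRESETS[name], **overrides)
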