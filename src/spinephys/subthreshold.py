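"""P/N leak subtraction and classification of subthreshold voltage-activated
currents.

The subthreshold protocol holds at -70 mV, hyperpolarises to -100 mV for
1 s (removing A-type and T-type inactivation, and activating any H current),
then steps to -40 mV for 200 ms.  After P/N subtraction the dominant
transient during the -40 mV step is classified: outward with latency to
peak below 15 ms -> fast A-type; outward at or above 15 ms -> slow A-type
(the published boundary is strict "fast < 15 ms", so exactly 15 ms is
slow); inward -> T-type-like; below the noise floor -> no current (NC).
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field

import numpy as np

from .core import ProtocolError, Sweep, require_units

__all__ = ["SubthresholdProfile", "pn_leak_subtract", "classify_subthreshold", "detect_ih"]

#: latency boundary separating fast from slow A-type currents, ms
KA_LATENCY_BOUNDARY_MS = 15.0

#: noise-floor multiplier (times the pre-step baseline sd) below which
#: a response is called NC
NC_NOISE_FLOOR_SD = 4.0

#: samples at the step edge skipped as residual capacitive artifact, ms
EDGE_BLANK_MS = 1.0

#: boxcar width applied before peak measurement, ms
SMOOTH_MS = 5.0


@dataclass
class SubthresholdProfile:
    current_class: str = "NC"       # {KA_fast, KA_slow, CaT_like, NC}
    peak_amplitude_pa: float = np.nan   # signed: outward positive
    latency_ms: float = np.nan          # step onset -> peak
    half_decay_ms: float = np.nan       # peak -> 50 % amplitude
    ih_present: bool | None = None
    ih_amplitude_pa: float = np.nan
    diagnostics: dict = field(default_factory=dict)


def pn_leak_subtract(test: Sweep, subsweeps: list[Sweep], n: int | None = None) -> Sweep:
    """Subtract scaled leak subsweeps from the test sweep.

    Subsweeps are responses to the command scaled down by 1/n around the
    holding level; both test and subsweeps are referenced to their pre-step
    holding baseline before the subtraction, so any pure-leak (linear)
    component cancels exactly.
    """
    require_units(test, "pA")
    if n is None:
        n = len(subsweeps)
    if n <= 0 or not subsweeps:
        raise ValueError("P/N subtraction needs n >= 1 scaled subsweeps")
    ep = test.step_epoch()
    dt = test.dt
    i_on = int(round(ep.start_ms / dt))

    def dev(sw: Sweep) -> np.ndarray:
        if sw.n_samples != test.n_samples or sw.dt != dt:
            raise ProtocolError("subsweep sampling does not match the test sweep")
        sub_ep = sw.step_epoch()
        if abs(sub_ep.start_ms - ep.start_ms) > dt:
            raise ProtocolError("subsweep epochs not aligned with the test sweep")
        base = float(np.mean(sw.samples[:i_on])) if i_on else 0.0
        return sw.samples - base

    corrected = dev(test) - n * np.mean([dev(sw) for sw in subsweeps], axis=0)
    return Sweep(corrected, dt=dt, units="pA", epochs=list(test.epochs))


def _depol_epoch(sweep: Sweep) -> "ProtocolEpoch":
    steps = [ep for ep in sweep.epochs if ep.kind == "step"]
    if not steps:
        raise ProtocolError("no step epochs annotated")
    for ep in steps:
        if ep.command_level > -55.0:
            return ep
    return steps[-1]


def classify_subthreshold(corrected: Sweep) -> SubthresholdProfile:
    """Classify and measure the dominant transient of the P/N-corrected
    response to the -40 mV step."""
    require_units(corrected, "pA")
    ep = _depol_epoch(corrected)
    dt = corrected.dt
    i_on = int(round(ep.start_ms / dt))
    i_off = int(round(ep.end_ms / dt))
    i0 = i_on + int(EDGE_BLANK_MS / dt)
    # light boxcar smoothing before peak finding: the currents of interest
    # develop over >= 5 ms, while the uncorrelated sample noise would
    # otherwise dominate the extreme statistic of a 200 ms window
    w = max(1, int(SMOOTH_MS / dt))
    kern = np.ones(w) / w
    smooth = np.convolve(corrected.samples, kern, mode="same")
    seg = smooth[i0:i_off]
    # noise floor from the raw pre-step baseline, rescaled to the smoothed
    # trace (boxcar over w uncorrelated samples reduces the sd by sqrt(w));
    # the raw window gives a far better-conditioned sd estimate than the
    # handful of independent smoothed samples
    base_win = corrected.samples[max(0, i_on - int(50.0 / dt)): i_on]
    noise_sd = float(np.std(base_win)) / math.sqrt(w) if base_win.size else 0.0

    prof = SubthresholdProfile()
    i_max = int(np.argmax(seg))
    i_min = int(np.argmin(seg))
    out_pk, in_pk = float(seg[i_max]), float(seg[i_min])
    prof.diagnostics = {"outward_peak_pa": out_pk, "inward_peak_pa": in_pk,
                        "noise_sd_pa": noise_sd}
    if max(abs(out_pk), abs(in_pk)) < NC_NOISE_FLOOR_SD * noise_sd:
        prof.current_class = "NC"
        return prof
    if abs(out_pk) >= abs(in_pk):
        i_pk, peak = i_max, out_pk
        if abs(in_pk) >= NC_NOISE_FLOOR_SD * noise_sd:
            prof.diagnostics["secondary_inward_pa"] = in_pk
    else:
        i_pk, peak = i_min, in_pk
        if abs(out_pk) >= NC_NOISE_FLOOR_SD * noise_sd:
            prof.diagnostics["secondary_outward_pa"] = out_pk
    # refine the peak location on the raw trace around the smoothed peak:
    # smoothing locates the transient robustly but biases the argmax of an
    # asymmetric peak by up to half the boxcar width
    raw = corrected.samples[i0:i_off]
    r0 = max(0, i_pk - w)
    r1 = min(raw.size, i_pk + w + 1)
    local = raw[r0:r1]
    i_pk = r0 + int(np.argmax(local) if peak > 0 else np.argmin(local))
    prof.peak_amplitude_pa = peak
    prof.latency_ms = (i0 + i_pk - i_on) * dt
    if peak > 0:
        prof.current_class = ("KA_fast" if prof.latency_ms < KA_LATENCY_BOUNDARY_MS
                              else "KA_slow")
    else:
        prof.current_class = "CaT_like"
    decay = seg[i_pk:]
    half = peak / 2.0
    below = np.flatnonzero(decay <= half) if peak > 0 else np.flatnonzero(decay >= half)
    if below.size:
        prof.half_decay_ms = float(below[0] * dt)
    else:
        prof.diagnostics["half_decay"] = "not reached within the step"
    return prof


def detect_ih(
    response: Sweep,
    noise_criterion_sd: float = 3.0,
    early_window_ms: tuple[float, float] = (20.0, 100.0),
) -> tuple[bool, float]:
    """Detect a hyperpolarisation-activated sag current (Ih).

    Amplitude is the difference between the current at the early plateau
    (20-100 ms after onset of the hyperpolarising step) and at the end of
    the step; present when a slow monotone inward development exceeds three
    baseline standard deviations.  Returns ``(present, amplitude_pA)``.
    """
    require_units(response, "pA")
    steps = [ep for ep in response.epochs if ep.kind == "step" and ep.command_level < -75.0]
    if not steps:
        raise ProtocolError("no hyperpolarising step epoch")
    ep = steps[0]
    if ep.duration_ms < 1000.0:
        raise ProtocolError("hyperpolarising epoch shorter than 1 s; Ih undefined")
    dt = response.dt
    i_on = int(round(ep.start_ms / dt))
    i_off = int(round(ep.end_ms / dt))
    base = response.samples[max(0, i_on - int(50.0 / dt)): i_on]
    noise_sd = float(np.std(base)) if base.size else 0.0
    e0 = i_on + int(early_window_ms[0] / dt)
    e1 = i_on + int(early_window_ms[1] / dt)
    early = float(np.mean(response.samples[e0:e1]))
    end = float(np.mean(response.samples[i_off - int(50.0 / dt): i_off]))
    amplitude = early - end  # inward (downward) development -> positive
    # require slow monotone development: mid-step level between the two
    mid = float(np.mean(response.samples[(e1 + i_off) // 2 - int(25.0 / dt):
                                         (e1 + i_off) // 2 + int(25.0 / dt)]))
    monotone = (end <= mid <= early) or (early <= mid <= end)
    present = bool(amplitude > noise_criterion_sd * max(noise_sd, 1e-12) and monotone)
    return present, float(amplitude)
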