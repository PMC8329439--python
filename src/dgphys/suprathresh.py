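"""Spike detection and suprathreshold (action-potential) measurements.

Thirteen measurements: the f-I curve at 50..250 pA (five rates, each the
spike count of a 700 ms injection extrapolated to 1 s), and eight
features of the response to the 250 pA pulse -- AP threshold (V_th, the
voltage where dV/dt first crosses 20 V/s on the upstroke), peak voltage
(V_AP_peak), AP amplitude relative to rest (V_AP), half-width referenced
to V_RMP (T_APHW), latency to first spike (T_1AP), first inter-spike
interval (T_1ISI, undefined with fewer than two spikes), and the extreme
temporal derivatives dVdt_max/dVdt_min.

dV/dt is a centered finite difference of voltage in mV over time in ms,
which is numerically equal to V/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import MeasurementError
from .subthresh import TimeSeriesTrace

__all__ = [
    "APMeasures",
    "detect_spikes",
    "firing_rate_curve",
    "ap_features",
    "DVDT_THRESHOLD",
    "FI_AMPLITUDES",
]

#: dV/dt threshold defining AP threshold (V/s).
DVDT_THRESHOLD = 20.0

#: Spike-peak acceptance criterion (mV) and refractory merge window (ms).
PEAK_CRITERION_MV = 0.0
MERGE_WINDOW_MS = 2.0

#: f-I protocol amplitudes (pA) and pulse duration (ms).
FI_AMPLITUDES = (50.0, 100.0, 150.0, 200.0, 250.0)
FI_DURATION_MS = 700.0


@dataclass
class APMeasures:
    """Suprathreshold measurements for one cell under one condition."""

    v_th: float
    v_ap_peak: float
    v_ap: float
    t_aphw: float
    t_1ap: float
    t_1isi: float  # NaN when fewer than two spikes
    dvdt_max: float
    dvdt_min: float
    firing_rates: Mapping[float, float] = field(default_factory=dict)


def _dvdt(v: np.ndarray, dt: float) -> np.ndarray:
    """Centered-difference temporal derivative, V/s (== mV/ms)."""
    return np.gradient(v, dt)


def detect_spikes(
    trace: TimeSeriesTrace,
    peak_criterion: float = PEAK_CRITERION_MV,
    merge_window: float = MERGE_WINDOW_MS,
    dvdt_threshold: float = DVDT_THRESHOLD,
) -> np.ndarray:
    """Spike peak times (ms), strictly increasing.

    A spike is a local voltage maximum above `peak_criterion` whose
    preceding upstroke crosses `dvdt_threshold` V/s; maxima closer than
    `merge_window` ms are merged (the larger peak is kept).
    """
    v = trace.voltage
    if v.size < 3 or np.max(v) < peak_criterion:
        return np.array([])
    dv = _dvdt(v, trace.dt)
    interior = np.nonzero(
        (v[1:-1] >= v[:-2]) & (v[1:-1] > v[2:]) & (v[1:-1] > peak_criterion)
    )[0] + 1
    peaks = []
    for k in interior:
        # require a fast upstroke in the 5 ms leading up to the peak
        j0 = max(0, k - int(round(5.0 / trace.dt)))
        if np.max(dv[j0 : k + 1]) >= dvdt_threshold:
            peaks.append(k)
    merged: list[int] = []
    for k in peaks:
        if merged and (k - merged[-1]) * trace.dt < merge_window:
            if v[k] > v[merged[-1]]:
                merged[-1] = k
        else:
            merged.append(k)
    return np.array(merged) * trace.dt


def firing_rate_curve(
    responses: Sequence[tuple[float, TimeSeriesTrace]],
    duration_ms: float = FI_DURATION_MS,
) -> dict[float, float]:
    """f-I curve: spike count of each `duration_ms` injection scaled to 1 s.

    With the standard 700 ms pulses the rate is ``count / 0.7`` Hz.
    """
    rates: dict[float, float] = {}
    for amp, tr in responses:
        if not math.isclose(tr.t_off - tr.t_on, duration_ms, rel_tol=1e-6):
            raise ValueError(
                f"f-I pulse duration {tr.t_off - tr.t_on} ms != expected {duration_ms} ms"
            )
        n_spk = detect_spikes(tr).size
        rates[float(amp)] = n_spk / (duration_ms / 1000.0)
    return rates


def _cross_time(t0: float, y0: float, t1: float, y1: float, level: float) -> float:
    """Linear-interpolated crossing time of `level` between two samples."""
    if y1 == y0:
        return t0
    return t0 + (level - y0) / (y1 - y0) * (t1 - t0)


def ap_features(
    trace: TimeSeriesTrace,
    v_rmp: float | None = None,
    dvdt_threshold: float = DVDT_THRESHOLD,
) -> APMeasures:
    """AP waveform features from the first spike of a suprathreshold trace.

    `v_rmp` defaults to the trace's recorded resting potential.  T_1ISI
    is NaN (flagged undefined, not an error) when only one spike fired.
    """
    if v_rmp is None:
        v_rmp = trace.v_rmp
    if v_rmp is None:
        raise ValueError("ap_features needs v_rmp (argument or trace.v_rmp)")
    peaks = detect_spikes(trace, dvdt_threshold=dvdt_threshold)
    if peaks.size == 0:
        raise MeasurementError("no AP in trace: cannot compute AP features")
    v = trace.voltage
    dt = trace.dt
    dv = _dvdt(v, dt)
    k_peak = trace.index(peaks[0])

    # threshold: first upward 20 V/s crossing in the upstroke before the peak
    k_th = None
    for k in range(k_peak, 0, -1):
        if dv[k - 1] < dvdt_threshold <= dv[k]:
            k_th = k
            break
    if k_th is None:
        raise MeasurementError("no 20 V/s upstroke crossing before the first peak")
    t_th = _cross_time((k_th - 1) * dt, dv[k_th - 1], k_th * dt, dv[k_th], dvdt_threshold)
    v_th = float(np.interp(t_th, [(k_th - 1) * dt, k_th * dt], [v[k_th - 1], v[k_th]]))

    v_ap_peak = float(v[k_peak])
    v_ap = v_ap_peak - v_rmp

    # half-width at v_rmp + v_ap/2, linear interpolation on both flanks
    half = v_rmp + v_ap / 2.0
    k = k_peak
    while k > 0 and v[k] > half:
        k -= 1
    t_rise = _cross_time(k * dt, v[k], (k + 1) * dt, v[k + 1], half)
    k = k_peak
    while k < v.size - 1 and v[k] > half:
        k += 1
    t_fall = _cross_time((k - 1) * dt, v[k - 1], k * dt, v[k], half)
    t_aphw = t_fall - t_rise

    t_1ap = float(peaks[0] - trace.t_on)
    t_1isi = float(peaks[1] - peaks[0]) if peaks.size >= 2 else float("nan")

    # derivative extremes over the first spike window (threshold to trough)
    k_end = trace.index(peaks[1]) if peaks.size >= 2 else v.size
    k_end = min(k_end, k_peak + int(round(10.0 / dt)))
    win = slice(max(0, k_th - 1), k_end)
    dvdt_max = float(np.max(dv[win]))
    dvdt_min = float(np.min(dv[win]))

    return APMeasures(
        v_th=v_th,
        v_ap_peak=v_ap_peak,
        v_ap=v_ap,
        t_aphw=t_aphw,
        t_1ap=t_1ap,
        t_1isi=t_1isi,
        dvdt_max=dvdt_max,
        dvdt_min=dvdt_min,
    )
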