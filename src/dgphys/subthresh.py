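"""Subthreshold intrinsic measurements from current-clamp traces.

Implements the eight subthreshold readouts used throughout the pipeline:
resting membrane potential (V_RMP), input resistance from the V-I slope
(R_in), percentage sag on a -100 pA pulse, temporal summation ratio of an
alpha-EPSP train (S_alpha), and the chirp-based impedance measurements
|Z|max, resonance frequency f_R, resonance strength Q and total inductive
phase Phi_L, plus the voltage-dependence protocol that repeats the
single-pulse R_in estimate and the impedance profile at several holding
voltages.

Conventions: voltage mV, current pA, time ms, impedance MOhm.  A slope of
1 mV/pA equals 1 GOhm, hence the factor 1000 between mV/pA fits and MOhm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import MeasurementError
from .stimgen import StimulusTrace

__all__ = [
    "TimeSeriesTrace",
    "ImpedanceProfile",
    "SubthresholdMeasures",
    "measure_rmp",
    "input_resistance",
    "percentage_sag",
    "summation_ratio",
    "impedance_profile",
    "impedance_metrics",
    "inductive_phase",
    "voltage_dependence",
    "steady_state_deflection",
    "DEFAULT_BAND",
]

#: Impedance analysis band (Hz).  The chirp starts at DC, which makes
#: frequencies below ~0.5 Hz ill-conditioned; 0.5 Hz is also the anchor
#: of the Q definition.
DEFAULT_BAND = (0.5, 15.0)

#: Steady-state window: mean over the last 100 ms of the pulse.
SS_WINDOW_MS = 100.0

#: Baseline window for V_RMP (ms of stimulus-free trace before onset).
RMP_WINDOW_MS = 100.0

#: Voltage above which a subthreshold trace is considered contaminated
#: by a spike (mV).
SPIKE_GUARD_MV = -20.0


@dataclass
class TimeSeriesTrace:
    """Uniformly sampled voltage (and optionally current) recording."""

    dt: float
    voltage: np.ndarray
    current: np.ndarray | None = None
    t_on: float = 0.0
    t_off: float = 0.0
    v_rmp: float | None = None
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=np.float64)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not np.all(np.isfinite(self.voltage)):
            raise ValueError("voltage trace contains non-finite samples")
        if self.current is not None:
            self.current = np.asarray(self.current, dtype=np.float64)
            if self.current.size != self.voltage.size:
                raise ValueError(
                    f"current length {self.current.size} != voltage length {self.voltage.size}"
                )

    @property
    def n(self) -> int:
        return self.voltage.size

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n) * self.dt

    def index(self, t_ms: float) -> int:
        return int(round(t_ms / self.dt))


@dataclass
class ImpedanceProfile:
    """|Z(f)| and phase(f) on an ascending frequency grid, restricted to a band."""

    freq: np.ndarray
    z_mag: np.ndarray
    z_phase: np.ndarray
    band: tuple[float, float] = DEFAULT_BAND

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=np.float64)
        self.z_mag = np.asarray(self.z_mag, dtype=np.float64)
        self.z_phase = np.asarray(self.z_phase, dtype=np.float64)
        if np.any(np.diff(self.freq) <= 0):
            raise ValueError("frequency grid must be strictly ascending")
        if np.any(self.z_mag < 0):
            raise ValueError("impedance magnitude must be non-negative")


@dataclass
class SubthresholdMeasures:
    """The eight subthreshold measurements for one cell under one condition."""

    v_rmp: float
    r_in: float
    sag_pct: float
    s_alpha: float
    z_max: float
    f_r: float
    q: float
    phi_l: float
    r_in_by_voltage: Mapping[float, float] = field(default_factory=dict)
    z_max_by_voltage: Mapping[float, float] = field(default_factory=dict)


def _baseline(trace: TimeSeriesTrace, window_ms: float) -> float:
    if trace.t_on < window_ms - 1e-9:
        raise MeasurementError(
            f"need >= {window_ms} ms of stimulus-free baseline, trace has {trace.t_on} ms"
        )
    i0 = trace.index(trace.t_on - window_ms)
    i1 = trace.index(trace.t_on)
    return float(np.mean(trace.voltage[i0:i1]))


def measure_rmp(trace: TimeSeriesTrace, window_ms: float = RMP_WINDOW_MS) -> float:
    """Resting membrane potential: mean voltage over the pre-stimulus baseline."""
    return _baseline(trace, window_ms)


def steady_state_deflection(
    trace: TimeSeriesTrace, window_ms: float = SS_WINDOW_MS
) -> float:
    """Steady-state voltage deflection from baseline (mV, signed).

    Mean over the last `window_ms` of the pulse minus the pre-stimulus
    baseline.
    """
    base = _baseline(trace, RMP_WINDOW_MS)
    i0 = trace.index(trace.t_off - window_ms)
    i1 = trace.index(trace.t_off)
    if i1 <= i0:
        raise MeasurementError("pulse shorter than the steady-state window")
    return float(np.mean(trace.voltage[i0:i1])) - base


def _guard_spikes(v: np.ndarray, what: str) -> None:
    if np.any(v > SPIKE_GUARD_MV):
        raise MeasurementError(f"spike detected in {what}: trace is not subthreshold")


def input_resistance(
    responses: Sequence[tuple[float, TimeSeriesTrace]],
    window_ms: float = SS_WINDOW_MS,
) -> float:
    """Input resistance (MOhm) from the slope of the steady-state V-I plot.

    `responses` pairs each injected amplitude (pA; -25..+25 in 5 pA steps
    in the standard protocol) with the recorded trace.  The slope of the
    least-squares line through (amplitude, deflection) is returned in
    MOhm.
    """
    amps = np.array([a for a, _ in responses], dtype=np.float64)
    if np.unique(amps).size < 2:
        raise ValueError("input_resistance needs >= 2 distinct amplitudes")
    defl = np.empty_like(amps)
    for i, (_, tr) in enumerate(responses):
        _guard_spikes(tr.voltage[tr.index(tr.t_on) : tr.index(tr.t_off)], "V-I pulse")
        defl[i] = steady_state_deflection(tr, window_ms)
    slope = np.polyfit(amps, defl, 1)[0]  # mV/pA
    return float(slope * 1000.0)


def percentage_sag(
    trace: TimeSeriesTrace,
    window_ms: float = SS_WINDOW_MS,
    noise_floor_mv: float = 0.5,
) -> float:
    """Percentage sag, ``100*(1 - Vss/Vpeak)``, on a hyperpolarizing pulse.

    Vpeak is the extremal (most negative) deflection from baseline within
    the pulse and Vss the steady-state deflection; both are signed, so a
    purely passive response gives 0 and a sagging response a positive
    percentage.
    """
    base = _baseline(trace, RMP_WINDOW_MS)
    i0, i1 = trace.index(trace.t_on), trace.index(trace.t_off)
    seg = trace.voltage[i0:i1] - base
    v_peak = float(np.min(seg))
    if v_peak >= 0:
        raise ValueError("percentage_sag expects a hyperpolarizing pulse")
    if abs(v_peak) < noise_floor_mv:
        raise MeasurementError(
            f"peak deflection {v_peak:.3g} mV below noise floor {noise_floor_mv} mV"
        )
    v_ss = steady_state_deflection(trace, window_ms)
    return float(100.0 * (1.0 - v_ss / v_peak))


def summation_ratio(
    trace: TimeSeriesTrace,
    n_events: int = 5,
    interval: float = 50.0,
    noise_floor_mv: float = 0.05,
) -> float:
    """Temporal summation ratio S_alpha = E_last / E_first of an EPSP train.

    Event j's amplitude is the peak voltage within its window
    ``[t_on + j*interval, t_on + (j+1)*interval)`` minus the pre-train
    baseline, so later amplitudes ride on the residual depolarization
    left by earlier events -- summation (S_alpha > 1) means the last
    peak sits higher above rest than the first.
    """
    base = _baseline(trace, RMP_WINDOW_MS)
    amps = []
    for j in range(n_events):
        on = trace.t_on + j * interval
        i0 = trace.index(on)
        i1 = trace.index(on + interval)
        if j == n_events - 1:
            i1 = min(trace.n, trace.index(on + 2 * interval))
        seg = trace.voltage[i0:i1]
        if seg.size == 0:
            raise MeasurementError(f"event {j} window is outside the trace")
        _guard_spikes(seg, "alpha-EPSP train")
        amps.append(float(np.max(seg) - base))
    if abs(amps[0]) < noise_floor_mv:
        raise MeasurementError("first EPSP amplitude below noise floor")
    return amps[-1] / amps[0]


def impedance_profile(
    v_trace: TimeSeriesTrace,
    i_trace: StimulusTrace | TimeSeriesTrace | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
    smooth_hz: float | None = None,
) -> ImpedanceProfile:
    """Impedance profile Z(f) from a chirp voltage/current pair.

    ``Z(f) = FFT(V - mean V) / FFT(I - mean I)`` on the chirp window; the
    magnitude is the impedance amplitude profile (ZAP, MOhm) and the
    angle the impedance phase profile (ZPP, rad), both restricted to
    `band`.  Optional moving-average smoothing over `smooth_hz` wide
    windows.
    """
    if i_trace is None:
        if v_trace.current is None:
            raise ValueError("impedance_profile needs a current trace")
        i_samp = v_trace.current
    else:
        i_samp = i_trace.samples if isinstance(i_trace, StimulusTrace) else i_trace.current
        if i_samp is None:
            raise ValueError("i_trace carries no current samples")
    if i_samp.size != v_trace.n:
        raise ValueError(
            f"voltage ({v_trace.n}) and current ({i_samp.size}) lengths differ"
        )
    i0, i1 = v_trace.index(v_trace.t_on), v_trace.index(v_trace.t_off)
    v = v_trace.voltage[i0:i1]
    i = np.asarray(i_samp, dtype=np.float64)[i0:i1]
    fv = np.fft.rfft(v - v.mean())
    fi = np.fft.rfft(i - i.mean())
    freq = np.fft.rfftfreq(v.size, d=v_trace.dt / 1000.0)
    mask = (freq >= band[0]) & (freq <= band[1])
    fi_band = np.abs(fi[mask])
    if np.any(fi_band < 1e-9 * fi_band.max()):
        raise MeasurementError("chirp current spectrum vanishes inside the band")
    z = fv[mask] / fi[mask] * 1000.0  # mV/pA -> MOhm
    z_mag = np.abs(z)
    z_phase = np.angle(z)
    if smooth_hz is not None and smooth_hz > 0:
        df = freq[1] - freq[0]
        w = max(1, int(round(smooth_hz / df)))
        kernel = np.ones(w) / w
        pad = w // 2
        z_mag = np.convolve(np.pad(z_mag, pad, mode="edge"), kernel, "same")[pad : pad + z_mag.size]
        z_phase = np.convolve(np.pad(z_phase, pad, mode="edge"), kernel, "same")[pad : pad + z_phase.size]
    return ImpedanceProfile(freq=freq[mask], z_mag=z_mag, z_phase=z_phase, band=band)


def impedance_metrics(profile: ImpedanceProfile) -> tuple[float, float, float]:
    """(|Z|max, f_R, Q) from an impedance profile.

    |Z|max is the maximum impedance amplitude on the band, f_R the lowest
    frequency attaining it, and Q = |Z|max / |Z|(0.5 Hz) with the 0.5 Hz
    value linearly interpolated from neighbouring grid points.
    """
    lo, hi = profile.band
    if not (lo <= 0.5 <= hi):
        raise ValueError("Q definition needs 0.5 Hz inside the analysis band")
    k = int(np.argmax(profile.z_mag))  # argmax returns the first (lowest-f) maximum
    z_max = float(profile.z_mag[k])
    f_r = float(profile.freq[k])
    z_half = float(np.interp(0.5, profile.freq, profile.z_mag))
    return z_max, f_r, z_max / z_half


def inductive_phase(profile: ImpedanceProfile) -> float:
    """Total inductive phase Phi_L (rad*Hz): area under the positive ZPP."""
    pos = np.clip(profile.z_phase, 0.0, None)
    return float(np.trapezoid(pos, profile.freq))


def voltage_dependence(
    model,
    holding_voltages: Sequence[float] = (-85.0, -80.0, -75.0, -70.0, -65.0),
    chirp_amplitude: float = 30.0,
    band: tuple[float, float] = DEFAULT_BAND,
) -> tuple[dict[float, float], dict[float, float]]:
    """Single-pulse R_in and |Z|max at each holding voltage.

    For every holding voltage a bias current is solved that settles the
    model there; a -100 pA pulse then gives ``R_in = |deflection|/100``
    (in MOhm via the mV/pA convention) and a Chirp15 sweep gives |Z|max.
    Returns the two voltage->value mappings.
    """
    from . import sim  # deferred: sim consumes this module's trace types

    if not 2 <= len(holding_voltages) <= 8:
        raise ValueError("voltage_dependence expects 2-8 holding voltages")
    r_map: dict[float, float] = {}
    z_map: dict[float, float] = {}
    for v_hold in holding_voltages:
        bias = sim.bias_for_voltage(model, v_hold)
        tr = sim.simulate(model, sim.sag_pulse_stimulus(), v_init=v_hold, bias=bias)
        defl = steady_state_deflection(tr)
        r_map[v_hold] = abs(defl) / 100.0 * 1000.0
        chirp = sim.chirp_stimulus(amplitude=chirp_amplitude)
        tv = sim.simulate(model, chirp, v_init=v_hold, bias=bias)
        prof = impedance_profile(tv, chirp, band=band)
        z_map[v_hold], _, _ = impedance_metrics(prof)
    return r_map, z_map
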