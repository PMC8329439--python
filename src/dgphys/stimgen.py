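"""Stimulus waveform generation for current-clamp protocols.

Three waveform families cover every protocol in the pipeline: square
current pulses (V-I curves, sag, f-I), trains of alpha-function current
injections mimicking EPSCs, and the linear chirp used for impedance
profiling.  All quantities are in the package-wide units: time in ms,
current in pA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "StimulusTrace",
    "make_step",
    "make_alpha_train",
    "make_chirp",
    "DEFAULT_DT",
    "CHIRP_F0",
    "CHIRP_F1",
    "CHIRP_DURATION",
]

#: Default sampling interval, ms (20 kHz).
DEFAULT_DT = 0.05

#: Chirp15 band and duration: 0-15 Hz swept linearly over 15 s.
CHIRP_F0 = 0.0
CHIRP_F1 = 15.0
CHIRP_DURATION = 15000.0


@dataclass(frozen=True)
class StimulusTrace:
    """A uniformly sampled injected-current waveform.

    Attributes
    ----------
    dt : float
        Sampling interval (ms).
    samples : np.ndarray
        Injected current at each sample (pA).
    t_on, t_off : float
        Stimulus onset/offset (ms); outside ``[t_on, t_off)`` the trace
        sits at the holding value (0 pA by default).
    kind : str
        One of ``{"step", "alpha_train", "chirp"}``.
    params : mapping
        Generator parameters used to build the waveform.
    """

    dt: float
    samples: np.ndarray
    t_on: float
    t_off: float
    kind: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not np.all(np.isfinite(samples)):
            raise ValueError("stimulus samples must be finite")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Total trace duration (ms)."""
        return self.n * self.dt

    @property
    def time(self) -> np.ndarray:
        """Sample times (ms), starting at 0."""
        return np.arange(self.n) * self.dt


def _n_samples(total: float, dt: float) -> int:
    n = int(round(total / dt))
    if abs(n * dt - total) > dt:
        raise ValueError(f"total={total} ms is not a multiple of dt={dt} ms")
    return n


def make_step(
    amplitude: float,
    t_on: float,
    duration: float,
    total: float,
    dt: float = DEFAULT_DT,
) -> StimulusTrace:
    """Square current pulse of `amplitude` pA on ``[t_on, t_on+duration)``.

    Used for the V-I input-resistance protocol (-25..+25 pA in 5 pA
    steps), the -100 pA sag pulse, and the 50-250 pA f-I series.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if t_on < 0 or t_on + duration > total + 1e-9:
        raise ValueError(
            f"pulse [{t_on}, {t_on + duration}) ms extends beyond total={total} ms"
        )
    n = _n_samples(total, dt)
    t = np.arange(n) * dt
    samples = np.where((t >= t_on) & (t < t_on + duration), float(amplitude), 0.0)
    return StimulusTrace(
        dt=dt,
        samples=samples,
        t_on=t_on,
        t_off=t_on + duration,
        kind="step",
        params={"amplitude": amplitude, "duration": duration, "total": total},
    )


def make_alpha_train(
    i_max: float,
    alpha: float = 0.1,
    n_events: int = 5,
    interval: float = 50.0,
    t_on: float = 100.0,
    total: float = 500.0,
    dt: float = DEFAULT_DT,
    normalize_peak: bool = True,
) -> StimulusTrace:
    """Train of alpha-current injections ``I(t) = i_max * t * exp(-alpha*t)``.

    Each of `n_events` kernels is shifted by ``j * interval`` from `t_on`
    and is zero before its own onset; the trace is their superposition.

    With ``normalize_peak=True`` (default) `i_max` is interpreted as the
    desired kernel *peak* in pA: the analytic peak of ``t*exp(-alpha*t)``
    is ``exp(-1)/alpha`` at ``t = 1/alpha``, so each kernel is rescaled by
    ``alpha*e``.  Without normalization `i_max` carries units pA/ms.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    if n_events < 1:
        raise ValueError(f"n_events must be >= 1, got {n_events}")
    if interval <= 0:
        raise ValueError(f"interval must be positive, got {interval}")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    n = _n_samples(total, dt)
    t = np.arange(n) * dt
    scale = i_max * alpha * np.e if normalize_peak else i_max
    samples = np.zeros(n)
    for j in range(n_events):
        rel = t - (t_on + j * interval)
        np.add(samples, np.where(rel > 0, scale * rel * np.exp(-alpha * np.clip(rel, 0, None)), 0.0), out=samples)
    return StimulusTrace(
        dt=dt,
        samples=samples,
        t_on=t_on,
        t_off=t_on + (n_events - 1) * interval + 10.0 / alpha,
        kind="alpha_train",
        params={
            "i_max": i_max,
            "alpha": alpha,
            "n_events": n_events,
            "interval": interval,
            "normalize_peak": normalize_peak,
        },
    )


def make_chirp(
    amplitude: float = 30.0,
    f0: float = CHIRP_F0,
    f1: float = CHIRP_F1,
    duration: float = CHIRP_DURATION,
    dt: float = DEFAULT_DT,
    t_on: float = 0.0,
    t_post: float = 0.0,
) -> StimulusTrace:
    """Constant-amplitude sinusoid with frequency swept linearly f0 -> f1.

    ``I(t) = amplitude * sin(2*pi*(f0*t + (f1-f0)*t^2/(2*duration)))`` with
    the phase integral evaluated in seconds.  The default is the Chirp15
    stimulus: 0-15 Hz over 15 s.  `t_on`/`t_post` prepend/append silent
    padding (baseline and settling).
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if f1 <= f0 or f0 < 0:
        raise ValueError(f"need f1 > f0 >= 0, got f0={f0}, f1={f1}")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    total = t_on + duration + t_post
    n = _n_samples(total, dt)
    t = np.arange(n) * dt
    rel_s = (t - t_on) / 1000.0  # seconds
    dur_s = duration / 1000.0
    phase = 2.0 * np.pi * (f0 * rel_s + (f1 - f0) * rel_s**2 / (2.0 * dur_s))
    samples = np.where(
        (t >= t_on) & (rel_s < dur_s), amplitude * np.sin(phase), 0.0
    )
    return StimulusTrace(
        dt=dt,
        samples=samples,
        t_on=t_on,
        t_off=t_on + duration,
        kind="chirp",
        params={"amplitude": amplitude, "f0": f0, "f1": f1, "duration": duration},
    )
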