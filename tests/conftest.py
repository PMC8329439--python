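"""Shared fixtures: synthetic traces, the default model, and the
session-scoped virtual-knockout study used by the population-level tests."""

from __future__ import annotations

import numpy as np
import pytest

import dgphys
from dgphys import sim
from dgphys.stats import run_blockade_study
from dgphys.subthresh import TimeSeriesTrace

N_CELLS = 20
SEED = 1


@pytest.fixture(scope="session")
def default_model():
    return sim.default_model()


@pytest.fixture(scope="session")
def default_record(default_model):
    """Full 21-measurement battery on the reference model."""
    return sim.run_protocol_suite(default_model)


@pytest.fixture(scope="session")
def population():
    """20 heterogeneous valid model cells (fixed seed)."""
    return sim.sample_population(sim.PopulationSpec(n_cells=N_CELLS, seed=SEED))


@pytest.fixture(scope="session")
def study(population):
    """Virtual-knockout study: baseline + full block of each channel."""
    return run_blockade_study(population, seed=SEED)


def rc_step_response(
    r_mohm: float,
    tau_ms: float,
    amplitude_pa: float,
    t_on: float = 200.0,
    duration: float = 700.0,
    total: float = 1100.0,
    dt: float = 0.05,
    baseline_mv: float = -75.0,
) -> TimeSeriesTrace:
    """Analytic RC response to a current step (independent of the simulator)."""
    t = np.arange(int(round(total / dt))) * dt
    v_ss = amplitude_pa * r_mohm / 1000.0  # mV
    v = np.full(t.size, baseline_mv)
    on = (t >= t_on) & (t < t_on + duration)
    v[on] += v_ss * (1.0 - np.exp(-(t[on] - t_on) / tau_ms))
    off = t >= t_on + duration
    v_end = v_ss * (1.0 - np.exp(-duration / tau_ms))
    v[off] += v_end * np.exp(-(t[off] - t_on - duration) / tau_ms)
    amps = np.where(on, amplitude_pa, 0.0)
    return TimeSeriesTrace(
        dt=dt, voltage=v, current=amps, t_on=t_on, t_off=t_on + duration,
        v_rmp=baseline_mv,
    )


def template_spike_trace(
    peak_times_ms,
    t_on: float = 50.0,
    total: float = 700.0,
    dt: float = 0.05,
    baseline_mv: float = -75.0,
    peak_mv: float = 40.0,
    width_ms: float = 1.0,
) -> TimeSeriesTrace:
    """Gaussian template spikes on a flat baseline (fast enough to cross 20 V/s)."""
    t = np.arange(int(round(total / dt))) * dt
    v = np.full(t.size, baseline_mv)
    for tp in peak_times_ms:
        v += (peak_mv - baseline_mv) * np.exp(-0.5 * ((t - tp) / (width_ms / 2.355)) ** 2)
    return TimeSeriesTrace(dt=dt, voltage=v, t_on=t_on, t_off=total, v_rmp=baseline_mv)
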