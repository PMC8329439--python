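"""Single-compartment conductance-based granule-cell model.

The synthetic-data generator of the pipeline: a somatic compartment with
six conductances -- passive leak, HCN (hyperpolarization-activated,
slow, tau ~500 ms, reversal -30 mV, hence a restorative mixed-cation
current), an instantaneous inward-rectifier potassium conductance (Kir,
open at hyperpolarized voltages), an instantaneous persistent sodium
conductance (NaP, amplifying near spike threshold), and a
transient-Na/delayed-rectifier-K spiking pair (NaT/KDR).  Gating uses
Boltzmann steady states with first-order kinetics; membrane dynamics are

    C dV/dt = -[ I_leak + I_HCN + I_Kir + I_NaP + I_NaT + I_KDR ] + I_inj

integrated by exponential Euler at an effective step <= 0.025 ms (the
HCN time constant of 500 ms against sub-ms spike dynamics makes the
system stiff; exponential Euler is unconditionally stable for the
voltage update).  The inner loop is JIT-compiled with numba when
available.

Pharmacological blockade is emulated by per-channel conductance scaling
(`apply_blockade`); heterogeneous cell populations are drawn by
rejection sampling against physiological validity windows
(`sample_population`); `run_protocol_suite` executes the full recording
battery and returns all 21 measurements.

Units: mV, pA, nS, pF, ms (so g*V is pA and C/g is ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import IntegrationError, MeasurementError, ProtocolError, SamplingError
from .records import MeasurementRecord
from .stimgen import StimulusTrace, make_alpha_train, make_chirp, make_step
from .subthresh import (
    TimeSeriesTrace,
    impedance_metrics,
    impedance_profile,
    inductive_phase,
    input_resistance,
    measure_rmp,
    percentage_sag,
    summation_ratio,
    voltage_dependence,
)
from .suprathresh import FI_AMPLITUDES, ap_features, detect_spikes, firing_rate_curve

try:  # pragma: no cover - exercised implicitly by every simulation
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(fn):
            return fn

        return deco


__all__ = [
    "GateKinetics",
    "GranuleCellModel",
    "BlockadeSpec",
    "PopulationSpec",
    "gate_inf",
    "steady_state_current",
    "find_rest",
    "bias_for_voltage",
    "simulate",
    "apply_blockade",
    "sample_population",
    "run_protocol_suite",
    "quick_measures",
    "default_model",
    "default_bounds",
    "default_validity",
    "CHANNELS",
    "MAX_SUBSTEP_MS",
    "vi_amplitudes",
    "vi_step_stimulus",
    "sag_pulse_stimulus",
    "alpha_train_stimulus",
    "chirp_stimulus",
    "fi_step_stimulus",
]

#: Effective integration step ceiling (ms).
MAX_SUBSTEP_MS = 0.025

#: Channel names accepted by BlockadeSpec, mapped to the conductance they
#: scale.  Tertiapin-Q's target maps to no conductance in the default
#: model: it is the zero-effect control.
CHANNELS: dict[str, str | None] = {
    "HCN": "hcn",
    "Kir": "kir",
    "NaP": "nap",
    "TPQ_target": None,
}


@dataclass(frozen=True)
class GateKinetics:
    """Boltzmann gate: x_inf(v) = 1/(1+exp((v - v_half)/k)).

    A positive slope `k` gives activation by hyperpolarization (HCN,
    Kir), a negative one activation by depolarization (NaP, NaT-m, KDR).
    `tau` is the first-order time constant in ms; ``tau=None`` marks an
    instantaneous gate.  `exponent` is the gate power in the current.
    """

    v_half: float
    k: float
    tau: float | None = None
    exponent: int = 1

    def __post_init__(self) -> None:
        if self.k == 0:
            raise ValueError("slope factor k must be nonzero")
        if self.tau is not None and self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")


def gate_inf(v: float | np.ndarray, kin: GateKinetics) -> float | np.ndarray:
    """Steady-state activation of a Boltzmann gate at voltage `v` (mV)."""
    return 1.0 / (1.0 + np.exp((v - kin.v_half) / kin.k))


@dataclass(frozen=True)
class GranuleCellModel:
    """Passive properties, maximal conductances, kinetics and block state."""

    c_m: float  # pF
    g_leak: float  # nS
    g_hcn: float
    g_kir: float
    g_nap: float
    g_nat: float
    g_kdr: float
    e_leak: float  # mV
    e_h: float
    e_k: float
    e_na: float
    kinetics: Mapping[str, GateKinetics]
    block: Mapping[str, float] = field(
        default_factory=lambda: {"hcn": 1.0, "kir": 1.0, "nap": 1.0, "nat": 1.0, "kdr": 1.0}
    )

    def __post_init__(self) -> None:
        if self.c_m <= 0:
            raise ValueError("membrane capacitance must be positive")
        for name in ("g_leak", "g_hcn", "g_kir", "g_nap", "g_nat", "g_kdr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for ch, b in self.block.items():
            if not 0.0 <= b <= 1.0:
                raise ValueError(f"block factor for {ch} must lie in [0,1], got {b}")

    def effective(self, channel: str) -> float:
        """Maximal conductance of `channel` after blockade scaling (nS)."""
        return getattr(self, f"g_{channel}") * self.block.get(channel, 1.0)


@dataclass(frozen=True)
class BlockadeSpec:
    """One pharmacological manipulation: which channel, how completely."""

    channel: str
    fraction_blocked: float = 1.0

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(
                f"unknown channel {self.channel!r}; expected one of {sorted(CHANNELS)}"
            )
        if not 0.0 <= self.fraction_blocked <= 1.0:
            raise ValueError("fraction_blocked must lie in [0,1]")


def default_model(**overrides: float) -> GranuleCellModel:
    """Reference granule-cell model.

    Conductance densities are tuned so the baseline battery lands inside
    the control windows typical of mature granule cells: RMP near
    -75 mV, R_in in the 150-210 MOhm range, Q ~ 1 with no inductive
    phase, small sag, and sparse regular firing at 50-250 pA.
    """
    params = dict(
        c_m=150.0,
        g_leak=3.8,
        g_hcn=3.43,
        g_kir=4.0,
        g_nap=1.4,
        g_nat=5000.0,
        g_kdr=2800.0,
        e_leak=-71.9,
        e_h=-68.0,
        e_k=-95.0,
        e_na=55.0,
    )
    params.update(overrides)
    kinetics = {
        "hcn": GateKinetics(v_half=-75.0, k=18.0, tau=500.0),
        "kir": GateKinetics(v_half=-90.0, k=18.0, tau=None),
        "nap": GateKinetics(v_half=-46.0, k=-5.0, tau=None),
        "nat_m": GateKinetics(v_half=-38.0, k=-4.5, tau=0.1, exponent=3),
        "nat_h": GateKinetics(v_half=-47.0, k=5.0, tau=0.7),
        "kdr": GateKinetics(v_half=-33.0, k=-9.0, tau=2.5, exponent=4),
    }
    return GranuleCellModel(kinetics=kinetics, **params)


def apply_blockade(model: GranuleCellModel, spec: BlockadeSpec) -> GranuleCellModel:
    """Return a copy with the targeted conductance scaled by (1 - fraction).

    Blockades compose multiplicatively; all other parameters are
    untouched.  The tertiapin-Q target maps to no conductance, so the
    returned model is functionally identical to the input.
    """
    cond = CHANNELS[spec.channel]
    if cond is None:
        return replace(model, block=dict(model.block))
    block = dict(model.block)
    block[cond] = block.get(cond, 1.0) * (1.0 - spec.fraction_blocked)
    return replace(model, block=block)


# --------------------------------------------------------------------------
# steady state and integration
# --------------------------------------------------------------------------


def steady_state_current(model: GranuleCellModel, v: float) -> float:
    """Total ionic current (pA, outward positive) with every gate at x_inf(v)."""
    kin = model.kinetics
    i = model.g_leak * (v - model.e_leak)
    i += model.effective("hcn") * gate_inf(v, kin["hcn"]) * (v - model.e_h)
    i += model.effective("kir") * gate_inf(v, kin["kir"]) * (v - model.e_k)
    i += model.effective("nap") * gate_inf(v, kin["nap"]) * (v - model.e_na)
    i += (
        model.effective("nat")
        * gate_inf(v, kin["nat_m"]) ** kin["nat_m"].exponent
        * gate_inf(v, kin["nat_h"])
        * (v - model.e_na)
    )
    i += model.effective("kdr") * gate_inf(v, kin["kdr"]) ** kin["kdr"].exponent * (v - model.e_k)
    return float(i)


def find_rest(model: GranuleCellModel, bias: float = 0.0, lo: float = -120.0, hi: float = -40.0) -> float:
    """Resting potential: the hyperpolarized root of the steady-state current.

    Scans upward from `lo` for the first sign change of
    ``I_ss(v) - bias`` and refines it with Brent's method, which singles
    out the stable subthreshold fixed point even when the spiking pair
    introduces further roots near threshold.
    """
    f = lambda v: steady_state_current(model, v) - bias
    grid = np.linspace(lo, hi, 161)
    vals = np.array([f(v) for v in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:
        raise ProtocolError(f"no resting potential in [{lo}, {hi}] mV for bias {bias} pA")
    k = sign_change[0]
    return float(brentq(f, grid[k], grid[k + 1], xtol=1e-7))


def bias_for_voltage(model: GranuleCellModel, v_hold: float) -> float:
    """Constant bias current (pA) whose steady state sits at `v_hold`."""
    bias = steady_state_current(model, v_hold)
    # confirm the fixed point is reachable/stable: it must be the first root
    v_check = find_rest(model, bias=bias)
    if abs(v_check - v_hold) > 0.5:
        raise ProtocolError(
            f"holding voltage {v_hold} mV unreachable: settles at {v_check:.2f} mV"
        )
    return float(bias)


@njit(cache=False)
def _integrate(stim, dt, n_sub, v0, h0, hna0, n0, m0, p):  # pragma: no cover - JIT
    (
        c_m, g_l, g_h, g_kir, g_nap, g_nat, g_kdr,
        e_l, e_h, e_k, e_na,
        h_vh, h_k, h_tau,
        kir_vh, kir_k,
        nap_vh, nap_k,
        m_vh, m_k, m_tau,
        hna_vh, hna_k, hna_tau,
        n_vh, n_k, n_tau,
    ) = (
        p[0], p[1], p[2], p[3], p[4], p[5], p[6],
        p[7], p[8], p[9], p[10],
        p[11], p[12], p[13],
        p[14], p[15],
        p[16], p[17],
        p[18], p[19], p[20],
        p[21], p[22], p[23],
        p[24], p[25], p[26],
    )
    nt = stim.size
    out = np.empty(nt)
    v, h, hna, n, m = v0, h0, hna0, n0, m0
    hsub = dt / n_sub
    a_h = 1.0 - math.exp(-hsub / h_tau)
    a_hna = 1.0 - math.exp(-hsub / hna_tau)
    a_n = 1.0 - math.exp(-hsub / n_tau)
    a_m = 1.0 - math.exp(-hsub / m_tau) if m_tau > 0.0 else 1.0
    for i in range(nt):
        inj = stim[i]
        for _ in range(n_sub):
            h += (1.0 / (1.0 + math.exp((v - h_vh) / h_k)) - h) * a_h
            hna += (1.0 / (1.0 + math.exp((v - hna_vh) / hna_k)) - hna) * a_hna
            n += (1.0 / (1.0 + math.exp((v - n_vh) / n_k)) - n) * a_n
            kir = 1.0 / (1.0 + math.exp((v - kir_vh) / kir_k))
            pna = 1.0 / (1.0 + math.exp((v - nap_vh) / nap_k))
            m += (1.0 / (1.0 + math.exp((v - m_vh) / m_k)) - m) * a_m
            gh = g_h * h
            gk = g_kir * kir
            gp = g_nap * pna
            gn = g_nat * m * m * m * hna
            gd = g_kdr * n * n * n * n
            g_tot = g_l + gh + gk + gp + gn + gd
            v_inf = (
                g_l * e_l + gh * e_h + gk * e_k + gp * e_na + gn * e_na + gd * e_k + inj
            ) / g_tot
            v = v_inf + (v - v_inf) * math.exp(-hsub * g_tot / c_m)
        out[i] = v
        if abs(v) > 150.0:
            return out, i
    return out, -1


def _pack_params(model: GranuleCellModel) -> np.ndarray:
    kin = model.kinetics
    return np.array(
        [
            model.c_m,
            model.g_leak,
            model.effective("hcn"),
            model.effective("kir"),
            model.effective("nap"),
            model.effective("nat"),
            model.effective("kdr"),
            model.e_leak,
            model.e_h,
            model.e_k,
            model.e_na,
            kin["hcn"].v_half, kin["hcn"].k, kin["hcn"].tau,
            kin["kir"].v_half, kin["kir"].k,
            kin["nap"].v_half, kin["nap"].k,
            kin["nat_m"].v_half, kin["nat_m"].k, kin["nat_m"].tau or 0.0,
            kin["nat_h"].v_half, kin["nat_h"].k, kin["nat_h"].tau,
            kin["kdr"].v_half, kin["kdr"].k, kin["kdr"].tau,
        ],
        dtype=np.float64,
    )


def simulate(
    model: GranuleCellModel,
    stim: StimulusTrace,
    v_init: float | None = None,
    bias: float = 0.0,
    max_substep: float = MAX_SUBSTEP_MS,
    noise_sd: float = 0.0,
    seed: int | None = None,
    meta: Mapping[str, object] | None = None,
) -> TimeSeriesTrace:
    """Integrate the model under `stim` (+ constant `bias`), sample-aligned.

    `v_init` defaults to the resting potential under `bias`; gating
    states start at their steady values for `v_init`, so a zero stimulus
    holds the membrane at rest exactly.  Optional `noise_sd` adds seeded
    Gaussian recording noise (mV) to the *recorded* trace; the dynamics
    stay deterministic.
    """
    if v_init is None:
        v_init = find_rest(model, bias=bias)
    n_sub = max(1, int(math.ceil(stim.dt / max_substep - 1e-12)))
    kin = model.kinetics
    h0 = float(gate_inf(v_init, kin["hcn"]))
    hna0 = float(gate_inf(v_init, kin["nat_h"]))
    n0 = float(gate_inf(v_init, kin["kdr"]))
    m0 = float(gate_inf(v_init, kin["nat_m"]))
    samples = stim.samples + bias if bias else stim.samples
    v, bad = _integrate(
        np.ascontiguousarray(samples, dtype=np.float64),
        stim.dt,
        n_sub,
        float(v_init),
        h0,
        hna0,
        n0,
        m0,
        _pack_params(model),
    )
    if bad >= 0:
        raise IntegrationError(
            f"voltage diverged (|V| > 150 mV) at t = {bad * stim.dt:.3f} ms "
            f"during a {stim.kind} stimulus"
        )
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=v.size)
    return TimeSeriesTrace(
        dt=stim.dt,
        voltage=v,
        current=np.asarray(samples, dtype=np.float64),
        t_on=stim.t_on,
        t_off=stim.t_off,
        v_rmp=v_init,
        meta=dict(meta or {}, stimulus=stim.kind),
    )


# --------------------------------------------------------------------------
# protocol battery
# --------------------------------------------------------------------------

_PULSE_T_ON = 200.0
_PULSE_DUR = 700.0
_PULSE_TOTAL = 1100.0
_EPSP_PEAK_PA = 30.0
_CHIRP_AMP_PA = 30.0


def vi_amplitudes() -> np.ndarray:
    """V-I protocol amplitudes: -25..+25 pA in 5 pA steps."""
    return np.arange(-25.0, 26.0, 5.0)


def vi_step_stimulus(amplitude: float, dt: float = 0.05) -> StimulusTrace:
    return make_step(amplitude, _PULSE_T_ON, _PULSE_DUR, _PULSE_TOTAL, dt)


def sag_pulse_stimulus(dt: float = 0.05) -> StimulusTrace:
    """The -100 pA hyperpolarizing pulse used for sag and single-pulse R_in."""
    return make_step(-100.0, _PULSE_T_ON, _PULSE_DUR, _PULSE_TOTAL, dt)


def alpha_train_stimulus(peak_pa: float = _EPSP_PEAK_PA, dt: float = 0.05) -> StimulusTrace:
    """Five alpha-currents (alpha = 0.1/ms) at 50 ms intervals (20 Hz)."""
    return make_alpha_train(
        i_max=peak_pa, alpha=0.1, n_events=5, interval=50.0, t_on=_PULSE_T_ON,
        total=700.0, dt=dt, normalize_peak=True,
    )


def chirp_stimulus(amplitude: float = _CHIRP_AMP_PA, dt: float = 0.05) -> StimulusTrace:
    """Chirp15 with 500 ms of silent baseline before the sweep."""
    return make_chirp(amplitude=amplitude, t_on=500.0, t_post=100.0, dt=dt)


def fi_step_stimulus(amplitude: float, dt: float = 0.05) -> StimulusTrace:
    return make_step(amplitude, _PULSE_T_ON, _PULSE_DUR, _PULSE_TOTAL, dt)


def run_protocol_suite(
    model: GranuleCellModel,
    include_voltage_dependence: bool = False,
    holding_voltages: Sequence[float] = (-85.0, -80.0, -75.0, -70.0, -65.0),
    noise_sd: float = 0.0,
    seed: int | None = None,
    meta: Mapping[str, object] | None = None,
) -> MeasurementRecord:
    """Run the full recording battery and return all 21 measurements.

    Protocols executed at the model's resting potential: the 11-step V-I
    series, the -100 pA sag pulse, the five-EPSP alpha train, Chirp15,
    and the 50-250 pA f-I series (AP features from the 250 pA response).
    The optional voltage-dependence block repeats the single-pulse R_in
    estimate and the impedance profile at five holding voltages.
    """
    v_rest = find_rest(model)
    rng = np.random.default_rng(seed)

    def sub_seed() -> int | None:
        return int(rng.integers(0, 2**31 - 1)) if noise_sd > 0 else None

    # V_RMP from a stimulus-free recording
    quiet = make_step(0.0, _PULSE_T_ON, _PULSE_DUR, _PULSE_TOTAL, 0.05)
    tr0 = simulate(model, quiet, v_init=v_rest, noise_sd=noise_sd, seed=sub_seed())
    v_rmp = measure_rmp(tr0)

    vi = [
        (a, simulate(model, vi_step_stimulus(a), v_init=v_rest, noise_sd=noise_sd, seed=sub_seed()))
        for a in vi_amplitudes()
    ]
    r_in = input_resistance(vi)

    sag_tr = simulate(model, sag_pulse_stimulus(), v_init=v_rest, noise_sd=noise_sd, seed=sub_seed())
    sag = percentage_sag(sag_tr)

    train = alpha_train_stimulus()
    s_alpha = summation_ratio(
        simulate(model, train, v_init=v_rest, noise_sd=noise_sd, seed=sub_seed())
    )

    chirp = chirp_stimulus()
    chirp_tr = simulate(model, chirp, v_init=v_rest, noise_sd=noise_sd, seed=sub_seed())
    prof = impedance_profile(chirp_tr, chirp)
    z_max, f_r, q = impedance_metrics(prof)
    phi_l = inductive_phase(prof)

    fi = [
        (a, simulate(model, fi_step_stimulus(a), v_init=v_rest, noise_sd=noise_sd, seed=sub_seed()))
        for a in FI_AMPLITUDES
    ]
    rates = firing_rate_curve(fi)
    try:
        ap = ap_features(fi[-1][1], v_rmp=v_rmp)
    except MeasurementError:
        # no spike at 250 pA (possible under strong blockade): AP features
        # are undefined, as in recordings where a cell stops firing
        nan = float("nan")
        from .suprathresh import APMeasures

        ap = APMeasures(nan, nan, nan, nan, nan, nan, nan, nan)

    r_map: dict[float, float] = {}
    z_map: dict[float, float] = {}
    if include_voltage_dependence:
        r_map, z_map = voltage_dependence(model, holding_voltages)

    return MeasurementRecord(
        v_rmp=v_rmp,
        r_in=r_in,
        sag_pct=sag,
        s_alpha=s_alpha,
        z_max=z_max,
        f_r=f_r,
        q=q,
        phi_l=phi_l,
        f_50=rates[50.0],
        f_100=rates[100.0],
        f_150=rates[150.0],
        f_200=rates[200.0],
        f_250=rates[250.0],
        v_th=ap.v_th,
        v_ap_peak=ap.v_ap_peak,
        v_ap=ap.v_ap,
        t_aphw=ap.t_aphw,
        t_1ap=ap.t_1ap,
        t_1isi=ap.t_1isi,
        dvdt_max=ap.dvdt_max,
        dvdt_min=ap.dvdt_min,
        r_in_by_voltage=r_map,
        z_max_by_voltage=z_map,
        meta=dict(meta or {}),
    )


# --------------------------------------------------------------------------
# population sampling
# --------------------------------------------------------------------------


def default_bounds() -> dict[str, tuple[float, float]]:
    """Uniform sampling ranges for the heterogeneous population."""
    return {
        "c_m": (120.0, 180.0),
        "g_leak": (3.2, 4.6),
        "g_hcn": (2.0, 4.8),
        "g_kir": (3.0, 5.2),
        "g_nap": (1.0, 1.8),
        "g_nat": (4000.0, 6500.0),
        "g_kdr": (2200.0, 3600.0),
        "e_leak": (-74.0, -70.0),
    }


def default_validity() -> dict[str, tuple[float, float]]:
    """Acceptance windows for baseline measurements of a sampled cell."""
    return {
        "rmp": (-82.0, -68.0),
        "r_in": (120.0, 240.0),
        "f_250": (8.0, 50.0),
    }


@dataclass(frozen=True)
class PopulationSpec:
    """How to draw a heterogeneous population of valid model cells."""

    n_cells: int
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=default_bounds)
    seed: int = 0
    validity: Mapping[str, tuple[float, float]] = field(default_factory=default_validity)
    max_attempts: int = 0  # 0 -> 100 * n_cells

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"bounds for {name}: low {lo} > high {hi}")


def quick_measures(model: GranuleCellModel) -> dict[str, float]:
    """Cheap validity triplet: RMP, single-pulse R_in, firing rate at 250 pA."""
    v_rest = find_rest(model)
    tr = simulate(model, sag_pulse_stimulus(), v_init=v_rest)
    from .subthresh import steady_state_deflection

    r_in = abs(steady_state_deflection(tr)) / 100.0 * 1000.0
    fi = simulate(model, fi_step_stimulus(250.0), v_init=v_rest)
    f_250 = detect_spikes(fi).size / 0.7
    return {"rmp": v_rest, "r_in": r_in, "f_250": f_250}


def sample_population(spec: PopulationSpec) -> list[GranuleCellModel]:
    """Rejection-sample `n_cells` models inside the validity windows.

    Parameters are drawn uniformly within `spec.bounds`; a candidate is
    retained iff its baseline RMP, single-pulse input resistance and
    250 pA firing rate fall inside `spec.validity`.  Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    budget = spec.max_attempts or 100 * spec.n_cells
    kept: list[GranuleCellModel] = []
    names = sorted(spec.bounds)
    for attempt in range(budget):
        draw = {nm: float(rng.uniform(*spec.bounds[nm])) for nm in names}
        model = default_model(**draw)
        try:
            qm = quick_measures(model)
        except (ProtocolError, IntegrationError):
            continue
        ok = all(lo <= qm[k] <= hi for k, (lo, hi) in spec.validity.items())
        if ok:
            kept.append(model)
            if len(kept) == spec.n_cells:
                return kept
    raise SamplingError(
        f"rejection sampling exhausted {budget} attempts with only "
        f"{len(kept)}/{spec.n_cells} valid cells "
        f"(acceptance rate {len(kept) / budget:.1%})"
    )
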