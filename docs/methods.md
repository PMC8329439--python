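# Methods

## Scope

The package measures intrinsic physiology of dentate-gyrus granule cells
from current-clamp voltage traces and emulates pharmacological
channel-blockade experiments on a synthetic cell population. Everything
operates in fixed units: mV, pA, nS, pF, ms, MΩ, Hz, V/s, rad·Hz. A
slope of 1 mV/pA equals 1 GΩ, hence the factor 1000 between fitted
slopes and reported MΩ.

## Measurement battery

Subthreshold: resting potential (mean over the 100 ms of baseline before
stimulus onset); input resistance as the least-squares slope of the
steady-state V–I relation over −25…+25 pA in 5 pA steps, with the steady
state taken as the mean over the last 100 ms of each 700 ms pulse (> 3
membrane time constants; the pulse window is a design choice, chosen to
be robust to noise); percentage sag `100·(1−V_ss/V_peak)` on the −100 pA
pulse with both deflections signed, so a passive response gives 0;
temporal summation ratio S_α = E₅/E₁ of a five-event alpha-current train
(α = 0.1 ms⁻¹, 50 ms interval), each amplitude measured as the peak
relative to the pre-train baseline — the standard convention in which
summation (later peaks riding residual depolarization) gives S_α > 1.

Impedance: Z(f) = FFT(V−V̄)/FFT(I−Ī) over the chirp window of a 0→15 Hz
in 15 s constant-amplitude sweep. The analysis band is [0.5, 15] Hz: the
chirp starts at DC so lower frequencies are ill-conditioned, and 0.5 Hz
anchors the definition of resonance strength Q = |Z|max/|Z|(0.5 Hz),
with |Z|(0.5 Hz) linearly interpolated between grid points
(nearest-FFT-bin readout is the main alternative; interpolation is
pinned here as the smoother choice). f_R ties break toward the
lowest frequency. Total inductive phase Φ_L integrates the positive part
of the phase profile by the trapezoidal rule. No smoothing by default; a
moving-average option exists.

Suprathreshold: a spike is a local maximum above 0 mV whose preceding
5 ms of upstroke crosses 20 V/s, with a 2 ms merge window (both
config-exposed detector defaults). Firing rates extrapolate the 700 ms
spike count to 1 s (n/0.7, kept exact). AP features come from the first
spike of the 250 pA response: threshold is the linearly interpolated
voltage at the first upward 20 V/s crossing before the peak; half-width
is measured at V_RMP + V_AP/2 with linear interpolation on both flanks;
dV/dt is a centered difference of mV against ms, numerically equal to
V/s. T_1ISI is reported as NaN ("undefined") with fewer than two spikes,
and all AP features are NaN when a cell fires no spike at 250 pA — both
situations occur in real recordings under NaP blockade and are flagged,
not fatal.

## The synthetic granule cell

One somatic compartment with leak, HCN, Kir, NaP, NaT and KDR
conductances; Boltzmann steady states, first-order gate kinetics,
exponential-Euler integration at an effective step ≤ 0.025 ms (the
500 ms HCN time constant alongside sub-ms spike dynamics makes the
system stiff; exponential Euler is unconditionally stable for the
voltage update). The inner loop is numba-compiled; integration is
deterministic, with optional seeded Gaussian recording noise added to
the recorded trace only.

Default parameters (all config-overridable):

| parameter | value | rationale |
|---|---|---|
| C_m | 150 pF | with R_in ≈ 170 MΩ gives τ_m ≈ 26 ms, needed for S_α ≈ 1.35 at 20 Hz |
| g_leak, E_L | 3.8 nS, −71.9 mV | pins RMP at −75 mV with the gated channels' resting currents |
| ḡ_h, V½, k, τ, E_h | 3.43 nS, −75 mV, +18 mV, 500 ms, −68 mV | see below |
| ḡ_Kir, V½, k, E_K | 4.0 nS, −90 mV, +18 mV, −95 mV | instantaneous inward rectifier; conductance grows with hyperpolarization |
| ḡ_NaP, V½, k | 1.4 nS, −46 mV, −5 mV | instantaneous; amplifies depolarization near threshold |
| ḡ_NaT (m³h), ḡ_KDR (n⁴) | 5000 nS, 2800 nS | spiking pair; τ_m = 0.1 ms keeps dV/dt grid-converged |

**The HCN reversal potential is an effective parameter.** Biophysically
HCN channels reverse near −30 mV; here E_h = −68 mV, just below rest,
with a shallow activation curve centred at rest. In a single compartment
with τ_h = 500 ms this is what reproduces the empirical
conductance-current balance of granule cells: blockade removes a small
inward current at rest (≈ −12 pA, hyperpolarizing the RMP by ~3 mV)
while removing a substantial standing conductance (≈ 1.7 nS), so input
resistance, summation, impedance and firing all *increase*. With a
far-depolarized reversal the resting-current term dominates at any
conductance that matters and blockade would always reduce firing — the
opposite of what granule cells do. The compression of dendritic and
axonal channel distributions into one compartment is absorbed into this
single effective number.

Sag is small (≈ 5–8%) and resonance absent (Q < 1.03, Φ_L = 0, f_R at
the band edge) because the HCN gate is simply too slow to express within
a 700 ms pulse or against a 0.5–15 Hz sweep — the same mechanism the
slow-kinetics account offers for real granule cells.

Known limitations: the AP half-width (~1.7 ms) is roughly double the in
vitro value — the price of the large C_m needed for a realistic membrane
time constant in one compartment; first-spike latency is accordingly at
the short end. Spike counts are quantized at 1/0.7 Hz ≈ 1.4 Hz, so
single-cell firing-rate changes near one spike per pulse flicker between
0 and 1.4 Hz; population medians smooth this out. Calcium dynamics,
morphology, axonal NaP localization and two-pore potassium channels are
out of scope.

## Blockade emulation and populations

Each pharmacological agent at its working concentration is treated as a
complete block of its target (fraction 1.0), implemented as
multiplicative scaling of the maximal conductance; partial fractions
compose multiplicatively. The tertiapin-Q-sensitive target maps to no
conductance in the default model, making it the built-in negative
control: its "blockade" changes nothing, as in the experiments it
emulates.

Populations are drawn by rejection sampling: conductances, capacitance
and leak reversal uniform within bounds spanning roughly ±30% around the
defaults (ḡ_h spans 2.4×, wide enough that disparate HCN densities can
produce near-identical input resistance — degeneracy by construction),
retaining cells whose baseline RMP ∈ [−82, −68] mV, single-pulse R_in ∈
[120, 240] MΩ and 250 pA firing rate ∈ [8, 50] Hz. This is a simplified
stand-in for a full multi-objective stochastic model search; it
reproduces the aspects that matter here (validity windows plus
parametric heterogeneity), not the full search machinery.

What passing tests show — and what they do not: the synthetic population
reproduces the *sign structure and heterogeneity* of channel-blockade
experiments and the formula-level definitions of all 21 measurements.
It does not reproduce, and is not tuned to, the quantitative effect
sizes of any particular recorded data set; real recordings add noise
sources (electrode drift, series resistance, temperature) that the
generator models only as optional additive Gaussian voltage noise.

## Statistics

Percentage change is `100·(after−before)/before` on raw signed values —
for negative baselines such as RMP this yields the reporting convention
in which hyperpolarization is a positive change. A zero
baseline flags the change undefined (NaN) rather than dropping the cell.
Heterogeneity is quantified by the sample SD (n−1), the IQR under the
linear-interpolation quantile convention (pinned; other conventions
differ at these n), and CV = SD/mean (flagged when the mean is ≈ 0).

`compare_conditions` dispatches on design × family: Wilcoxon signed-rank
(exact null for n ≤ 25 after dropping zero differences, tie-corrected
normal approximation otherwise), Wilcoxon rank-sum, paired/unpaired t;
Kruskal–Wallis covers k groups. All tests are two-sided (sidedness was
an open choice; two-sided is the conservative default). No
multiple-testing correction is applied by default, matching the
single-comparison reporting style the tables emulate; a
Benjamini–Hochberg flag is available.

The mapping matrix assigns each (channel, measurement) entry the sign of
the median percentage change when the paired test rejects at α = 0.05
*and* the median effect clears a 1% floor — the floor prevents calling
sub-percent systematic shifts at large n. Entries with fewer than 5
usable pairs, or with degenerate (all-zero-difference) comparisons, are
flagged and reported as 0 rather than dropped.

## Problem sizes

The shipped study uses 20 cells × 5 conditions × the full battery
(18 protocol sweeps per record, ≈ 35 s of simulated time each at 20 kHz
sampling and 0.025 ms integration), which runs in well under a minute.
The sequential-blockade analysis compares baseline → Kir block → Kir+HCN
block per cell, with firing compared as the mean rate over the whole
50–250 pA battery (single-amplitude counts are spike-quantized and can
stall at one stage even when every amplitude trends upward).
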