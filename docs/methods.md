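# Methods

This note documents the models behind `puffquant`: what the synthetic
generator simulates, how its defaults were calibrated, what each
measurement and statistical operator assumes, and where the package's
design had to make choices the underlying experiment does not dictate.

## Receptor current model

A puff response in voltage clamp is modelled as a sum of per-receptor
difference-of-exponentials components. Component *c* contributes

    I_c(t) = A_c · [exp(−t/τd_c) − exp(−t/τr_c)] / w_c ,   t ≥ onset,

peak-normalised by `w_c` so `A_c` is the literal component peak in pA
(negative = inward at −60 mV). Closed forms used throughout (and as
test oracles):

* peak time `t* = ln(τd/τr)·τd·τr/(τd−τr)`;
* area `A·(τd−τr)/w` (pA·ms), with the truncated-window variant used
  for charge-conservation checks.

Two components are simulated:

| component | τ_rise (ms) | τ_decay (ms) | role |
|---|---|---|---|
| α3β4\* | 134.013 | 351.404 | dominant slow current, 92.6% of charge |
| α7 | 5 | 120 | small fast current, 7.4% of charge |

The α3β4\* time constants are **solved numerically**
(`kinetics.calibrate_kinetics`, a 2-D root find) so that the summed
template, measured by the pipeline's own operators at 50 kHz over a 2 s
window, returns a 10–90% rise time of 89 ms and a fitted
single-exponential decay of 438 ms; the amplitudes are then scaled so
the summed peak is −329 pA and the α7 charge share 0.074. Note the
fitted τ (438 ms) exceeds the α3β4\* τ_decay (351 ms) because the slow
rise term is still relaxing during the fit window — a single
exponential is a deliberate simplification of a two-component decay,
matching how such decays are routinely summarised.

The α7 kinetics are nominal. A faster α7 (τ_decay tens of ms) cannot
carry 7.4% of the charge without its peak rivalling the slow
component's, which would make the summed template double-peaked; the
chosen 5/120 ms keeps the residual current after full α3β4\* block
about one third of the control peak and clearly faster than control.

**Dose–response.** Puff concentration scales all amplitudes through a
Hill function (EC50 140 µM, coefficient 1.2, normalised to 1 at
1 mM). No dose–response data constrain this placeholder; only the
relative ordering matters (30 µM subthreshold, 1 mM strongly
suprathreshold), and it is exposed in `kinetics`.

**Pharmacology.** Scenarios are per-component blocked fractions:
mecamylamine and SR16584 block α3β4\* fully; MLA blocks α7 fully;
atropine, DHβE, fast-synaptic blockers and low Ca²⁺ block nothing.
This is the qualitative pattern of the experiments the package
emulates; graded block is supported but not used by default.

## Current-clamp model

The membrane is a single compartment: resting potential −65 mV, input
resistance 150 MΩ, capacitance 100 pF (τ_m = 15 ms). The subthreshold
envelope is the first-order low-pass of `V_rest − I(t)·R_in`, so an
inward (negative) current depolarises with unit DC gain and the
envelope area equals the drive area.

Spikes are timed by an **integrate-and-fire pacing state** that obeys
the same membrane equation but resets to −55 mV after crossing the
−40 mV threshold and holds through a 2 ms refractory period. The
emitted trace is the *smooth envelope* with a stereotyped 2 ms
triangular action potential (peak 80 mV above threshold) spliced at
each spike time; the pacing state itself, and the true spike times, are
returned for oracle tests. Splicing spikes onto the envelope (rather
than emitting the resetting sawtooth) keeps the median-filterable
envelope explicit — which is the property the analysis pipeline
depends on — while the reset dynamics produce realistic interspike
intervals and spike counts (≈40 spikes for the default 1 mM response,
decaying over ~1 s).

Two consequences worth knowing:

* the envelope is **linear in the current**: strong train stimuli can
  drive it to unphysiological voltages (no conductance saturation or
  Na⁺ inactivation). Absolute areas of strong trains are therefore
  larger than a real neuron's; normalized summation measures are
  unaffected, which is why the train analysis normalizes per cell;
* the default spike-detection threshold is −10 mV: the default
  envelope peaks near −16 mV, so a threshold in the classic −20 mV
  range would sit *below* the envelope and saturate. The threshold is
  a parameter everywhere it appears.

## Quantification pipeline

* **Spike detection**: upward threshold crossings; crossings within
  the refractory window (default 1 ms) of the previous accepted spike
  are ignored.
* **Median filter**: window `round(80 ms · rate)` samples forced odd
  (3999 at 50 kHz — one sample narrower than the nominal 4000 so the
  window is symmetric), reflection padding, length preserved. Runs on
  a skip-list rolling median (O(n log w)).
* **Baseline**: mean over a 100 ms window ending 5 ms before puff
  onset. The experiment this emulates does not state a baseline rule;
  this one is declared, not inferred.
* **Area / peak**: trapezoidal integral and signed extremum of
  (signal − baseline) from onset over the response window (default
  2 s; train analyses extend the window to the end of the sweep, which
  always includes ≥2.5 s beyond the last puff so <0.1% of the charge
  is truncated). Voltage-clamp areas are reported as magnitudes with a
  sign flag.
* **Rise time**: first crossings of 10% and 90% of peak, linearly
  interpolated between samples.
* **Decay fit**: nonlinear least squares of `A·exp(−t/τ)` from the
  peak sample to the end of the window, log-linear initialisation,
  τ bounded to (1 ms, 10 s); non-convergence is reported with
  diagnostics (`success=False`), never silently defaulted.
* **Condition averages**: arithmetic mean of spike count and area over
  the (nominally five) puffs of one cell × condition block.

## Statistics

**Estimation.** The resampling unit is the cell's paired difference
(responses are first averaged over puffs within cell × condition).
BCa intervals use 10,000 resamples; z₀ counts ties at half weight;
acceleration is the jackknife skewness; densities for plotting use a
normal kernel with Silverman bandwidth. With all differences equal the
interval degenerates to a point and is flagged.

A calibration caveat the test suite measures explicitly: at n = 7
cells, the 95% BCa interval covers a true Normal mean-difference in
only ≈88% of simulations — reproduced exactly by
`scipy.stats.bootstrap(method="BCa")` on the same data, while the
Student-t interval covers ≈97%. This is the estimator's known
small-sample behaviour, not an implementation artefact; the package
reports it rather than papering over it.

**Permutation test** (2 conditions): within-cell label swaps are sign
flips of the paired differences; statistic = mean difference, which is
monotone-equivalent under within-block permutation to the pooled
Pearson-correlation statistic (verified by exhaustive enumeration in
the tests), so the two formulations give identical p-values. p uses
the add-one estimator, two-sided; Z standardizes the observed
statistic against the Monte-Carlo null.

**Repeated measures** (k ≥ 3 conditions): balanced complete data only
— the random-intercept REML solution is then the closed-form two-way
decomposition, F on (k−1, (k−1)(n−1)) df, contrasts on (k−1)(n−1) df
(equal to the Satterthwaite df in this balanced case; cross-checked
against `statsmodels` MixedLM). Unbalanced data are rejected with an
explicit message rather than approximated. Contrast p-values are
unadjusted, matching the reporting convention the package emulates.

## Train summation and profile calibration

The k-th puff of a train is scaled by `d + (1−d)·r^(k−1)` (first puff
always 1), so cumulative noiseless envelope area after K puffs is
`N(K) = d·K + (1−d)(1−r^K)/(1−r)` in 1-puff units. `d` is the
asymptotic per-puff gain (facilitation > 1, depression < 1), `r` the
relaxation rate. Whether real supralinearity is spike- or
conductance-driven is not resolved by the data this emulates; the law
is agnostic — it prescribes areas, not mechanisms.

`calibrate_summation_profiles` solves (d, r) from target line-fit
slopes (and optionally the 10-puff ratio) either against the closed
form or through the **full noiseless pipeline** (simulate → median
filter → area → normalize → line fit). The shipped defaults are
pipeline-calibrated, which matters because dense spiking during strong
trains biases the median-filtered area by a few percent; pipeline
calibration absorbs that bias:

| condition | d | r | measured slope | measured 10:1 ratio |
|---|---|---|---|---|
| 30 µM, 10 Hz | 1.4227 | 0.5 | 1.400 | 13.5 |
| 100 µM, 10 Hz | 3.9664 | 0.5 | 4.000 | 36.3 |
| 30 µM, 30 Hz | 0.3477 | 0.02 | 0.349 | 4.15 |

Slope-only targets leave `r` unidentified; `r = 0.5` is fixed by
convention. For the 30 Hz condition the target pair (slope 0.38 *and*
ratio 3.8) is **jointly infeasible** for any single mean neuron under
per-cell normalization: N(1) = 1 and N(10) = 3.8 bound the OLS slope
over counts {1, 2, 3, 5, 10} to ≤ ~0.364 for every monotone summation
curve, and to ≤ ~0.311 within this profile family. (Heterogeneous
cells can print both numbers because the fitted slope and the ratio
aggregate differently across cells.) The default is the equal-weight
least-squares compromise over both targets' relative errors, and the
calibrator reports the target set as infeasible instead of clipping.

## Population model

Positive parameters vary lognormally (peak magnitude 329 ± 154 pA; a
joint kinetic time-scale factor with CV 173/438 applied to both α3β4\*
time constants so rise and fitted decay co-vary; α7 charge share
0.074 ± 0.062 clipped to [0, 1]), the resting potential normally
(−65 ± 2 mV); all draws truncated at 3 SD. A neuron responds at all
with probability 116/126; non-responders get zero receptor amplitude.
Membrane R and C are fixed across the population — they are not
anchored by any measurement here, and varying them would mostly
re-scale the (already lognormal) drive.

## What the generator does and does not emulate

Emulated: the kinetic shape and pharmacological decomposition of the
puff response; spike trains riding a slow depolarisation, with exact
ground truth; per-condition five-puff blocks; train summation with a
controllable gain law; across-cell variability and non-responders;
additive Gaussian recording noise and optional linear drift.

Not emulated: receptor-state kinetics (desensitisation, rebound),
dendritic filtering, conductance saturation of the envelope, pink/1-f
noise, seal or access-resistance artefacts, puff fluid dynamics.
Passing tests therefore show that the *measurement and statistical
operators* are correct against controlled ground truth — not that the
generator is a biophysical model of the neurons.

## Numerical choices

* Sampling: 50 kHz default (matching the emulated recordings); the
  current-clamp generator refuses rates under 10/τ_m.
* Integration: trapezoid; envelope filtering by exact zero-order-hold
  discretisation of the first-order ODE (`scipy.signal.lfilter`).
* Decay-fit tolerance: scipy `curve_fit` defaults, τ ∈ (1 ms, 10 s).
* Quantile convention for bootstrap endpoints: linear interpolation
  (`numpy.quantile` default), ties in z₀ half-weighted.
* Degenerate inputs: flagged (degenerate BCa interval), rejected
  (incomplete paired data, <3 line-fit points, windows outside the
  trace), or defined (p = 1 for all-zero differences).
* All randomness flows from explicit integer seeds;
  `numpy.random.SeedSequence` derives per-stage seeds in the pipeline.

## Problem sizes used by the test suite

Deterministic round trips run at the native 50 kHz. Statistical
calibration suites use 1000 simulated null datasets (permutation
uniformity, F-test type-I error) and 500 datasets of n = 7 for BCa
coverage, with 2000-iteration Monte-Carlo nulls and 10,000-resample
bootstraps; the spike-count oracle battery covers 50 sweeps across
five scenarios × ten seeds at 25 kHz. These sizes give Monte-Carlo
standard errors comfortably inside the asserted bands while keeping
the default `pytest` run to a few minutes.
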