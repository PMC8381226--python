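"""Per-trace measurements for puff-evoked responses.

The measurement chain mirrors common practice for slow agonist-evoked
responses in whole-cell recordings:

1. count action potentials with a threshold-crossing rule
   (:func:`detect_spikes`);
2. remove the action potentials with a running-median filter whose
   window (80 ms, 4000 samples at 50 kHz, forced odd to 3999) is long
   relative to a spike but short relative to the slow envelope
   (:func:`median_filter_envelope`);
3. measure the baseline-subtracted envelope: area under the curve,
   signed peak, 10-90% rise time and a single-exponential decay fit
   (:func:`response_area`, :func:`peak_amplitude`,
   :func:`rise_time_10_90`, :func:`fit_exponential_decay`);
4. average the five per-puff measurements of each cell x condition
   block (:func:`average_condition`).

Areas are reported in mV*ms (current clamp) or pA*ms (voltage clamp);
for voltage-clamp sweeps the inward current integrates to a negative
number, and the per-puff record stores its magnitude together with an
explicit sign field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trace import CURRENT_CLAMP, VOLTAGE_CLAMP, Trace

__all__ = [
    "SpikeTrain",
    "DecayFit",
    "PuffResponseMeasurement",
    "ConditionSummary",
    "detect_spikes",
    "median_filter_envelope",
    "estimate_baseline",
    "response_area",
    "peak_amplitude",
    "rise_time_10_90",
    "fit_exponential_decay",
    "average_condition",
    "quantify_sweep",
    "QuantifyParams",
]

DEFAULT_SPIKE_THRESHOLD_MV = -20.0
DEFAULT_REFRACTORY_MS = 1.0
DEFAULT_MEDIAN_WINDOW_MS = 80.0
DEFAULT_RESPONSE_WINDOW_S = 2.0
DEFAULT_BASELINE_WINDOW_S = 0.1
DEFAULT_BASELINE_GAP_S = 0.005


@dataclass(frozen=True)
class SpikeTrain:
    """Detected action potentials: ascending times in seconds."""

    spike_times: np.ndarray

    @property
    def count(self) -> int:
        return int(np.asarray(self.spike_times).size)


@dataclass(frozen=True)
class DecayFit:
    """Result of a single-exponential fit to the decay phase.

    ``tau_ms`` is the decay time constant; ``amplitude`` the fitted
    value at the fit start (baseline-subtracted); ``rms`` the residual
    root mean square.  ``success`` is False when the optimiser failed to
    converge, in which case ``message`` carries the diagnostics and
    ``tau_ms`` is NaN — never a silently substituted default.
    """

    tau_ms: float
    amplitude: float
    rms: float
    n_points: int
    t_start: float
    success: bool = True
    message: str = ""


@dataclass
class PuffResponseMeasurement:
    """Quantification of one puff response within a sweep."""

    cell_id: str
    condition: str
    puff_index: int
    spike_count: int
    area: float  # mV*ms (CC, signed) or pA*ms magnitude (VC)
    area_sign: int  # +1 depolarisation / -1 inward current
    peak: float  # signed, relative to baseline
    rise_10_90: float  # ms, NaN when no clear peak
    decay_tau: float  # ms, NaN when the fit failed
    baseline: float  # mV or pA


@dataclass
class ConditionSummary:
    """Per cell x condition average over the puffs of one block."""

    cell_id: str
    condition: str
    mean_spike_count: float
    mean_area: float
    n_puffs: int


def detect_spikes(
    trace: Trace,
    threshold: float = DEFAULT_SPIKE_THRESHOLD_MV,
    refractory_ms: float = DEFAULT_REFRACTORY_MS,
) -> SpikeTrain:
    """Count action potentials by upward threshold crossings.

    A spike is recorded at each sample where the voltage first reaches
    ``threshold`` from below; crossings within ``refractory_ms`` of the
    previous accepted spike are ignored.
    """
    if trace.mode != CURRENT_CLAMP:
        raise ValueError("spike detection requires a current-clamp trace")
    v = trace.samples
    above = v >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above[0]:
        crossings = np.concatenate([[0], crossings])
    refractory_s = refractory_ms / 1000.0
    times: list[float] = []
    t = trace.start_time
    last = -np.inf
    for idx in crossings:
        ts = t + idx / trace.rate
        if ts - last >= refractory_s:
            times.append(ts)
            last = ts
    return SpikeTrain(spike_times=np.asarray(times))


def median_filter_envelope(
    trace: Trace, window_ms: float = DEFAULT_MEDIAN_WINDOW_MS
) -> Trace:
    """Running-median filter that removes spikes, keeps the slow envelope.

    The window is ``round(window_ms * rate)`` samples forced odd (3999 at
    50 kHz for the default 80 ms) so the window is symmetric about each
    sample; edges are handled by reflection padding and the output has
    the same length as the input.
    """
    n = trace.n_samples
    w = int(round(window_ms / 1000.0 * trace.rate))
    if w % 2 == 0:
        w -= 1
    if w < 1:
        raise ValueError("median window shorter than one sample")
    if w >= n:
        raise ValueError(
            f"median window ({w} samples) must be shorter than the trace ({n})"
        )
    h = w // 2
    padded = np.concatenate(
        [trace.samples[h:0:-1], trace.samples, trace.samples[-2 : -h - 2 : -1]]
    )
    filt = (
        pd.Series(padded)
        .rolling(window=w, center=True, min_periods=w)
        .median()
        .to_numpy()[h : h + n]
    )
    return trace.with_samples(filt, median_window_samples=w)


def estimate_baseline(
    trace: Trace,
    onset: float,
    window_s: float = DEFAULT_BASELINE_WINDOW_S,
    gap_s: float = DEFAULT_BASELINE_GAP_S,
) -> float:
    """Mean level over a pre-stimulus window.

    The window spans ``[onset - gap_s - window_s, onset - gap_s]``; it
    must lie entirely inside the trace and precede the first puff.
    """
    t0 = onset - gap_s - window_s
    t1 = onset - gap_s
    if t0 < trace.start_time - 0.5 / trace.rate or t1 > trace.start_time + trace.duration:
        raise ValueError("baseline window falls outside the trace")
    i0, i1 = trace.index_at(t0), trace.index_at(t1)
    if i1 <= i0:
        raise ValueError("baseline window contains no samples")
    return float(np.mean(trace.samples[i0:i1]))


def _window_slice(trace: Trace, onset: float, window_s: float) -> slice:
    if window_s <= 0:
        raise ValueError("window must be positive")
    i0 = trace.index_at(onset)
    end = onset + window_s
    if end > trace.start_time + trace.duration + 0.5 / trace.rate:
        raise ValueError("analysis window extends past the end of the trace")
    i1 = min(trace.index_at(end) + 1, trace.n_samples)
    return slice(i0, i1)


def response_area(
    filtered: Trace, baseline: float, onset: float, window_s: float
) -> float:
    """Trapezoidal integral of (signal - baseline) over the response window.

    Returned in units*ms (mV*ms or pA*ms), signed: depolarisations give
    positive areas, inward currents negative ones.
    """
    sl = _window_slice(filtered, onset, window_s)
    y = filtered.samples[sl] - baseline
    return float(np.trapezoid(y, dx=filtered.dt) * 1000.0)


def peak_amplitude(
    filtered: Trace, baseline: float, onset: float, window_s: float
) -> float:
    """Signed extremum of (signal - baseline) within the response window."""
    sl = _window_slice(filtered, onset, window_s)
    y = filtered.samples[sl] - baseline
    return float(y[np.argmax(np.abs(y))])


def _peak_index(filtered: Trace, baseline: float, sl: slice) -> int:
    y = filtered.samples[sl] - baseline
    return sl.start + int(np.argmax(np.abs(y)))


def rise_time_10_90(
    filtered: Trace,
    baseline: float,
    onset: float,
    window_s: float = DEFAULT_RESPONSE_WINDOW_S,
    noise_sd: float = 0.0,
) -> float:
    """10-90% rise time of the response in ms.

    Measured between the first crossings of 10% and 90% of the peak
    (relative to baseline) after onset, with linear interpolation
    between samples.  When ``noise_sd`` is given, a peak smaller than
    three times the baseline noise is rejected.
    """
    sl = _window_slice(filtered, onset, window_s)
    y = filtered.samples[sl] - baseline
    ipk = int(np.argmax(np.abs(y)))
    peak = y[ipk]
    if noise_sd > 0 and abs(peak) < 3.0 * noise_sd:
        raise ValueError("no identifiable peak above the noise floor")
    # work on the magnitude so inward currents and depolarisations share code
    m = y[: ipk + 1] * np.sign(peak)
    t10 = _first_crossing(m, 0.1 * abs(peak))
    t90 = _first_crossing(m, 0.9 * abs(peak))
    return float((t90 - t10) / filtered.rate * 1000.0)


def _first_crossing(m: np.ndarray, level: float) -> float:
    """Fractional sample index of the first upward crossing of ``level``."""
    idx = np.flatnonzero(m >= level)
    if idx.size == 0:
        raise ValueError("signal never reaches the requested level")
    i = int(idx[0])
    if i == 0:
        return 0.0
    y0, y1 = m[i - 1], m[i]
    return i - 1 + (level - y0) / (y1 - y0)


def fit_exponential_decay(
    filtered: Trace,
    baseline: float,
    onset: float = 0.0,
    window_s: float = DEFAULT_RESPONSE_WINDOW_S,
    from_time: float | None = None,
    min_points: int = 100,
) -> DecayFit:
    """Least-squares single-exponential fit to the decay phase.

    Fits ``A * exp(-(t - t_peak)/tau)`` to (signal - baseline) from the
    response peak (or ``from_time``) to the end of the response window.
    The fit is initialised from a log-linear regression and bounded to
    tau in (1 ms, 10 s).  On optimiser failure the returned
    :class:`DecayFit` has ``success=False`` and NaN tau with the
    diagnostics in ``message``.
    """
    from scipy.optimize import curve_fit

    sl = _window_slice(filtered, onset, window_s)
    if from_time is None:
        ipk = _peak_index(filtered, baseline, sl)
    else:
        ipk = filtered.index_at(from_time)
    y = filtered.samples[ipk : sl.stop] - baseline
    if y.size < min_points:
        raise ValueError(
            f"decay fit needs at least {min_points} samples after the peak, "
            f"got {y.size}"
        )
    sign = np.sign(y[0]) if y[0] != 0 else 1.0
    m = y * sign
    t_ms = np.arange(y.size) / filtered.rate * 1000.0

    # log-linear initialisation on the positive part of the decay
    pos = m > max(1e-12, 1e-6 * m.max())
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t_ms[pos], np.log(m[pos]), 1)
        tau0 = -1.0 / slope if slope < 0 else 100.0
        a0 = float(np.exp(intercept))
    else:
        tau0, a0 = 100.0, float(m[0])
    tau0 = float(np.clip(tau0, 1.1, 9999.0))

    def model(t: np.ndarray, a: float, tau: float) -> np.ndarray:
        return a * np.exp(-t / tau)

    t_start = filtered.start_time + ipk / filtered.rate
    try:
        popt, _ = curve_fit(
            model,
            t_ms,
            m,
            p0=[max(a0, 1e-9), tau0],
            bounds=([0.0, 1.0], [np.inf, 10_000.0]),
            maxfev=10_000,
        )
    except RuntimeError as err:  # pragma: no cover - pathological inputs
        return DecayFit(
            tau_ms=float("nan"),
            amplitude=float("nan"),
            rms=float("nan"),
            n_points=int(y.size),
            t_start=t_start,
            success=False,
            message=f"decay fit did not converge: {err}",
        )
    resid = m - model(t_ms, *popt)
    return DecayFit(
        tau_ms=float(popt[1]),
        amplitude=float(sign * popt[0]),
        rms=float(np.sqrt(np.mean(resid**2))),
        n_points=int(y.size),
        t_start=t_start,
    )


def average_condition(
    measurements: list[PuffResponseMeasurement],
) -> ConditionSummary:
    """Average the per-puff measurements of one cell x condition block."""
    if not measurements:
        raise ValueError("no measurements to average")
    cells = {m.cell_id for m in measurements}
    conds = {m.condition for m in measurements}
    if len(cells) != 1 or len(conds) != 1:
        raise ValueError(
            f"measurements mix cells {sorted(cells)} / conditions {sorted(conds)}"
        )
    return ConditionSummary(
        cell_id=measurements[0].cell_id,
        condition=measurements[0].condition,
        mean_spike_count=float(np.mean([m.spike_count for m in measurements])),
        mean_area=float(np.mean([m.area for m in measurements])),
        n_puffs=len(measurements),
    )


@dataclass
class QuantifyParams:
    """Tunable measurement parameters with their field-standard defaults."""

    spike_threshold: float = DEFAULT_SPIKE_THRESHOLD_MV
    refractory_ms: float = DEFAULT_REFRACTORY_MS
    median_window_ms: float = DEFAULT_MEDIAN_WINDOW_MS
    response_window_s: float = DEFAULT_RESPONSE_WINDOW_S
    baseline_window_s: float = DEFAULT_BASELINE_WINDOW_S
    baseline_gap_s: float = DEFAULT_BASELINE_GAP_S
    extra: dict = field(default_factory=dict)


def quantify_sweep(
    trace: Trace,
    onset: float,
    puff_index: int = 1,
    params: QuantifyParams | None = None,
    response_window_s: float | None = None,
) -> PuffResponseMeasurement:
    """Full measurement chain for one puff response in one sweep.

    Current-clamp sweeps are spike-counted first, then median filtered;
    voltage-clamp sweeps are median filtered only.  The area of a
    voltage-clamp response is stored as a magnitude with ``area_sign=-1``.
    """
    p = params or QuantifyParams()
    win = response_window_s if response_window_s is not None else p.response_window_s
    if trace.mode == CURRENT_CLAMP:
        spikes = detect_spikes(trace, p.spike_threshold, p.refractory_ms).count
    else:
        spikes = 0
    filtered = median_filter_envelope(trace, p.median_window_ms)
    baseline = estimate_baseline(filtered, onset, p.baseline_window_s, p.baseline_gap_s)
    area = response_area(filtered, baseline, onset, win)
    peak = peak_amplitude(filtered, baseline, onset, win)
    try:
        rise = rise_time_10_90(filtered, baseline, onset, win)
    except ValueError:
        rise = float("nan")
    try:
        fit = fit_exponential_decay(filtered, baseline, onset, win)
        tau = fit.tau_ms if fit.success else float("nan")
    except ValueError:
        tau = float("nan")
    sign = -1 if trace.mode == VOLTAGE_CLAMP and area < 0 else 1
    return PuffResponseMeasurement(
        cell_id=str(trace.meta.get("cell_id", "cell0")),
        condition=str(trace.meta.get("condition", "control")),
        puff_index=puff_index,
        spike_count=spikes,
        area=abs(area) if sign < 0 else area,
        area_sign=sign,
        peak=peak,
        rise_10_90=rise,
        decay_tau=tau,
        baseline=baseline,
    )
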