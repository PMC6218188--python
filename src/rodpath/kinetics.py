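"""Kinetics analyses: flash-kernel → sinusoid prediction, temporal-shift
estimation, integration time, zero-crossing time and membrane-τ fits.

The central assumption is linearity: responses to sinusoidal stimuli
are the steady-state output of the linear system whose impulse response
is the measured flash response, so amplitude and phase at a frequency
f equal the kernel's frequency response at f.  Temporal shifts between
responses are estimated by cross-correlation with parabolic sub-sample
interpolation; a phase-based estimate at the stimulus frequency is the
built-in cross-check.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError
from .adaptation import HillFit, fit_hill
from .traces import Trace, TraceStore

__all__ = [
    "ShiftCurve",
    "predict_sinusoid_response",
    "temporal_shift",
    "phase_shift",
    "shift_curve",
    "integration_time",
    "integration_time_ratio",
    "zero_crossing_time",
    "fit_membrane_tau",
]


@dataclasses.dataclass
class ShiftCurve:
    """Temporal shifts (ms, relative to the lowest background) vs background."""

    backgrounds: np.ndarray
    shifts_ms: np.ndarray
    source: str
    hill: HillFit | None = None

    def __post_init__(self) -> None:
        self.backgrounds = np.asarray(self.backgrounds, float)
        self.shifts_ms = np.asarray(self.shifts_ms, float)
        if not np.all(np.isfinite(self.shifts_ms)):
            raise ValueError("shifts must be finite")

    @property
    def total_shift_ms(self) -> float:
        return float(self.shifts_ms[-1] - self.shifts_ms[0])


# ---------------------------------------------------------------------------
# sinusoid prediction from flash kernels
# ---------------------------------------------------------------------------

def kernel_frequency_response(kernel: Trace, frequency: float) -> complex:
    """Frequency response H(f) = ∫ h(t)·exp(−i 2π f t) dt of a flash kernel."""
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    if frequency >= 0.5 / kernel.dt:
        raise ValueError(
            f"frequency {frequency} Hz is at or above Nyquist for dt={kernel.dt}")
    t = kernel.time
    h = kernel.values
    return complex(np.sum(h * np.exp(-2j * math.pi * frequency * t)) * kernel.dt)


def predict_sinusoid_response(flash_kernel: Trace, frequency: float,
                              n_periods: int = 8) -> tuple[float, float, Trace]:
    """Steady-state sinusoid response predicted from a flash kernel.

    Treats the (baseline-subtracted) flash response as the impulse
    response of a linear system: for input sin(2πft) the steady-state
    output is ``A·sin(2πft + φ)`` with ``A = |H(f)|`` and ``φ = arg H(f)``.
    Returns ``(amplitude, phase, predicted trace)`` over ``n_periods``.

    The kernel must span at least one stimulus period.
    """
    T = 1.0 / frequency
    if kernel_duration(flash_kernel) < T:
        raise ValueError("kernel duration must cover at least one stimulus period")
    H = kernel_frequency_response(flash_kernel, frequency)
    amp, phase = abs(H), math.atan2(H.imag, H.real)
    dt = flash_kernel.dt
    t = np.arange(0.0, n_periods * T, dt)
    pred = Trace(t0=0.0, dt=dt,
                 values=amp * np.sin(2 * math.pi * frequency * t + phase),
                 units=flash_kernel.units, stimulus=flash_kernel.stimulus,
                 meta={**flash_kernel.meta, "predicted_frequency_hz": frequency})
    return amp, phase, pred


def kernel_duration(kernel: Trace) -> float:
    return kernel.dt * len(kernel.values)


def phase_delay_ms(flash_kernel: Trace, frequency: float) -> float:
    """Group-delay-style delay −φ/(2πf) of the kernel at ``frequency``, in ms."""
    H = kernel_frequency_response(flash_kernel, frequency)
    phase = math.atan2(H.imag, H.real)
    # kernels here are causal low-pass cascades: unwrap into a positive delay
    while phase > 0:
        phase -= 2 * math.pi
    return -phase / (2 * math.pi * frequency) * 1000.0


# ---------------------------------------------------------------------------
# temporal shift
# ---------------------------------------------------------------------------

def temporal_shift(trace_a: Trace, trace_b: Trace,
                   frequency: float | None = None) -> float:
    """Delay of ``trace_a`` relative to ``trace_b`` in ms (positive = A lags B).

    The lag of the cross-correlation maximum, refined by parabolic
    interpolation between the bracketing samples; correlations are
    normalized by overlap length so finite windows do not bias the
    peak.  For periodic (sinusoidal) inputs pass ``frequency`` — the
    result is then reported modulo one period with the
    smallest-magnitude representative.
    """
    if not math.isclose(trace_a.dt, trace_b.dt, rel_tol=1e-9):
        raise ValueError("traces must share the same sample interval")
    a = trace_a.values - trace_a.values.mean()
    b = trace_b.values - trace_b.values.mean()
    if not (np.any(a) and np.any(b)):
        raise ValueError("temporal shift is undefined for an all-constant trace")
    n = min(len(a), len(b))
    a, b = a[:n], b[:n]

    if frequency is not None:
        # periodic input: circular cross-correlation over an integer number
        # of periods is free of windowing bias
        P = int(round(1.0 / (frequency * trace_a.dt)))
        m = (n // P) * P
        if m == 0:
            raise ValueError("traces must span at least one stimulus period")
        a, b = a[:m] - a[:m].mean(), b[:m] - b[:m].mean()
        c = np.fft.irfft(np.fft.rfft(a) * np.conj(np.fft.rfft(b)), m)
        lags = np.arange(m)
        i = int(np.argmax(c))
        cm1, c0, cp1 = c[(i - 1) % m], c[i], c[(i + 1) % m]
        lag = float(lags[i])
        denom = cm1 - 2 * c0 + cp1
        if denom < 0:
            lag += 0.5 * (cm1 - cp1) / denom
        shift = lag * trace_a.dt * 1000.0
        T = 1000.0 / frequency
        shift = (shift + 0.5 * T) % T - 0.5 * T
        if shift <= -0.5 * T:
            shift += T
        return shift

    c = np.correlate(a, b, mode="full")
    lags = np.arange(-(n - 1), n)
    overlap = n - np.abs(lags)
    c = c / overlap
    # keep lags with at least half overlap so the unbiased estimate stays stable
    keep = overlap >= max(2, n // 2)
    c, lags = c[keep], lags[keep]
    i = int(np.argmax(c))
    lag = float(lags[i])
    if 0 < i < len(c) - 1:
        denom = c[i - 1] - 2 * c[i] + c[i + 1]
        if denom < 0:
            lag += 0.5 * (c[i - 1] - c[i + 1]) / denom
    return lag * trace_a.dt * 1000.0


def phase_shift(trace_a: Trace, trace_b: Trace, frequency: float) -> float:
    """Phase-based delay estimate (ms) of A relative to B at ``frequency``.

    Cross-check for :func:`temporal_shift`; the two agree within a
    couple of milliseconds on clean periodic responses.
    """
    w = 2 * math.pi * frequency

    def phase(tr: Trace) -> float:
        t = tr.time
        v = tr.values - tr.values.mean()
        z = np.sum(v * np.exp(-1j * w * t))
        return math.atan2(z.imag, z.real)

    d = phase(trace_b) - phase(trace_a)
    T = 1000.0 / frequency
    shift = d / w * 1000.0
    shift = (shift + 0.5 * T) % T - 0.5 * T
    return shift


def shift_curve(store: TraceStore, cell_type: str, frequency: float,
                condition: str = "control", source: str = "excitatory",
                analysis_start_s: float = 1.0) -> ShiftCurve:
    """Temporal shifts of sinusoid responses versus background.

    Shifts are measured against the response at the lowest background
    (so they increase as responses speed with light level) and a Hill
    fit of shift versus background is attached.  Requires responses at
    three or more backgrounds.
    """
    traces = [tr for tr in store.select(cell_type=cell_type, condition=condition)
              if tr.stimulus is not None and tr.stimulus.kind == "sinusoid"
              and tr.stimulus.frequency_hz == frequency]
    by_bg: dict[float, list[Trace]] = {}
    for tr in traces:
        by_bg.setdefault(tr.stimulus.background, []).append(tr)
    if len(by_bg) < 3:
        raise ValueError("shift curve requires sinusoid responses at >= 3 backgrounds")
    bgs = np.array(sorted(by_bg))
    t_stop = min(tr.time[-1] for trs in by_bg.values() for tr in trs)
    ref = _mean_trace(by_bg[bgs[0]]).window(analysis_start_s, t_stop)
    shifts = [0.0]  # shift at the reference background is zero by construction
    for b in bgs[1:]:
        tr = _mean_trace(by_bg[b]).window(analysis_start_s, t_stop)
        shifts.append(temporal_shift(ref, tr, frequency=frequency))
    shifts = np.array(shifts)
    pos = bgs > 0
    hill = None
    if pos.sum() >= 3:
        try:
            hill = fit_hill(bgs[pos], shifts[pos] - shifts[pos].min())
        except (ValueError, FitError):
            hill = None
    return ShiftCurve(bgs, shifts, source=source, hill=hill)


def _mean_trace(traces: list[Trace]) -> Trace:
    n = min(tr.n for tr in traces)
    vals = np.mean([tr.values[:n] for tr in traces], axis=0)
    tr0 = traces[0]
    return Trace(t0=tr0.t0, dt=tr0.dt, values=vals, units=tr0.units,
                 stimulus=tr0.stimulus, meta=dict(tr0.meta))


# ---------------------------------------------------------------------------
# integration time and zero crossings
# ---------------------------------------------------------------------------

def integration_time(trace: Trace) -> float:
    """Integration time in ms: response integral up to the first
    post-peak zero crossing, divided by the peak amplitude.

    The trace must be baseline-subtracted with a positive main lobe;
    without a zero crossing the integral runs to the trace end.  The
    statistic is invariant to amplitude scaling and scales linearly
    under time dilation.
    """
    v = trace.values
    peak = float(np.max(v))
    if peak <= 0:
        raise ValueError("integration time requires a positive response lobe")
    i_peak = int(np.argmax(v))
    tzc_idx = None
    frac = 0.0
    for j in range(i_peak + 1, len(v)):
        if v[j] < 0 <= v[j - 1]:
            tzc_idx = j
            denom = v[j - 1] - v[j]
            frac = v[j - 1] / denom if denom > 0 else 0.0
            break
    if tzc_idx is None:
        integral = float(np.trapezoid(v, dx=trace.dt))
    else:
        integral = float(np.trapezoid(v[:tzc_idx], dx=trace.dt))
        # partial trapezoid up to the interpolated crossing
        integral += 0.5 * v[tzc_idx - 1] * frac * trace.dt
    return integral / peak * 1000.0


def integration_time_ratio(store: TraceStore, cell_type: str,
                           bg_low: float, bg_high: float,
                           condition: str = "control") -> float:
    """Ratio of integration times at a low versus a high background.

    Rod-derived ganglion-cell responses contract about three-fold from
    low scotopic to high mesopic backgrounds.
    """
    def one(bg: float) -> float:
        trs = [tr for tr in store.select(cell_type=cell_type, condition=condition,
                                         background=bg)
               if tr.stimulus is not None and tr.stimulus.kind == "flash"]
        if not trs:
            raise ValueError(f"no flash responses at background {bg}")
        tr = _mean_trace(trs)
        t = tr.time
        resp = Trace(t0=0.0, dt=tr.dt, values=(tr.values - tr.baseline())[t >= 0],
                     units=tr.units, stimulus=tr.stimulus, meta=dict(tr.meta))
        if resp.values.max() < 0:  # hyperpolarizing responses: flip sign
            resp.values = -resp.values
        return integration_time(resp)

    return one(bg_low) / one(bg_high)


def zero_crossing_time(trace: Trace) -> float | None:
    """Time (ms, from trace start) of the first sign change after the
    peak, linearly interpolated; ``None`` for monophasic responses."""
    v = trace.values
    i_peak = int(np.argmax(np.abs(v)))
    s = np.sign(v[i_peak])
    for j in range(i_peak + 1, len(v)):
        if np.sign(v[j]) == -s and np.sign(v[j - 1]) != -s:
            t_prev = trace.t0 + (j - 1) * trace.dt
            denom = v[j - 1] - v[j]
            frac = v[j - 1] / denom if denom != 0 else 0.0
            return (t_prev + frac * trace.dt - trace.t0) * 1000.0
    return None


# ---------------------------------------------------------------------------
# membrane time constant
# ---------------------------------------------------------------------------

def fit_membrane_tau(pulse_response: Trace) -> float:
    """Exponential fit of the post-pulse relaxation; returns τ in ms.

    Expects the response to a brief (~1 ms) current pulse; the tail
    after the response extremum is fit with A·exp(−t/τ) around the
    resting level (taken from the pre-pulse epoch, or the final samples
    when the trace starts at the pulse).
    """
    t = trace_t = pulse_response.time
    v = pulse_response.values
    base = pulse_response.baseline() if np.any(trace_t < 0) else float(np.median(v[-max(3, len(v) // 20):]))
    y = v - base
    i_peak = int(np.argmax(np.abs(y)))
    tail = y[i_peak:]
    tt = (t[i_peak:] - t[i_peak])
    peak = tail[0]
    if abs(tail[-1]) > 0.5 * abs(peak):
        raise FitError("tail does not decay; cannot fit a membrane time constant")
    sgn = np.sign(peak) or 1.0
    ytail = sgn * tail

    def model(x, A, tau):
        return A * np.exp(-x / tau)

    # crude 1/e estimate for initialization
    below = np.nonzero(ytail < ytail[0] / math.e)[0]
    tau0 = tt[below[0]] if len(below) else (tt[-1] / 3 or 1e-3)
    try:
        popt, _ = curve_fit(model, tt, ytail, p0=(ytail[0], max(tau0, 1e-4)),
                            bounds=([0.0, 1e-6], [np.inf, 10.0]), maxfev=10000)
    except RuntimeError as e:
        raise FitError(f"membrane tau fit failed: {e}") from e
    return float(popt[1] * 1000.0)
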