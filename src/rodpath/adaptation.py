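"""Light-adaptation analyses: gain curves, Weber slopes, Hill fits,
half-max and saturation estimation from trace collections.

These are the measurements applied to flash and step responses across
adapting backgrounds: response gain (peak divided by flash strength),
gain curves normalized to the gain at 0.3 R*/rod/s, the log–log Weber
slope, nonlinear least-squares Hill fits of amplitude-versus-background
curves, and the steady-state suppression analysis that locates the
half-suppression and 90%-suppression backgrounds.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError
from .traces import Trace, TraceStore

__all__ = [
    "GainCurve",
    "HillFit",
    "peak_amplitude",
    "response_gain",
    "gain_curve",
    "weber_slope",
    "fit_hill",
    "half_max_background",
    "suppression_from_traces",
]


@dataclasses.dataclass
class GainCurve:
    """Per-background gain, normalized to the gain at the reference background."""

    backgrounds: np.ndarray
    gains: np.ndarray
    sem: np.ndarray
    cell_type: str
    n_cells: int
    normalize_at: float = 0.3

    def __post_init__(self) -> None:
        self.backgrounds = np.asarray(self.backgrounds, float)
        self.gains = np.asarray(self.gains, float)
        if np.any(np.diff(self.backgrounds) <= 0):
            raise ValueError("backgrounds must be strictly increasing")
        if np.any(self.gains < 0):
            raise ValueError("gains must be >= 0")


@dataclasses.dataclass
class HillFit:
    """Result of fitting y = ymax · x^n / (x^n + K^n)."""

    K: float
    n: float
    ymax: float
    rss: float
    converged: bool

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        return _hill(x, self.K, self.n, self.ymax)

    @property
    def bg90(self) -> float:
        """Abscissa at 90% of the asymptote: K·9^(1/n)."""
        return self.K * 9.0 ** (1.0 / self.n)


def _hill(x, K, n, ymax):
    x = np.asarray(x, float)
    out = np.zeros_like(x)
    pos = x > 0
    r = (x[pos] / K) ** n
    out[pos] = ymax * r / (1.0 + r)
    return out


# ---------------------------------------------------------------------------
# amplitude and gain
# ---------------------------------------------------------------------------

def peak_amplitude(trace: Trace, baseline_window: tuple[float, float] | None = None,
                   response_window: tuple[float, float] | None = None) -> float:
    """Signed peak of the baseline-subtracted response.

    The baseline is the mean over ``baseline_window`` (default: the
    final 20% of the pre-stimulus epoch) and the peak is the largest
    absolute excursion within ``response_window`` (default: stimulus
    onset to onset + 500 ms), signed by its polarity.
    """
    t = trace.time
    if baseline_window is None:
        base = trace.baseline(0.2)
    else:
        m = (t >= baseline_window[0]) & (t < baseline_window[1])
        if not m.any():
            raise ValueError("baseline window does not overlap the trace")
        base = float(trace.values[m].mean())
    if response_window is None:
        response_window = (0.0, 0.5)
    m = (t >= response_window[0]) & (t < response_window[1])
    if not m.any():
        raise ValueError("response window does not overlap the trace")
    dev = trace.values[m] - base
    i = int(np.argmax(np.abs(dev)))
    return float(dev[i])


def response_gain(trace: Trace, flash_strength: float, **window_kw) -> float:
    """Response gain: peak amplitude divided by flash strength (units per R*/rod)."""
    if flash_strength <= 0:
        raise ValueError("flash_strength must be positive")
    return peak_amplitude(trace, **window_kw) / flash_strength


def gain_curve(store: TraceStore, cell_type: str, normalize_at: float = 0.3,
               condition: str = "control", **window_kw) -> GainCurve:
    """Per-background flash gain averaged over cells, normalized at
    ``normalize_at`` R*/rod/s.

    Requires the store to contain flash responses at two or more
    backgrounds including the normalization background.
    """
    traces = [tr for tr in store.select(cell_type=cell_type, condition=condition)
              if tr.stimulus is not None and tr.stimulus.kind == "flash"
              and tr.meta.get("role", "stimulus") == "stimulus"]
    if not traces:
        raise ValueError(f"store has no flash traces for cell_type={cell_type!r}")
    by_bg: dict[float, list[float]] = {}
    for tr in traces:
        g = abs(response_gain(tr, tr.stimulus.flash_strength, **window_kw))
        by_bg.setdefault(tr.stimulus.background, []).append(g)
    bgs = np.array(sorted(by_bg))
    if len(bgs) < 2:
        raise ValueError("gain curve requires flashes at >= 2 backgrounds")
    ref = [b for b in bgs if np.isclose(b, normalize_at, rtol=1e-9)]
    if not ref:
        raise ValueError(f"store lacks the normalization background {normalize_at} R*/rod/s")
    means = np.array([np.mean(by_bg[b]) for b in bgs])
    sems = np.array([
        (np.std(by_bg[b], ddof=1) / np.sqrt(len(by_bg[b]))) if len(by_bg[b]) > 1 else 0.0
        for b in bgs
    ])
    g0 = means[np.isclose(bgs, ref[0])][0]
    if g0 <= 0:
        raise ValueError("gain at the normalization background is zero")
    n_cells = len({tr.meta.get("cell", 0) for tr in traces})
    return GainCurve(bgs, means / g0, sems / g0, cell_type, n_cells, normalize_at)


def weber_slope(curve: GainCurve, bg_range: tuple[float, float] = (3.0, 100.0)) -> float:
    """Least-squares slope of log10(gain) versus log10(background).

    Over the Weber range the slope is close to −1 (gain inversely
    proportional to background).
    """
    m = (curve.backgrounds >= bg_range[0]) & (curve.backgrounds <= bg_range[1]) \
        & (curve.gains > 0)
    if m.sum() < 2:
        raise ValueError("need >= 2 positive-gain points inside the range")
    x = np.log10(curve.backgrounds[m])
    y = np.log10(curve.gains[m])
    return float(np.polyfit(x, y, 1)[0])


# ---------------------------------------------------------------------------
# Hill fitting
# ---------------------------------------------------------------------------

def fit_hill(x, y, weights=None) -> HillFit:
    """Nonlinear least-squares Hill fit with multi-start initialization.

    K is initialized at the half-rise abscissa (and at the geometric
    mean of x), n at {0.5, 1, 2}; the best-RSS solution is kept.
    Overall-decreasing data cannot be described by a rising Hill curve
    and is flagged unconverged with K/n unset (NaN).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need >= 3 points for a Hill fit")
    if np.any(x <= 0):
        raise ValueError("Hill fit requires x > 0")
    order = np.argsort(x)
    x, y = x[order], y[order]
    sigma = None
    if weights is not None:
        w = np.asarray(weights, float)[order]
        sigma = 1.0 / np.sqrt(np.clip(w, 1e-300, None))

    # an overall falling curve has no feasible rise
    if np.polyfit(np.log10(x), y, 1)[0] < 0 and y[-1] < 0.5 * np.max(y):
        return HillFit(np.nan, np.nan, np.nan, np.inf, converged=False)

    ymax0 = float(np.max(y))
    half = 0.5 * ymax0
    above = x[y >= half]
    k_half = float(above[0]) if len(above) else float(np.sqrt(x[0] * x[-1]))
    k_inits = {k_half, float(np.exp(np.mean(np.log(x))))}
    best = None
    for k0 in k_inits:
        for n0 in (0.5, 1.0, 2.0):
            try:
                popt, _ = curve_fit(
                    _hill, x, y, p0=(k0, n0, ymax0 if ymax0 > 0 else 1.0),
                    sigma=sigma, absolute_sigma=False,
                    bounds=([1e-12, 1e-3, 1e-12], [1e12, 20.0, 1e12]),
                    maxfev=20000,
                )
            except RuntimeError:
                continue
            rss = float(np.sum((_hill(x, *popt) - y) ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss)
    if best is None:
        return HillFit(np.nan, np.nan, np.nan, np.inf, converged=False)
    (K, n, ymax), rss = best
    return HillFit(float(K), float(n), float(ymax), rss, converged=True)


def half_max_background(store: TraceStore, cell_type: str,
                        condition: str = "control", **window_kw) -> float:
    """Half-maximal background of fixed-contrast response amplitudes.

    Fits a Hill curve to peak amplitude versus background and returns
    its half-max constant K (e.g. ~300 R*/rod/s for primate
    NBQX-insensitive AII responses, ~5 for mouse horizontal cells).
    """
    traces = [tr for tr in store.select(cell_type=cell_type, condition=condition)
              if tr.stimulus is not None and tr.meta.get("role", "stimulus") == "stimulus"]
    by_bg: dict[float, list[float]] = {}
    for tr in traces:
        if tr.stimulus.background <= 0:
            continue
        amp = abs(peak_amplitude(tr, **window_kw))
        by_bg.setdefault(tr.stimulus.background, []).append(amp)
    if len(by_bg) < 4:
        raise ValueError("half-max estimation needs amplitudes at >= 4 backgrounds")
    bgs = np.array(sorted(by_bg))
    amps = np.array([np.mean(by_bg[b]) for b in bgs])
    fit = fit_hill(bgs, amps)
    if not fit.converged:
        raise FitError(f"Hill fit did not converge for {cell_type}/{condition}")
    return fit.K


# ---------------------------------------------------------------------------
# steady-state suppression
# ---------------------------------------------------------------------------

def suppression_from_traces(store: TraceStore, cell_type: str = "rod_current",
                            steady_window_frac: float = 0.25):
    """Steady-state suppression of the circulating current versus background.

    For each cell, the dark (saturating-flash) reference amplitude
    scales the steady currents measured during background steps:
    suppression = 1 − steady/reference.  Returns
    ``(backgrounds, suppression fractions, HillFit)``; the 90%
    suppression background is available as ``fit.bg90``.  The result is
    invariant to overall current scaling.
    """
    refs: dict[int, float] = {}
    for tr in store.select(cell_type=cell_type, role="reference_flash"):
        refs[tr.meta.get("cell", 0)] = abs(peak_amplitude(tr))
    if not refs:
        raise ValueError("store lacks saturating reference flashes "
                         "(protocol key 'reference_flash')")
    by_bg: dict[float, list[float]] = {}
    for tr in store.select(cell_type=cell_type, role="stimulus"):
        if tr.stimulus is None or tr.stimulus.kind != "step":
            continue
        ref = refs.get(tr.meta.get("cell", 0))
        if ref is None or ref <= 0:
            raise ValueError(f"cell {tr.meta.get('cell')} has no saturating reference")
        t = tr.time
        t_end = t[-1]
        m = t >= t_end - steady_window_frac * (t_end - 0.0)
        steady = float(tr.values[m & (t >= 0)].mean())
        by_bg.setdefault(tr.stimulus.background, []).append(1.0 - steady / ref)
    if not by_bg:
        raise ValueError("store has no background-step traces")
    bgs = np.array(sorted(by_bg))
    supp = np.array([np.mean(by_bg[b]) for b in bgs])
    pos = bgs > 0
    fit = fit_hill(bgs[pos], np.clip(supp[pos], 0.0, None)) if pos.sum() >= 3 else \
        HillFit(np.nan, np.nan, np.nan, np.inf, False)
    return bgs, supp, fit
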