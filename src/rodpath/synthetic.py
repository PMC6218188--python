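"""Calibrated generative model of rod-pathway retinal electrophysiology.

This module is the synthetic-data stage of the package: a compact,
seeded model of the signals the analysis stages consume — rod outer
segment photocurrents with Weber gain scaling and Hill-type steady-state
saturation, rod voltages with luminance-dependent hyperpolarization and
voltage-dependent membrane filtering, the species-specific routing of
rod signals through the primary (rod bipolar), secondary (rod–cone
coupling) and tertiary pathways to horizontal cells, AII amacrine cells
and retinal ganglion cells, and inhomogeneous-Poisson spike generation.

Model overview
--------------
Steady state.  A background of ``bg`` R*/rod/s suppresses the fraction
``bg^n / (bg^n + K^n)`` of the rod circulating (dark) current.  The
exponent ``n = ln 9 / ln 6.25`` and the half-suppression constants
(primate K = 40, mouse K = 160 R*/rod/s) place 90% suppression at 250
(primate) and 1000 (mouse) R*/rod/s.  Rod flash gain declines as a
Weber term ``1/(1 + bg/I0)`` times the unsuppressed current fraction.

Kinetics.  Flash kernels are multi-stage low-pass cascades.  The
phototransduction stage is four identical first-order stages whose time
constant shrinks with background; the current-to-voltage stage is four
first-order stages at the voltage-dependent membrane time constant
``tau(V) = tau_dark + tau_slope (V − V_dark)``, which halves over the
9 mV steady hyperpolarization produced by a 1→60 R*/rod/s step.  The
stage schedules are calibrated so that at 4 Hz the full cascade speeds
by 100 ms between backgrounds 0.2 and 100 R*/rod/s, with the
phototransduction stage contributing 40% of that shift, and so that
the integration time of ganglion-cell responses contracts three-fold
between 0.3 and 300 R*/rod/s.

Routing.  For fixed-contrast stimuli the primary-pathway amplitude
follows the rod gain law (Weber-flat in the mid range, collapsing with
rod saturation, shaped at low backgrounds by post-rod adaptation and —
in mouse — by an additional primary-pathway saturation term).  The
secondary/tertiary amplitude follows an empirical Hill curve of
background with half-max at 300 (primate) or 5 (mouse) R*/rod/s.
NBQX removes the primary-pathway drive to AII cells; an mGluR6
agonist/antagonist mixture (LY/APB) removes all On-bipolar-derived
drive.
"""

from __future__ import annotations

import dataclasses
import math
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import ConfigError
from .traces import StimulusSpec, Trace, TraceStore

__all__ = [
    "SpeciesParams",
    "species_defaults",
    "CONDITIONS",
    "CELL_TYPES",
    "steady_suppression",
    "rod_gain",
    "steady_voltage",
    "tau_of_voltage",
    "membrane_filter",
    "pathway_weights",
    "primary_amplitude",
    "secondary_amplitude",
    "simulate_rod_current",
    "simulate_cell",
    "spikes_from_rate",
    "sample_cell_params",
    "generate_dataset",
]

# ---------------------------------------------------------------------------
# species parameters
# ---------------------------------------------------------------------------

#: Hill exponent of steady-state saturation, pinned by the primate anchor
#: points (half-suppression at 40, 90% suppression at 250 R*/rod/s):
#: (250/40)^n = 9.
SAT_N = math.log(9.0) / math.log(6.25)

#: hyperpolarization half-max background (R*/rod/s): closed-form solution of
#: dV_max·[H(60) − H(1)] = 9 mV with dV_max = 12 mV and a first-order Hill —
#: the lower root of 3K² − 53K + 180 = 0.
HYP_K = (53.0 - math.sqrt(649.0)) / 6.0

#: membrane potential range (mV) over which tau(V) is linear; clamped outside
V_CLAMP = (-56.0, -42.0)

CONDITIONS = ("control", "NBQX", "LY_APB")

CELL_TYPES = (
    "rod_current",
    "rod_voltage",
    "cone",
    "H1",
    "AII",
    "On_parasol_exc",
    "Off_parasol_exc",
    "On_parasol_spikes",
    "On_midget_spikes",
    "Off_alpha_exc",
)

#: units per cell type
_UNITS = {
    "rod_current": "pA",
    "rod_voltage": "mV",
    "cone": "mV",
    "H1": "mV",
    "AII": "mV",
    "On_parasol_exc": "pA",
    "Off_parasol_exc": "pA",
    "On_parasol_spikes": "spikes_s",
    "On_midget_spikes": "spikes_s",
    "Off_alpha_exc": "pA",
}

#: relative drive of the rod-derived (primary-pathway) signal per LED class
_ROD_LED_DRIVE = {"rod_preferring": 1.0, "mid": 1.0, "cone_preferring": 0.0}


@dataclasses.dataclass(frozen=True)
class SpeciesParams:
    """All calibrated constants for one species.

    Rates are in R*/rod/s, currents in pA, voltages in mV, time
    constants in seconds unless suffixed otherwise.
    """

    name: str

    # steady-state saturation of the circulating current
    sat_K: float
    sat_n: float = SAT_N

    # flash gain: Weber constant and post-rod (circuit) adaptation constant
    weber_I0: float = 3.0
    post_rod_I0: float = 0.3

    # rod absolute scales
    dark_current_pA: float = 20.0
    sens_dark_pA_per_rstar: float = 1.0
    sens_dark_mV_per_rstar: float = 1.0

    # steady-state voltage: V(bg) = V_dark − dV_max · Hill(bg; hyp_K, hyp_n)
    V_dark_mV: float = -44.0
    dV_max_mV: float = 12.0
    hyp_K: float = HYP_K
    hyp_n: float = 1.0

    # membrane time constant vs voltage: tau(V) = tau_dark + tau_slope·(V−V_dark),
    # calibrated so tau halves over a 9 mV hyperpolarization
    tau_mem_dark_s: float = 0.030602737
    input_resistance_gohm: float = 0.25

    # phototransduction kernel: n identical stages, tau shrinking with bg.
    # (tau_photo_dark, photo_I, photo_p) and tau_mem_dark are solved jointly
    # against the three kinetics contracts: 40 ms phototransduction-only and
    # 100 ms full-cascade 4 Hz shift between 0.2 and 100 R*/rod/s, and a
    # 3-fold integration-time contraction between 0.3 and 300 R*/rod/s
    n_photo_stages: int = 4
    tau_photo_dark_s: float = 0.02110553
    photo_I: float = 0.039351618
    photo_p: float = 0.2567637

    # current-to-voltage stage: n first-order stages at tau(V(bg))
    n_voltage_stages: int = 4

    # cone-circuit kernel (secondary-pathway kinetics)
    n_cone_stages: int = 4
    tau_cone_s: float = 0.010

    # routing amplitudes
    secondary_K: float = 300.0
    secondary_n: float = 1.0
    primary_weight: float = 1.0
    secondary_weight: float = 1.0
    tertiary_weight: float = 0.0
    on_rod_cone_weight: float = 1.0
    off_rod_cone_weight: float = 0.5
    # primary-pathway (post-rod-bipolar) saturation; inf disables it
    primary_sat_K: float = math.inf
    primary_sat_n: float = 1.0
    # relative drive of the secondary readout by the rod-preferring LED:
    # near 1 in mouse (rod signals reach the readout through gap junctions),
    # small in primate (the secondary readout there originates in cones,
    # which the short-wavelength LED stimulates weakly)
    secondary_led_rod_drive: float = 0.1

    # LY/APB block completeness of On-bipolar-derived drive
    ly_apb_block_fraction: float = 1.0

    # output scaling
    exc_scale_pA: float = 100.0
    voltage_scale_mV: float = 10.0
    spike_base_rate: float = 10.0
    spike_gain_per_pA: float = 0.5

    # default noise / inter-cell variability
    noise_frac: float = 0.1
    cell_cv: float = 0.15
    v_dark_sd_mV: float = 3.0
    dark_current_cv: float = 0.10

    @property
    def tau_slope_s_per_mV(self) -> float:
        """Slope of tau(V): tau(V_dark − 9 mV) = tau_dark/2."""
        return self.tau_mem_dark_s / 18.0

    def tau_photo(self, bg: float) -> float:
        """Phototransduction stage time constant at background ``bg``."""
        return self.tau_photo_dark_s / (1.0 + bg / self.photo_I) ** self.photo_p

    def tau_membrane(self, bg: float) -> float:
        """Membrane stage time constant at the steady voltage set by ``bg``."""
        return tau_of_voltage(steady_voltage(bg, self), self)


def _primate() -> SpeciesParams:
    return SpeciesParams(name="primate", sat_K=40.0)


def _mouse() -> SpeciesParams:
    return SpeciesParams(
        name="mouse",
        sat_K=160.0,
        secondary_K=5.0,
        secondary_led_rod_drive=1.0,
        # mouse primary-pathway responses collapse in the low mesopic range;
        # the saturation constant and the secondary/tertiary weights are
        # solved jointly so that removing On-bipolar drive (LY/APB) spares
        # 10% of the Off-alpha response at 0.5 R*/rod/s and 65% at 5 R*/rod/s,
        # with the tertiary weight fixed at half the secondary weight
        primary_sat_K=4.8697016,
        primary_sat_n=1.0,
        secondary_weight=0.32971425,
        tertiary_weight=0.16485713,
    )


def species_defaults(name: str) -> SpeciesParams:
    """Return the calibrated default parameter set for ``"primate"`` or ``"mouse"``."""
    if name == "primate":
        return _primate()
    if name == "mouse":
        return _mouse()
    raise ValueError(f"unknown species {name!r}; expected 'primate' or 'mouse'")


# ---------------------------------------------------------------------------
# steady-state functions
# ---------------------------------------------------------------------------

def steady_suppression(bg: float, params: SpeciesParams) -> float:
    """Fraction of the dark current suppressed by background ``bg``.

    Hill function of background with half-suppression at ``sat_K``
    (40 R*/rod/s primate, 160 mouse) and exponent ``sat_n``; 90%
    suppression falls at 250 (primate) and 1000 (mouse) R*/rod/s.
    """
    if bg < 0:
        raise ValueError("background must be >= 0")
    if bg == 0:
        return 0.0
    x = (bg / params.sat_K) ** params.sat_n
    return x / (1.0 + x)


def rod_gain(bg: float, params: SpeciesParams) -> float:
    """Rod flash gain relative to darkness.

    The product of a Weber term 1/(1 + bg/I0) and the unsuppressed
    current fraction; approximately proportional to 1/bg over the Weber
    range (3–100 R*/rod/s primate) and collapsing steeply as the rods
    saturate.
    """
    if bg < 0:
        raise ValueError("background must be >= 0")
    return (1.0 - steady_suppression(bg, params)) / (1.0 + bg / params.weber_I0)


def post_rod_gain(bg: float, params: SpeciesParams) -> float:
    """Divisive post-rod (circuit) adaptation seen at the ganglion-cell level.

    Driven by the rod-adapted signal, so it accumulates over backgrounds
    below ~3 R*/rod/s and then saturates — ganglion-cell gain declines
    faster than rod gain between darkness and 3 R*/rod/s, and in
    parallel with it above.
    """
    bg_eff = bg / (1.0 + bg / params.weber_I0)
    return 1.0 / (1.0 + bg_eff / params.post_rod_I0)


def steady_voltage(bg: float, params: SpeciesParams) -> float:
    """Steady membrane potential (mV) of a rod at background ``bg``.

    V(bg) = V_dark − dV_max·bg^h/(bg^h + K^h); defaults give −44 mV in
    darkness and a 9.0 mV hyperpolarization for a 1→60 R*/rod/s step.
    """
    if bg < 0:
        raise ValueError("background must be >= 0")
    if bg == 0:
        return params.V_dark_mV
    x = (bg / params.hyp_K) ** params.hyp_n
    return params.V_dark_mV - params.dV_max_mV * x / (1.0 + x)


def tau_of_voltage(V: float, params: SpeciesParams) -> float:
    """Membrane time constant (s) at membrane potential ``V`` (mV).

    Linear in V over the physiological range (clamped outside
    [−56, −42] mV); hyperpolarizing by 9 mV from V_dark halves tau.
    """
    v = min(max(V, V_CLAMP[0]), V_CLAMP[1])
    tau = params.tau_mem_dark_s + params.tau_slope_s_per_mV * (v - params.V_dark_mV)
    if tau <= 0:
        raise ValueError(f"membrane time constant is non-positive at V={V} mV")
    return tau


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

#: kernel support (s); long enough that the slowest dark-adapted cascade
#: has decayed to numerical zero
_KERNEL_DUR = 1.75


@lru_cache(maxsize=256)
def _cascade_kernel(stages: tuple, dt: float, dur: float = _KERNEL_DUR) -> np.ndarray:
    """Unit-area impulse response of a cascade of first-order stages.

    ``stages`` is a tuple of (n, tau) blocks; identical-tau blocks are
    gamma kernels, composed by discrete convolution.
    """
    t = np.arange(0.0, dur, dt)
    out = None
    for n, tau in stages:
        if tau <= 0:
            raise ValueError("stage time constants must be positive")
        k = t ** (n - 1) * np.exp(-t / tau) / (tau**n * math.gamma(n))
        s = k.sum() * dt
        if s <= 0:  # tau far below the sample interval: stage acts as identity
            k = np.zeros_like(t)
            k[0] = 1.0 / dt
        else:
            k = k / s  # exact discrete unit area
        out = k if out is None else np.convolve(out, k)[: len(t)] * dt
    return out


def photo_kernel(bg: float, params: SpeciesParams, dt: float, peak_norm: bool = True) -> np.ndarray:
    """Phototransduction-stage flash kernel at background ``bg``."""
    k = _cascade_kernel(((params.n_photo_stages, params.tau_photo(bg)),), dt)
    return k / k.max() if peak_norm else k


def rod_full_kernel(bg: float, params: SpeciesParams, dt: float, peak_norm: bool = True) -> np.ndarray:
    """Full rod kernel: phototransduction plus current-to-voltage stages."""
    k = _cascade_kernel(
        (
            (params.n_photo_stages, params.tau_photo(bg)),
            (params.n_voltage_stages, params.tau_membrane(bg)),
        ),
        dt,
    )
    return k / k.max() if peak_norm else k


def cone_kernel(params: SpeciesParams, dt: float, peak_norm: bool = True) -> np.ndarray:
    """Cone-circuit (secondary-pathway) kernel; background-independent."""
    k = _cascade_kernel(((params.n_cone_stages, params.tau_cone_s),), dt)
    return k / k.max() if peak_norm else k


def membrane_filter(current: Trace, V: float, params: SpeciesParams) -> Trace:
    """Convert a current trace to a voltage trace through the rod membrane.

    A first-order low-pass filter with the voltage-dependent time
    constant tau(V) and DC gain equal to the input resistance; the
    impulse response integrates exactly to the DC gain.
    """
    tau = tau_of_voltage(V, params)
    a = math.exp(-current.dt / tau)
    x = current.values
    y = np.empty_like(x)
    acc = 0.0
    for i in range(len(x)):  # simple exact exponential integrator
        acc = a * acc + (1.0 - a) * x[i]
        y[i] = acc
    return Trace(
        t0=current.t0,
        dt=current.dt,
        values=V + params.input_resistance_gohm * y,
        units="mV",
        stimulus=current.stimulus,
        meta={**current.meta, "filter_tau_s": tau, "filter_V_mV": V},
    )


# ---------------------------------------------------------------------------
# routing amplitudes
# ---------------------------------------------------------------------------

def _primary_shape_raw(bg: float, params: SpeciesParams) -> float:
    """Unnormalized fixed-contrast primary-pathway amplitude vs background."""
    strength = bg  # fixed contrast: flash strength proportional to background
    path_sat = 1.0
    if math.isfinite(params.primary_sat_K):
        path_sat = 1.0 / (1.0 + (bg / params.primary_sat_K) ** params.primary_sat_n)
    return strength * rod_gain(bg, params) * post_rod_gain(bg, params) * path_sat


_shape_max_cache: dict[tuple, float] = {}


def _primary_shape_max(params: SpeciesParams) -> float:
    key = (params.sat_K, params.sat_n, params.weber_I0, params.post_rod_I0,
           params.primary_sat_K, params.primary_sat_n)
    if key not in _shape_max_cache:
        grid = np.logspace(-2, 3.5, 400)
        _shape_max_cache[key] = max(_primary_shape_raw(b, params) for b in grid)
    return _shape_max_cache[key]


def primary_amplitude(bg: float, params: SpeciesParams, contrast: float = 6.0,
                      led: str = "rod_preferring") -> float:
    """Primary-pathway response amplitude to a fixed-contrast stimulus.

    Normalized so the peak over backgrounds equals ``primary_weight``
    for the default species parameters; Weber-flat in the mid range and
    collapsing with rod saturation (mouse additionally with
    primary-pathway saturation).
    """
    shape = _primary_shape_raw(bg, params) / _primary_shape_max(params)
    return params.primary_weight * shape * (contrast / 6.0) * _ROD_LED_DRIVE[led]


def secondary_hill(bg: float, params: SpeciesParams) -> float:
    """Empirical Hill curve of the secondary-pathway fixed-contrast amplitude."""
    if bg == 0:
        return 0.0
    x = (bg / params.secondary_K) ** params.secondary_n
    return x / (1.0 + x)


def secondary_amplitude(bg: float, params: SpeciesParams, contrast: float = 6.0,
                        led: str = "rod_preferring") -> float:
    """Secondary-pathway (cone-routed) response amplitude.

    For rod-preferring stimuli the amplitude follows the background Hill
    curve (half-max 300 primate / 5 mouse R*/rod/s), scaled by the
    species' secondary LED drive; cone-preferring stimuli drive the cone
    circuit directly at full amplitude regardless of background.
    """
    if led == "cone_preferring":
        drive = 1.0
    else:
        drive = params.secondary_led_rod_drive * secondary_hill(bg, params)
        if led == "mid":
            drive = max(drive, secondary_hill(bg, params))  # 520 nm also drives cones well
    return params.secondary_weight * (contrast / 6.0) * drive


def tertiary_amplitude(bg: float, params: SpeciesParams, contrast: float = 6.0,
                       led: str = "rod_preferring") -> float:
    """Tertiary-pathway amplitude: a secondary-shaped term, zero in primate."""
    if params.tertiary_weight == 0.0:
        return 0.0
    base = secondary_amplitude(bg, params, contrast, led)
    return params.tertiary_weight / max(params.secondary_weight, 1e-300) * base


def pathway_weights(bg: float, species: str | SpeciesParams,
                    condition: str = "control") -> tuple[float, float, float]:
    """(primary, secondary, tertiary) signal amplitudes for a fixed-contrast
    stimulus at background ``bg``, without LED spectral scaling.

    NBQX zeroes the primary-pathway drive (at the AII); LY/APB scales
    On-bipolar-derived drive by (1 − block_fraction).
    """
    params = species if isinstance(species, SpeciesParams) else species_defaults(species)
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    prim = params.primary_weight * _primary_shape_raw(bg, params) / _primary_shape_max(params)
    sec = params.secondary_weight * secondary_hill(bg, params)
    tert = params.tertiary_weight * secondary_hill(bg, params)
    if condition == "NBQX":
        prim = 0.0
    elif condition == "LY_APB":
        prim *= 1.0 - params.ly_apb_block_fraction
    return prim, sec, tert


# ---------------------------------------------------------------------------
# trace simulation
# ---------------------------------------------------------------------------

def _grid(stim: StimulusSpec) -> tuple[float, np.ndarray]:
    n = int(round((stim.pre_s + stim.stim_s + stim.tail_s) / stim.dt_s))
    t0 = -stim.pre_s
    return t0, t0 + stim.dt_s * np.arange(n)


def _place_kernel(t: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Return kernel values aligned so the kernel starts at t = 0."""
    y = np.zeros_like(t)
    i0 = int(np.searchsorted(t, -1e-12))
    m = min(len(kernel), len(t) - i0)
    y[i0 : i0 + m] = kernel[:m]
    return y


def _place_step(t: np.ndarray, step_resp: np.ndarray) -> np.ndarray:
    """Like :func:`_place_kernel` but holds the final value after the
    kernel support (step responses settle, they do not return to zero)."""
    y = _place_kernel(t, step_resp)
    i0 = int(np.searchsorted(t, -1e-12))
    if i0 + len(step_resp) < len(t):
        y[i0 + len(step_resp):] = step_resp[-1]
    return y


def _sin_response(t: np.ndarray, kernel: np.ndarray, dt: float, f: float,
                  stim_s: float) -> np.ndarray:
    """Convolve a peak-normalized kernel with a sinusoid switched on at t=0."""
    on = (t >= -1e-12) & (t < stim_s - 1e-12)
    drive = np.zeros_like(t)
    tt = t[on]
    drive[on] = np.sin(2.0 * math.pi * f * tt)
    return np.convolve(drive, kernel)[: len(t)] * dt


def _add_noise(values: np.ndarray, sd: float, rng: np.random.Generator | None) -> np.ndarray:
    if sd <= 0 or rng is None:
        return values
    return values + rng.normal(0.0, sd, size=values.shape)


def simulate_rod_current(stim: StimulusSpec, params: SpeciesParams | None = None,
                         noise_sd: float = 0.0,
                         seed: int | np.random.Generator | None = None) -> Trace:
    """Simulate a rod outer segment (suction-electrode) current trace.

    The trace records the circulating current in pA; light responses are
    plotted as upward (suppressed-current) deflections, bounded by the
    circulating current available at that background.  Flash responses
    are ``flash strength × rod gain × sensitivity`` times the
    peak-normalized phototransduction kernel; steps relax to the new
    steady level through the same cascade.  ``noise_sd`` is additive
    Gaussian SD in pA; ``seed`` makes the trace reproducible.
    """
    params = params or species_defaults("primate")
    rng = seed if isinstance(seed, np.random.Generator) else (
        np.random.default_rng(seed) if noise_sd > 0 else None)
    t0, t = _grid(stim)
    bg = stim.background
    i_circ = params.dark_current_pA * (1.0 - steady_suppression(bg, params))

    if stim.kind == "flash":
        amp = stim.flash_strength * rod_gain(bg, params) * params.sens_dark_pA_per_rstar
        resp = np.minimum(amp * _place_kernel(t, photo_kernel(bg, params, stim.dt_s)), i_circ)
        values = i_circ + resp
    elif stim.kind == "step":
        i_pre = params.dark_current_pA * (1.0 - steady_suppression(stim.pre_background, params))
        k = photo_kernel(bg if bg > 0 else 1.0, params, stim.dt_s, peak_norm=False)
        step_resp = np.cumsum(k) * stim.dt_s
        values = i_pre + (i_circ - i_pre) * _place_step(t, step_resp)
    elif stim.kind == "sinusoid":
        amp = (stim.contrast * bg * 0.010) * rod_gain(bg, params) * params.sens_dark_pA_per_rstar
        y = amp * _sin_response(t, photo_kernel(bg, params, stim.dt_s), stim.dt_s,
                                stim.frequency_hz, stim.stim_s)
        values = i_circ + np.clip(y, -i_circ, i_circ)
    else:  # pragma: no cover - StimulusSpec already validates
        raise ValueError(f"unknown stimulus kind {stim.kind!r}")

    values = _add_noise(values, noise_sd, rng)
    return Trace(t0=t0, dt=stim.dt_s, values=values, units="pA", stimulus=stim,
                 meta={"cell_type": "rod_current", "species": params.name,
                       "condition": "control", "seed": _seed_repr(seed)})


def compatible(cell_type: str, condition: str) -> bool:
    """Whether a pharmacological condition is meaningful for a cell type.

    NBQX and LY/APB act at or downstream of the rod bipolar output, so
    photoreceptor, cone and horizontal-cell recordings only exist in
    control solution.
    """
    if condition == "control":
        return True
    return cell_type in ("AII", "On_parasol_exc", "Off_parasol_exc",
                         "On_parasol_spikes", "On_midget_spikes", "Off_alpha_exc")


def _routing_amplitudes(cell_type: str, stim: StimulusSpec, params: SpeciesParams,
                        condition: str) -> tuple[float, float]:
    """(rod-pathway amplitude, cone-pathway amplitude) for a downstream cell."""
    bg, C, led = stim.background, stim.contrast, stim.led
    prim = primary_amplitude(bg, params, C, led)
    sec = secondary_amplitude(bg, params, C, led)
    tert = tertiary_amplitude(bg, params, C, led)

    on_cell = cell_type in ("AII", "On_parasol_exc", "On_parasol_spikes", "On_midget_spikes")
    off_cell = cell_type in ("Off_parasol_exc", "Off_alpha_exc")

    if cell_type in ("cone", "H1"):
        if condition != "control":
            raise ValueError(f"{condition} is incompatible with {cell_type}: the "
                             "manipulation acts downstream of the secondary readout")
        return 0.0, sec
    if off_cell:
        prim = params.off_rod_cone_weight / params.on_rod_cone_weight * prim
        cone_side = sec + tert
    else:
        cone_side = sec

    if condition == "NBQX":
        prim = 0.0
    elif condition == "LY_APB":
        block = 1.0 - params.ly_apb_block_fraction
        prim *= block
        if on_cell:
            cone_side *= block  # On cells lose cone-bipolar drive too
    return prim, cone_side


def simulate_cell(cell_type: str, stim: StimulusSpec,
                  species: str | SpeciesParams = "primate",
                  condition: str = "control",
                  seed: int | np.random.Generator | None = None,
                  noise_frac: float = 0.0) -> Trace:
    """Simulate a trace for any supported cell type.

    Composes phototransduction, membrane/kinetics stages and pathway
    weighting: horizontal cells and cones carry the secondary-pathway
    signal only; AII amacrine cells carry primary plus secondary; On
    parasol excitatory input shares the AII routing weights; Off cells
    weight the rod-derived side at half the On weight; rod- and
    cone-derived components add linearly.  ``noise_frac`` sets the
    additive Gaussian SD as a fraction of the response peak.
    """
    params = species if isinstance(species, SpeciesParams) else species_defaults(species)
    if cell_type not in CELL_TYPES:
        raise ValueError(f"unknown cell type {cell_type!r}; expected one of {CELL_TYPES}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    if cell_type == "Off_alpha_exc" and params.name != "mouse":
        raise ValueError("Off_alpha_exc is a mouse cell type")
    rng = seed if isinstance(seed, np.random.Generator) else (
        np.random.default_rng(seed) if noise_frac > 0 else None)

    if cell_type == "rod_current":
        if condition != "control":
            raise ValueError(f"{condition} is incompatible with rod_current recordings")
        tr = simulate_rod_current(stim, params, 0.0, None)
        sd = noise_frac * _response_scale(tr)
        tr.values = _add_noise(tr.values, sd, rng)
        tr.meta["seed"] = _seed_repr(seed)
        return tr

    t0, t = _grid(stim)
    dt = stim.dt_s
    bg = stim.background

    if cell_type == "rod_voltage":
        if condition != "control":
            raise ValueError(f"{condition} is incompatible with rod_voltage recordings")
        v_ss = steady_voltage(bg, params)
        if stim.kind == "flash":
            amp = stim.flash_strength * rod_gain(bg, params) * params.sens_dark_mV_per_rstar
            amp = min(amp, params.dV_max_mV)  # response bounded by the operating range
            values = v_ss - amp * _place_kernel(t, rod_full_kernel(bg, params, dt))
        elif stim.kind == "step":
            v_pre = steady_voltage(stim.pre_background, params)
            k = rod_full_kernel(bg if bg > 0 else 1.0, params, dt, peak_norm=False)
            values = v_pre + (v_ss - v_pre) * _place_step(t, np.cumsum(k) * dt)
        else:
            amp = (stim.contrast * bg * 0.010) * rod_gain(bg, params) * params.sens_dark_mV_per_rstar
            values = v_ss - amp * _sin_response(t, rod_full_kernel(bg, params, dt), dt,
                                                stim.frequency_hz, stim.stim_s)
        values = _add_noise(values, noise_frac * _scale_of(values), rng)
        return _mk(values, t0, stim, cell_type, params, condition, seed, "mV")

    # downstream cells: additive rod- and cone-pathway components
    if stim.kind == "step":
        raise ValueError("step stimuli are supported for rod_current and rod_voltage only")
    a_rod, a_cone = _routing_amplitudes(cell_type, stim, params, condition)
    scale = params.exc_scale_pA if _UNITS[cell_type] == "pA" else params.voltage_scale_mV
    if cell_type == "On_midget_spikes":
        scale = params.exc_scale_pA * 0.7
    elif cell_type == "On_parasol_spikes":
        scale = params.exc_scale_pA

    k_rod = rod_full_kernel(bg, params, dt)
    k_cone = cone_kernel(params, dt)
    if stim.kind == "flash":
        values = scale * (a_rod * _place_kernel(t, k_rod) + a_cone * _place_kernel(t, k_cone))
    else:
        values = scale * (
            a_rod * _sin_response(t, k_rod, dt, stim.frequency_hz, stim.stim_s)
            + a_cone * _sin_response(t, k_cone, dt, stim.frequency_hz, stim.stim_s)
        )

    if cell_type.endswith("_spikes"):
        values = np.clip(params.spike_base_rate + params.spike_gain_per_pA * values, 0.0, None)
        values = _add_noise(values, noise_frac * _scale_of(values), rng)
        return _mk(np.clip(values, 0.0, None), t0, stim, cell_type, params, condition,
                   seed, "spikes_s")
    values = _add_noise(values, noise_frac * _scale_of(values), rng)
    return _mk(values, t0, stim, cell_type, params, condition, seed, _UNITS[cell_type])


def _scale_of(values: np.ndarray) -> float:
    v = values - values[0]
    return float(np.max(np.abs(v))) if np.any(v) else float(np.max(np.abs(values)) or 1.0)


def _response_scale(tr: Trace) -> float:
    return _scale_of(tr.values)


def _seed_repr(seed) -> int | None:
    return seed if isinstance(seed, (int, np.integer)) else None


def _mk(values, t0, stim, cell_type, params, condition, seed, units) -> Trace:
    return Trace(t0=t0, dt=stim.dt_s, values=values, units=units, stimulus=stim,
                 meta={"cell_type": cell_type, "species": params.name,
                       "condition": condition, "seed": _seed_repr(seed)})


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

def spikes_from_rate(rate: Trace, n_trials: int, seed: int | np.random.Generator | None,
                     return_trains: bool = False):
    """Generate inhomogeneous-Poisson spike trains and their PSTH.

    Each trial draws independent Poisson counts per time bin with mean
    ``rate·dt``; the PSTH is the trial-averaged binned rate, so its
    expectation equals the input rate.  Returns the PSTH trace, or
    ``(psth, trains)`` with per-trial spike-time arrays when
    ``return_trains`` is set.
    """
    if np.any(rate.values < 0):
        raise ValueError("rate must be non-negative")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = rate.values * rate.dt
    counts = rng.poisson(lam[None, :].repeat(n_trials, axis=0))
    psth = counts.mean(axis=0) / rate.dt
    out = Trace(t0=rate.t0, dt=rate.dt, values=psth, units="spikes_s",
                stimulus=rate.stimulus,
                meta={**rate.meta, "n_trials": n_trials, "psth": True})
    if not return_trains:
        return out
    t = rate.time
    trains = []
    for i in range(n_trials):
        idx = np.nonzero(counts[i])[0]
        times = np.concatenate(
            [t[j] + rate.dt * rng.random(counts[i, j]) for j in idx]
        ) if len(idx) else np.array([])
        trains.append(np.sort(times))
    return out, trains


# ---------------------------------------------------------------------------
# inter-cell variability
# ---------------------------------------------------------------------------

def sample_cell_params(params: SpeciesParams, rng: np.random.Generator) -> SpeciesParams:
    """Draw one cell's parameters around the species defaults.

    Lognormal multiplicative jitter (CV ``cell_cv``) on response
    amplitudes and the hyperpolarization range, CV 10% on the dark
    current, and Gaussian jitter (SD ``v_dark_sd_mV``) on the dark
    resting potential.
    """
    g = lambda cv: float(rng.lognormal(mean=-0.5 * cv * cv, sigma=cv))  # mean-1 lognormal
    return dataclasses.replace(
        params,
        dark_current_pA=params.dark_current_pA * g(params.dark_current_cv),
        sens_dark_pA_per_rstar=params.sens_dark_pA_per_rstar * g(params.cell_cv),
        sens_dark_mV_per_rstar=params.sens_dark_mV_per_rstar * g(params.cell_cv),
        dV_max_mV=params.dV_max_mV * g(params.cell_cv),
        V_dark_mV=params.V_dark_mV + float(rng.normal(0.0, params.v_dark_sd_mV)),
        exc_scale_pA=params.exc_scale_pA * g(params.cell_cv),
        voltage_scale_mV=params.voltage_scale_mV * g(params.cell_cv),
    )


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

_PROTOCOL_KEYS = {
    "master_seed", "species", "cell_types", "conditions", "backgrounds",
    "n_cells", "noise_frac", "cell_variability", "stimulus", "reference_flash",
    "n_trials",
}
_STIMULUS_KEYS = {
    "kind", "contrast", "duration_ms", "frequency_hz", "led", "pre_ms",
    "stim_ms", "tail_ms", "dt_ms", "strength_rstar", "pre_background",
}


def _stimulus_from_protocol(sdict: dict, background: float) -> StimulusSpec:
    unknown = set(sdict) - _STIMULUS_KEYS
    if unknown:
        raise ConfigError(f"unknown stimulus key(s): {sorted(unknown)}")
    ms = lambda key, default: float(sdict.get(key, default)) / 1000.0
    return StimulusSpec(
        kind=sdict.get("kind", "flash"),
        background=background,
        pre_background=float(sdict.get("pre_background", 0.0)),
        contrast=float(sdict.get("contrast", 6.0)),
        duration_s=ms("duration_ms", 10.0),
        strength_rstar=(None if sdict.get("strength_rstar") is None
                        else float(sdict["strength_rstar"])),
        frequency_hz=(None if sdict.get("frequency_hz") is None
                      else float(sdict["frequency_hz"])),
        led=sdict.get("led", "rod_preferring"),
        pre_s=ms("pre_ms", 500.0),
        stim_s=ms("stim_ms", 1000.0),
        tail_s=ms("tail_ms", 1000.0),
        dt_s=ms("dt_ms", 1.0),
    )


def load_protocol(source: str | Path | dict) -> dict:
    """Load and validate a protocol mapping from YAML (path or text) or a dict."""
    if isinstance(source, dict):
        proto = dict(source)
    else:
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        try:
            proto = yaml.safe_load(text)
        except yaml.YAMLError as e:
            mark = getattr(e, "problem_mark", None)
            loc = f" at line {mark.line + 1}" if mark is not None else ""
            raise ConfigError(f"malformed protocol YAML{loc}: {e}") from e
        if proto is None:
            proto = {}
        if not isinstance(proto, dict):
            raise ConfigError("protocol must be a mapping")
    unknown = set(proto) - _PROTOCOL_KEYS
    if unknown:
        raise ConfigError(f"unknown protocol key(s): {sorted(unknown)}")
    if proto and "master_seed" not in proto:
        raise ConfigError("protocol is missing required key 'master_seed'")
    return proto


def generate_dataset(protocol: str | Path | dict) -> TraceStore:
    """Generate the full factorial dataset a protocol describes.

    The factorial is cells × conditions × backgrounds for each requested
    cell type, with per-trace seeds spawned deterministically from
    ``master_seed``; rerunning with the same protocol and master seed
    reproduces the store exactly.  An optional saturating reference
    flash from darkness is added per rod for suppression analyses.
    """
    proto = load_protocol(protocol)
    store = TraceStore(protocol=proto)
    if not proto:
        return store

    master_seed = int(proto["master_seed"])
    species = proto.get("species", "primate")
    params0 = species_defaults(species)
    cell_types = list(proto.get("cell_types", ["rod_current"]))
    conditions = list(proto.get("conditions", ["control"]))
    backgrounds = [float(b) for b in proto.get("backgrounds", [0.0])]
    n_cells = int(proto.get("n_cells", 1))
    noise_frac = float(proto.get("noise_frac", params0.noise_frac))
    variability = bool(proto.get("cell_variability", True))
    n_trials = int(proto.get("n_trials", 20))
    sdict = dict(proto.get("stimulus", {}))

    for ct in cell_types:
        if ct not in CELL_TYPES:
            raise ConfigError(f"unknown cell type {ct!r} in protocol")
    for cond in conditions:
        if cond not in CONDITIONS:
            raise ConfigError(f"unknown condition {cond!r} in protocol")

    trace_idx = 0
    cell_idx = 0
    for ct in cell_types:
        for ci in range(n_cells):
            cell_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=master_seed, spawn_key=(0, cell_idx)))
            params = sample_cell_params(params0, cell_rng) if variability else params0
            cell_idx += 1
            if bool(proto.get("reference_flash", False)) and ct == "rod_current":
                stim = _stimulus_from_protocol(
                    {**sdict, "kind": "flash", "strength_rstar": 1e4}, 0.0)
                tr = simulate_cell(ct, stim, params, "control", None, 0.0)
                tr.meta.update(cell=ci, role="reference_flash",
                               master_seed=master_seed, trace_index=-1)
                store.add(tr, key=f"{ct}/reference/cell{ci}")
            for cond in conditions:
                if not compatible(ct, cond):
                    continue  # pharmacology acts downstream of this recording
                for bg in backgrounds:
                    rng = np.random.default_rng(
                        np.random.SeedSequence(entropy=master_seed, spawn_key=(1, trace_idx)))
                    stim = _stimulus_from_protocol(sdict, bg)
                    tr = simulate_cell(ct, stim, params, cond, rng, noise_frac)
                    if ct.endswith("_spikes"):
                        tr = spikes_from_rate(tr, n_trials, rng)
                    tr.meta.update(cell=ci, role="stimulus", master_seed=master_seed,
                                   trace_index=trace_idx, seed=None)
                    store.add(tr, key=f"{ct}/{cond}/bg{bg:g}/cell{ci}")
                    trace_idx += 1
    return store
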