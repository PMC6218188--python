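"""Stimulus photometry: photon flux to photoisomerization bookkeeping.

Light levels throughout the package are expressed as photoisomerization
rates (R*/receptor/s).  This module converts calibrated photon fluxes to
R* rates through the receptor collecting area, computes fixed-contrast
flash strengths (flash strength scales with the background so that
Weber contrast is constant), and decomposes two-LED response ratios
into rod and cone fractions under a linear, additive two-source
mixture model.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

__all__ = [
    "ReceptorOptics",
    "FlashSpec",
    "PRIMATE_ROD_OPTICS",
    "PRIMATE_CONE_OPTICS",
    "MOUSE_ROD_OPTICS",
    "isomerization_rate",
    "flash_isomerizations",
    "fixed_contrast_series",
    "rod_cone_decomposition",
]


@dataclasses.dataclass(frozen=True)
class ReceptorOptics:
    """Effective light-collection properties of one receptor/LED pair.

    ``collecting_area`` is in μm² per receptor; ``spectral_factor`` is the
    unitless relative sensitivity of the receptor to a given LED
    (1.0 = nominal).  Absolute LED emission and pigment absorption
    spectra are out of scope; any spectral mismatch is folded into
    ``spectral_factor``.
    """

    collecting_area: float
    spectral_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.collecting_area <= 0:
            raise ValueError("collecting_area must be positive (μm²)")
        if self.spectral_factor < 0:
            raise ValueError("spectral_factor must be >= 0")


# collecting areas used for calibration: primate rods 1 μm², primate
# cones 0.37 μm², mouse rods 0.5 μm²
PRIMATE_ROD_OPTICS = ReceptorOptics(collecting_area=1.0)
PRIMATE_CONE_OPTICS = ReceptorOptics(collecting_area=0.37)
MOUSE_ROD_OPTICS = ReceptorOptics(collecting_area=0.5)


@dataclasses.dataclass(frozen=True)
class FlashSpec:
    """A fixed-contrast flash on a steady background.

    ``background`` is in R*/receptor/s; ``contrast`` is a unitless
    fraction (6.0 ≡ 600% contrast); ``duration`` in seconds.
    """

    background: float
    contrast: float
    duration: float
    led_class: str = "rod_preferring"

    def __post_init__(self) -> None:
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.contrast < -1:
            raise ValueError("contrast must be >= -1")


def isomerization_rate(intensity: float, optics: ReceptorOptics) -> float:
    """Convert photon flux (photons/μm²/s) to R*/receptor/s.

    The conversion is the product of the flux, the receptor collecting
    area and the LED-specific spectral factor.
    """
    if intensity < 0:
        raise ValueError("intensity must be >= 0 (photons/μm²/s)")
    return float(intensity) * optics.collecting_area * optics.spectral_factor


def flash_isomerizations(flash: FlashSpec) -> float:
    """Total R*/receptor delivered during the flash window.

    Counts background plus increment photons, (1 + C)·bg·Δt: a 600%
    contrast, 10 ms flash delivers 0.07 R*/rod from a background of
    1 R*/rod/s and 0.7 R*/rod from 10 R*/rod/s.
    """
    return (1.0 + flash.contrast) * flash.background * flash.duration


def fixed_contrast_series(
    backgrounds: Sequence[float], contrast: float, duration: float
) -> np.ndarray:
    """Flash strengths for a series of backgrounds at fixed contrast.

    Output is exactly proportional to the backgrounds.
    """
    bgs = np.asarray(backgrounds, dtype=float)
    if bgs.size == 0:
        return np.array([])
    if np.any(bgs < 0):
        raise ValueError("backgrounds must be >= 0")
    return np.array(
        [flash_isomerizations(FlashSpec(b, contrast, duration)) for b in bgs]
    )


def rod_cone_decomposition(kappa: float, rho_obs: float) -> tuple[float, float]:
    """Split a two-LED response ratio into cone fractions per LED.

    The control measurement compares responses to a comparison LED and a
    reference LED.  Pure-rod responses give an LED ratio of 1 (after
    normalisation), pure-cone responses a ratio of ``kappa`` (~2.4 for
    rod vs M-cone spectral sensitivities).  Assuming the rod- and
    cone-derived components respond linearly and additively, an
    observed ratio ``rho_obs`` solves

        rho_obs = (1 + kappa·α) / (1 + α)

    for α, the cone/rod amplitude ratio on the reference LED.  Returns
    ``(cone fraction of the reference-LED response,
       cone fraction of the comparison-LED response)``
    = (α/(1+α), kappa·α/(1+kappa·α)).

    Raises
    ------
    ValueError
        If ``kappa <= 1`` or ``rho_obs`` lies outside [1, kappa]
        (infeasible mixture).
    """
    if kappa <= 1:
        raise ValueError("kappa must exceed 1 (cone/rod LED-ratio factor)")
    if not (1.0 <= rho_obs <= kappa):
        raise ValueError(
            f"rho_obs={rho_obs} infeasible: a two-source mixture requires 1 <= rho_obs <= kappa={kappa}"
        )
    if rho_obs == kappa:
        return 1.0, 1.0
    alpha = (rho_obs - 1.0) / (kappa - rho_obs)
    return alpha / (1.0 + alpha), kappa * alpha / (1.0 + kappa * alpha)


def mixture_ratio(kappa: float, alpha: float) -> float:
    """Forward mixture model: LED ratio produced by cone/rod amplitude α."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    return (1.0 + kappa * alpha) / (1.0 + alpha)
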