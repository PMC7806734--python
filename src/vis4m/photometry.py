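"""Stimulus characterization: photometric conversions, LED spectral models,
pigment nomogram templates and opsin-effective photon flux.

The maze's arm illumination is measured with a light meter in exposure-value
(EV) mode at ISO 100 and converted to photometric units by

    illuminance [lux]    = 2.5 * 2^EV
    luminance   [cd/m^2] = 2^(EV - 3)

(so lux = 20 * cd/m^2 for this meter setup).  Radiometric quantities follow
from the LED's relative spectral power distribution S(lambda): an
illuminance L corresponds to irradiance

    E_e [W/m^2] = L / (683 * integral S(lambda) V(lambda) d lambda)

with S normalized to unit integral and V the CIE photopic efficiency curve
(683 lm/W at 555 nm is the candela anchor).  Photon flux weights the
spectral irradiance by lambda/(h c); the opsin-effective flux additionally
weights by a visual-pigment spectral-sensitivity template and (optionally)
the lens transmission in front of the retina.

LED emission bands are modeled as Gaussian components from their printed
peak wavelength and FWHM (sigma = FWHM / (2 sqrt(2 ln 2))); the phosphor
white LED is a two-component mixture (blue pump + broad phosphor band).
A component with ``fwhm_nm=0`` is treated as a monochromatic line, for
which all conversions reduce to their closed forms.

Pigment templates are the A1 visual-pigment nomogram of Govardovskii et al.
(alpha and beta absorbance bands parameterized solely by the peak
wavelength), peak-normalized to 1.  Mouse opsins: S-cone 360 nm, M-cone
508 nm, rod 498 nm, melanopsin 480 nm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from ._cie import K_M, photopic_efficiency

__all__ = [
    "SpectrumComponent",
    "LEDSpectrum",
    "OpsinTemplate",
    "LightCondition",
    "RED_LED",
    "GREEN_LED",
    "BLUE_LED",
    "WHITE_LED",
    "LED_BY_ARM",
    "OPSIN_PEAKS",
    "ev_to_illuminance",
    "illuminance_to_ev",
    "ev_to_luminance",
    "luminance_to_ev",
    "illuminance_to_irradiance",
    "irradiance_to_log_photon_flux",
    "pigment_sensitivity",
    "lens_transmission",
    "effective_log_photon_flux",
    "classify_light_regime",
    "luminance_ratio",
]

# Planck constant [J s] and speed of light [m/s]
_H = 6.62607015e-34
_C = 2.99792458e8

_GRID = np.arange(300.0, 800.0 + 1.0, 1.0)  # 1-nm working grid
_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # ~2.355


@dataclass(frozen=True)
class SpectrumComponent:
    """One emission band: peak wavelength, FWHM and relative power weight."""

    peak_nm: float
    fwhm_nm: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not 300.0 <= self.peak_nm <= 800.0:
            raise ValueError(f"peak_nm {self.peak_nm} outside [300, 800]")
        if self.fwhm_nm < 0:
            raise ValueError("fwhm_nm must be >= 0 (0 = monochromatic line)")
        if self.weight <= 0:
            raise ValueError("weight must be positive")


@dataclass(frozen=True)
class LEDSpectrum:
    """Relative spectral power distribution built from 1-2 components.

    Gaussian components are evaluated on a 1-nm grid over 300-800 nm and the
    total is normalized to unit integral; zero-FWHM components are discrete
    lines carrying their weight fraction of the power.
    """

    components: tuple[SpectrumComponent, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.components) <= 2:
            raise ValueError("an LED spectrum has 1 or 2 components")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            object.__setattr__(
                self,
                "components",
                tuple(
                    SpectrumComponent(c.peak_nm, c.fwhm_nm, c.weight / total)
                    for c in self.components
                ),
            )

    @classmethod
    def monochromatic(cls, wavelength_nm: float) -> "LEDSpectrum":
        return cls((SpectrumComponent(wavelength_nm, 0.0, 1.0),))

    @property
    def lines(self) -> list[SpectrumComponent]:
        return [c for c in self.components if c.fwhm_nm == 0.0]

    @property
    def bands(self) -> list[SpectrumComponent]:
        return [c for c in self.components if c.fwhm_nm > 0.0]

    def band_spd(self) -> np.ndarray:
        """Gaussian (non-line) part of the SPD on the 1-nm grid, unit-weight-scaled.

        Integrates (trapezoid) to the summed weight of the Gaussian
        components; line components are handled analytically elsewhere.
        """
        spd = np.zeros_like(_GRID)
        for c in self.bands:
            sigma = c.fwhm_nm / _FWHM_TO_SIGMA
            g = np.exp(-0.5 * ((_GRID - c.peak_nm) / sigma) ** 2)
            area = np.trapezoid(g, _GRID)
            spd += c.weight * g / area
        return spd

    def weighted_integral(self, fn: Callable[[np.ndarray], np.ndarray]) -> float:
        """integral S(lambda) fn(lambda) d lambda with S unit-normalized."""
        total = 0.0
        for c in self.lines:
            total += c.weight * float(np.asarray(fn(np.asarray([c.peak_nm])))[0])
        if self.bands:
            total += float(np.trapezoid(self.band_spd() * fn(_GRID), _GRID))
        return total


# The four arm LEDs: peak/FWHM in nm.  The white LED is a blue pump plus a
# broad yellow phosphor band; the pump/phosphor power split is not a printed
# quantity and defaults to 0.3/0.7.
RED_LED = LEDSpectrum((SpectrumComponent(628.0, 17.0),))
GREEN_LED = LEDSpectrum((SpectrumComponent(517.0, 31.0),))
BLUE_LED = LEDSpectrum((SpectrumComponent(452.0, 22.0),))


def white_led(blue_weight: float = 0.3) -> LEDSpectrum:
    return LEDSpectrum(
        (
            SpectrumComponent(441.0, 19.0, blue_weight),
            SpectrumComponent(533.0, 104.0, 1.0 - blue_weight),
        )
    )


WHITE_LED = white_led()

LED_BY_ARM: dict[str, LEDSpectrum] = {
    "R": RED_LED,
    "G": GREEN_LED,
    "B": BLUE_LED,
    "W": WHITE_LED,
}

#: Peak sensitivities (nm) of the mouse photopigments.
OPSIN_PEAKS: dict[str, float] = {
    "S-opsin": 360.0,
    "M-opsin": 508.0,
    "rod": 498.0,
    "melanopsin": 480.0,
}


def ev_to_illuminance(ev: float) -> float:
    """lux = 2.5 * 2^EV (light meter at ISO 100)."""
    return 2.5 * 2.0**ev


def illuminance_to_ev(lux: float) -> float:
    if lux <= 0:
        raise ValueError("illuminance must be positive")
    return math.log2(lux / 2.5)


def ev_to_luminance(ev: float) -> float:
    """cd/m^2 = 2^(EV - 3)."""
    return 2.0 ** (ev - 3.0)


def luminance_to_ev(cd_m2: float) -> float:
    if cd_m2 <= 0:
        raise ValueError("luminance must be positive")
    return math.log2(cd_m2) + 3.0


def illuminance_to_irradiance(lux: float, spectrum: LEDSpectrum) -> float:
    """Irradiance in uW/cm^2 equivalent to ``lux`` for the given spectrum.

    E_e [W/m^2] = lux / (683 * <V>) with <V> the photopic efficiency of the
    unit-normalized spectrum; 1 W/m^2 = 100 uW/cm^2.
    """
    if lux < 0:
        raise ValueError("illuminance must be >= 0")
    v_bar = spectrum.weighted_integral(photopic_efficiency)
    if v_bar <= 0:
        raise ValueError("non-visible spectrum: zero photopic overlap")
    e_e_w_m2 = lux / (K_M * v_bar)
    return e_e_w_m2 * 100.0


def irradiance_to_log_photon_flux(
    irradiance_uw_cm2: float, spectrum: LEDSpectrum
) -> float:
    """log10 photon flux [photons/cm^2/s] for a given irradiance and spectrum.

    Photon flux = integral E_e S(lambda) * lambda/(h c) d lambda.
    """
    if irradiance_uw_cm2 <= 0:
        raise ValueError("irradiance must be positive")
    # mean of lambda/(h c) in photons per joule, lambda in meters
    photons_per_joule = spectrum.weighted_integral(
        lambda wl: wl * 1e-9 / (_H * _C)
    )
    flux = irradiance_uw_cm2 * 1e-6 * photons_per_joule  # photons/cm^2/s
    return math.log10(flux)


# -- pigment nomogram ---------------------------------------------------------

# A1 nomogram constants (alpha band) and beta-band parameterization.
_A_ALPHA, _B_ALPHA, _C_ALPHA, _D_ALPHA = 69.7, 28.0, -14.9, 0.674
_B_BAND_B, _B_BAND_C = 0.922, 1.104


def _a1_template(lambda_max: float, wl: np.ndarray) -> np.ndarray:
    """Un-normalized A1 pigment absorbance: alpha + beta bands."""
    x = lambda_max / wl
    a = 0.8795 + 0.0459 * math.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    with np.errstate(over="ignore"):
        alpha = 1.0 / (
            np.exp(_A_ALPHA * (a - x))
            + np.exp(_B_ALPHA * (_B_BAND_B - x))
            + np.exp(_C_ALPHA * (_B_BAND_C - x))
            + _D_ALPHA
        )
    lambda_mb = 189.0 + 0.315 * lambda_max
    b_beta = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((wl - lambda_mb) / b_beta) ** 2))
    return alpha + beta


@dataclass(frozen=True)
class OpsinTemplate:
    """A pigment spectral-sensitivity function, peak-normalized to 1."""

    name: str
    lambda_max_nm: float
    _norm: float = field(repr=False, default=1.0)

    def sensitivity(self, wavelength_nm) -> np.ndarray | float:
        wl = np.atleast_1d(np.asarray(wavelength_nm, dtype=float))
        s = _a1_template(self.lambda_max_nm, wl) / self._norm
        s = np.clip(s, 0.0, 1.0)
        if np.isscalar(wavelength_nm):
            return float(s[0])
        return s

    def __call__(self, wavelength_nm):
        return self.sensitivity(wavelength_nm)


def pigment_sensitivity(lambda_max_nm: float, name: str | None = None) -> OpsinTemplate:
    """A1 nomogram template for a pigment peaking at ``lambda_max_nm``."""
    if not 330.0 <= lambda_max_nm <= 600.0:
        raise ValueError(
            f"lambda_max {lambda_max_nm} nm outside nomogram validity [330, 600]"
        )
    peak = float(np.max(_a1_template(lambda_max_nm, _GRID)))
    if name is None:
        name = f"pigment-{lambda_max_nm:g}nm"
    return OpsinTemplate(name=name, lambda_max_nm=lambda_max_nm, _norm=peak)


def opsin_template(name: str) -> OpsinTemplate:
    """Template for a named mouse photopigment (S-opsin, M-opsin, rod, melanopsin)."""
    try:
        peak = OPSIN_PEAKS[name]
    except KeyError:
        raise KeyError(f"unknown opsin {name!r}; options: {sorted(OPSIN_PEAKS)}")
    return pigment_sensitivity(peak, name=name)


def lens_transmission(wavelength_nm) -> np.ndarray | float:
    """Synthetic mouse lens transmission curve (0-1), logistic in wavelength.

    A smooth stand-in for the tabulated murine lens transmission used by
    spectral toolboxes: high transmission through the visible range, rolling
    off in the UV but retaining substantial near-UV transmission (the mouse
    lens, unlike the human lens, passes much of the 350-400 nm band).
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    t = 1.0 / (1.0 + np.exp(-(wl - 340.0) / 12.0))
    if np.isscalar(wavelength_nm):
        return float(t)
    return t


def effective_log_photon_flux(
    spectrum: LEDSpectrum,
    irradiance_uw_cm2: float,
    opsin: OpsinTemplate,
    lens_correction: bool = True,
) -> float:
    """log10 opsin-effective photon flux [effective photons/cm^2/s].

    The spectral photon flux is weighted by the pigment sensitivity and,
    when ``lens_correction`` is on, by the lens transmission.  Always
    <= the total photon flux; returns -inf (with a warning) when the
    spectrum and pigment do not overlap.
    """
    if irradiance_uw_cm2 <= 0:
        raise ValueError("irradiance must be positive")

    def weighting(wl: np.ndarray) -> np.ndarray:
        w = (wl * 1e-9 / (_H * _C)) * opsin.sensitivity(wl)
        if lens_correction:
            w = w * lens_transmission(wl)
        return w

    eff_photons_per_joule = spectrum.weighted_integral(weighting)
    flux = irradiance_uw_cm2 * 1e-6 * eff_photons_per_joule
    if flux <= 0:
        warnings.warn(
            f"zero overlap between spectrum and {opsin.name}; returning -inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("-inf")
    return math.log10(flux)


def classify_light_regime(luminance_cd_m2: float) -> str:
    """scotopic < 0.001 <= mesopic <= 3 < transition <= 10 < photopic [cd/m^2]."""
    if luminance_cd_m2 < 0:
        raise ValueError("luminance must be >= 0")
    if luminance_cd_m2 < 0.001:
        return "scotopic"
    if luminance_cd_m2 <= 3.0:
        return "mesopic"
    if luminance_cd_m2 <= 10.0:
        return "transition"
    return "photopic"


def luminance_ratio(object_luminance: float, background_luminance: float) -> float:
    """Simple object/background luminance ratio (contrast-mode characterization)."""
    if background_luminance <= 0:
        raise ValueError("background luminance must be positive")
    return object_luminance / background_luminance


@dataclass(frozen=True)
class ArmStimulus:
    """Fully derived photometric/radiometric description of one arm's light."""

    arm: str
    ev: float | None
    illuminance_lux: float
    luminance_cd_m2: float
    irradiance_uw_cm2: float
    log_photon_flux: float
    effective_log_flux: Mapping[str, float]
    regime: str


@dataclass(frozen=True)
class LightCondition:
    """One named illumination condition: a stimulus per arm (or unlit)."""

    name: str
    arms: Mapping[str, ArmStimulus | None]  # None = unlit (NC condition)


def characterize_arm(
    arm: str,
    spectrum: LEDSpectrum,
    ev: float | None = None,
    lux: float | None = None,
    lens_correction: bool = True,
    opsins: tuple[str, ...] = ("S-opsin", "M-opsin", "rod", "melanopsin"),
) -> ArmStimulus:
    """Derive the full photometric/radiometric profile of one arm.

    Exactly one of ``ev`` or ``lux`` must be given; the other photometric
    quantities follow from the meter formulas, and the radiometric chain
    from the arm's LED spectrum.
    """
    if (ev is None) == (lux is None):
        raise ValueError("give exactly one of ev or lux")
    if ev is not None:
        lux = ev_to_illuminance(ev)
    else:
        ev = illuminance_to_ev(lux) if lux > 0 else None
    if lux < 0:
        raise ValueError("negative illuminance")
    luminance = lux / 20.0  # implied by the two meter formulas
    irradiance = illuminance_to_irradiance(lux, spectrum) if lux > 0 else 0.0
    if irradiance > 0:
        log_flux = irradiance_to_log_photon_flux(irradiance, spectrum)
        eff = {
            o: effective_log_photon_flux(
                spectrum, irradiance, opsin_template(o), lens_correction
            )
            for o in opsins
        }
    else:
        log_flux = float("-inf")
        eff = {o: float("-inf") for o in opsins}
    return ArmStimulus(
        arm=arm,
        ev=ev,
        illuminance_lux=lux,
        luminance_cd_m2=luminance,
        irradiance_uw_cm2=irradiance,
        log_photon_flux=log_flux,
        effective_log_flux=eff,
        regime=classify_light_regime(luminance),
    )
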