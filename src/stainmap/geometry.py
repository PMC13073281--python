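"""Scan geometry for modulation-based imaging.

The beam passes a periodic phase modulator, the sample a distance ``l``
downstream, and reaches the detector a further ``delta_m`` downstream.
The quantitative chain uses parallel-beam geometry; magnification enters
only through the effective pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import wavelength_nm

__all__ = ["ScanGeometry", "ratio_cm_to_px2"]


@dataclass(frozen=True)
class ScanGeometry:
    """Beamline geometry and sampling.

    Attributes
    ----------
    energy_kev : photon energy in keV
    source_to_modulator_m : source-modulator distance s (m)
    modulator_to_sample_m : modulator-sample distance l (m)
    sample_to_detector_m : propagation distance Delta (m)
    detector_pixel_um : pixel pitch p at the detector face (µm)
    magnification : optical magnification (effective = p / magnification)

    Defaults reflect a bending-magnet micro-CT setup: 25 keV, a silicon
    Talbot array illuminator 21.3 m from the source, sample 0.19 m
    behind the modulator, detector 0.16 m behind the sample, 1.44 µm
    pixels.  The simulator works on the effective-pixel grid, so the
    default magnification is 1.
    """

    energy_kev: float = 25.0
    source_to_modulator_m: float = 21.3
    modulator_to_sample_m: float = 0.19
    sample_to_detector_m: float = 0.16
    detector_pixel_um: float = 1.44
    magnification: float = 1.0

    def __post_init__(self):
        if self.energy_kev <= 0:
            raise ValueError("energy must be positive")
        for d in (
            self.source_to_modulator_m,
            self.modulator_to_sample_m,
            self.sample_to_detector_m,
        ):
            if d < 0:
                raise ValueError("distances must be non-negative")
        if self.detector_pixel_um <= 0 or self.magnification <= 0:
            raise ValueError("pixel pitch and magnification must be positive")

    @property
    def wavelength_nm(self) -> float:
        return wavelength_nm(self.energy_kev)

    @property
    def effective_pixel_um(self) -> float:
        return self.detector_pixel_um / self.magnification

    @property
    def displacement_to_phase_gradient(self) -> float:
        """Factor converting a pattern displacement in pixels into a
        phase gradient in rad per (effective) pixel.

        d(phi)/d(pixel) = (2 pi / lambda) * (u * p / Delta) * p_eff
        """
        lam_m = self.wavelength_nm * 1e-9
        p_m = self.detector_pixel_um * 1e-6
        p_eff_m = self.effective_pixel_um * 1e-6
        if self.sample_to_detector_m == 0:
            raise ZeroDivisionError("sample-to-detector distance is zero")
        return 2.0 * 3.141592653589793 / lam_m * p_m / self.sample_to_detector_m * p_eff_m


def ratio_cm_to_px2(ratio_cm: float, geometry: ScanGeometry) -> float:
    """Convert a relative delta/mu ratio (cm) times Delta into effective
    pixel-squared units: the dimensionless filter strength
    (delta/mu)_rel * Delta / p_eff^2 used with grid frequencies in
    rad/pixel."""
    p_eff_m = geometry.effective_pixel_um * 1e-6
    return ratio_cm * 1e-2 * geometry.sample_to_detector_m / p_eff_m**2
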