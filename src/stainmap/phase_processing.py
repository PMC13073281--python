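"""Phase integration, electron-density conversion and calibration.

The tracker yields the two transverse phase gradients (phi_x, phi_y).
They are combined into the phase map by 2D Fourier integration,

    phi = Re F^-1[ F(phi_x + i phi_y) / (i kx - ky) ],

with the undefined DC term set to zero; the physical offset is restored
by defining the phase of the air surrounding the object to be zero.
The projected electron density follows as

    rho_e_perp = -phi / (lambda * r_e)      [1/nm^2],

and, after tomographic reconstruction, residual scale errors are
removed by an affine calibration that pins the air background to zero
and a reference material (PMMA by default, paraffin also in use) to
its theoretical electron density.

Gradients are mirror-extended with the correct parity (odd along the
differentiated axis, even along the other) before the FFT, which
suppresses periodic wrap-around streaks from non-periodic fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import R_E_NM

__all__ = [
    "CalibrationSpec",
    "integrate_gradients",
    "zero_reference",
    "projected_electron_density",
    "calibrate_volume",
]


def _mirror_gradient(g: np.ndarray, odd_axis: int) -> np.ndarray:
    """Mirror-extend a gradient field to twice the size.

    The extension is odd (sign-flipped) along the axis the gradient
    differentiates and even along the other, matching the symmetric
    extension of the underlying scalar field.
    """
    out = np.pad(g, ((0, g.shape[0]), (0, g.shape[1])), mode="symmetric")
    h, w = g.shape
    if odd_axis == 0:
        out[h:, :] *= -1.0
    else:
        out[:, w:] *= -1.0
    return out


def integrate_gradients(phi_x: np.ndarray, phi_y: np.ndarray, pad: bool = True) -> np.ndarray:
    """2D Fourier integration of the differential phase signals.

    ``phi_x`` and ``phi_y`` are the x- and y-derivatives of the phase in
    rad per pixel; the result is the phase in rad, defined up to an
    additive constant (DC set to zero; see :func:`zero_reference`).
    All-zero gradients integrate to a zero map.
    """
    gx = np.asarray(phi_x, dtype=float)
    gy = np.asarray(phi_y, dtype=float)
    if gx.shape != gy.shape or gx.ndim != 2:
        raise ValueError("gradient maps must be 2D arrays of one shape")
    if not (np.all(np.isfinite(gx)) and np.all(np.isfinite(gy))):
        raise ValueError("gradient maps must be finite")
    h, w = gx.shape
    if pad:
        gx_p = _mirror_gradient(gx, odd_axis=1)
        gy_p = _mirror_gradient(gy, odd_axis=0)
    else:
        gx_p, gy_p = gx, gy
    ky = 2.0 * np.pi * np.fft.fftfreq(gx_p.shape[0])
    kx = 2.0 * np.pi * np.fft.fftfreq(gx_p.shape[1])
    denom = 1j * kx[None, :] - ky[:, None]
    spec = np.fft.fft2(gx_p + 1j * gy_p)
    with np.errstate(divide="ignore", invalid="ignore"):
        spec = np.where(denom == 0, 0.0, spec / np.where(denom == 0, 1.0, denom))
    phi = np.fft.ifft2(spec).real
    return phi[:h, :w]


def zero_reference(phi: np.ndarray, air_mask: np.ndarray) -> np.ndarray:
    """Subtract the mean phase over an air region (exact zero mean there)."""
    mask = np.asarray(air_mask, dtype=bool)
    if not mask.any():
        raise ValueError("air region is empty")
    return phi - phi[mask].mean()


def projected_electron_density(phi: np.ndarray, wavelength_nm: float) -> np.ndarray:
    """rho_e_perp = -phi / (lambda r_e), elementwise, in 1/nm^2."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    return -np.asarray(phi, dtype=float) / (wavelength_nm * R_E_NM)


@dataclass
class CalibrationSpec:
    """Air-background and reference-material regions for rescaling.

    ``bg_mask`` and ``ref_mask`` are boolean voxel masks (disjoint,
    non-empty); ``rho_e_theo`` is the theoretical electron density of
    the reference material in 1/nm^3 (383 for PMMA).
    """

    bg_mask: np.ndarray
    ref_mask: np.ndarray
    rho_e_theo: float

    def __post_init__(self):
        self.bg_mask = np.asarray(self.bg_mask, dtype=bool)
        self.ref_mask = np.asarray(self.ref_mask, dtype=bool)
        if not self.bg_mask.any() or not self.ref_mask.any():
            raise ValueError("calibration regions must be non-empty")
        if (self.bg_mask & self.ref_mask).any():
            raise ValueError("calibration regions must be disjoint")


def calibrate_volume(rho_raw: np.ndarray, cal: CalibrationSpec) -> np.ndarray:
    """Affine rescaling pinning background to 0 and reference to theory.

    rho_cal = (rho_raw - mean_bg) / (mean_ref - mean_bg) * rho_e_theo.
    Exact at its two fixed points; raises on a degenerate calibration
    (equal region means).
    """
    raw = np.asarray(rho_raw, dtype=float)
    bg = raw[cal.bg_mask].mean()
    ref = raw[cal.ref_mask].mean()
    if ref == bg:
        raise ValueError("degenerate calibration: reference and background means equal")
    return (raw - bg) / (ref - bg) * cal.rho_e_theo
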