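"""Validation metrics: Fourier ring correlation, Bland-Altman, ROI stats."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "FRCResult",
    "fourier_ring_correlation",
    "BlandAltmanResult",
    "bland_altman",
    "roi_statistics",
]


@dataclass
class FRCResult:
    """FRC curve, threshold curve and the derived resolution."""

    frequency: np.ndarray  # ring centre frequencies, cycles/pixel
    frc: np.ndarray
    threshold: np.ndarray
    resolution_um: float
    at_nyquist: bool  # no crossing found: resolution limited by sampling


def _threshold_curve(n_per_ring: np.ndarray, criterion: str) -> np.ndarray:
    """Information-threshold curves (half-bit / full-bit) per ring."""
    sqn = np.sqrt(np.maximum(n_per_ring, 1.0))
    if criterion == "half_bit":
        return (0.2071 + 1.9102 / sqn) / (1.2071 + 0.9102 / sqn)
    if criterion == "full_bit":
        return (0.5 + 2.4142 / sqn) / (1.5 + 1.4142 / sqn)
    raise ValueError("criterion must be 'half_bit' or 'full_bit'")


def fourier_ring_correlation(
    slice_a: np.ndarray,
    slice_b: np.ndarray,
    pixel_um: float,
    criterion: str = "half_bit",
) -> FRCResult:
    """Spectral correlation of two independent images of one object.

    FRC(r) = |sum F_a conj(F_b)| / sqrt(sum |F_a|^2 sum |F_b|^2) over
    rings one frequency bin wide.  The resolution is the inverse of the
    frequency where the curve first drops below the chosen information
    threshold; if it never does, the sentinel resolution is the Nyquist
    period (2 pixels) and ``at_nyquist`` is set.
    """
    a = np.asarray(slice_a, dtype=float)
    b = np.asarray(slice_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("slices must be 2D arrays of one shape")
    fa = np.fft.fft2(a - a.mean())
    fb = np.fft.fft2(b - b.mean())
    fy = np.fft.fftfreq(a.shape[0])
    fx = np.fft.fftfreq(a.shape[1])
    r = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)  # cycles/pixel
    n_rings = min(a.shape) // 2
    ring = np.round(r * min(a.shape)).astype(int)
    ring_flat = ring.ravel()
    cross = np.bincount(ring_flat, weights=(fa * np.conj(fb)).real.ravel())
    cross_im = np.bincount(ring_flat, weights=(fa * np.conj(fb)).imag.ravel())
    pa = np.bincount(ring_flat, weights=np.abs(fa).ravel() ** 2)
    pb = np.bincount(ring_flat, weights=np.abs(fb).ravel() ** 2)
    count = np.bincount(ring_flat)
    sel = slice(1, n_rings)
    frc = np.abs(cross[sel] + 1j * cross_im[sel]) / np.sqrt(pa[sel] * pb[sel])
    freq = np.arange(1, n_rings) / min(a.shape)
    thr = _threshold_curve(count[sel].astype(float), criterion)

    below = frc < thr
    if not below.any():
        return FRCResult(freq, frc, thr, resolution_um=2.0 * pixel_um, at_nyquist=True)
    i = int(np.argmax(below))
    if i == 0:
        f_cross = freq[0]
    else:
        # linear interpolation of the (frc - threshold) zero crossing
        d0 = frc[i - 1] - thr[i - 1]
        d1 = frc[i] - thr[i]
        f_cross = freq[i - 1] + d0 / (d0 - d1) * (freq[i] - freq[i - 1])
    return FRCResult(freq, frc, thr, resolution_um=pixel_um / f_cross, at_nyquist=False)


@dataclass
class BlandAltmanResult:
    mean_difference: float
    loa_low: float  # lower 95% limit of agreement
    loa_high: float
    r: float  # Pearson correlation of the paired means
    p_value: float


def bland_altman(roi_means_a, roi_means_b) -> BlandAltmanResult:
    """Agreement between two methods from paired ROI means.

    Mean difference, 1.96-sigma limits of agreement, and the Pearson
    correlation (with p-value) of the paired values.
    """
    a = np.asarray(roi_means_a, dtype=float)
    b = np.asarray(roi_means_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equally long lists of at least 2 paired ROI means")
    diff = a - b
    md = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        r, p = 1.0 if np.allclose(a - a.mean(), b - b.mean()) else 0.0, float("nan")
    else:
        r, p = stats.pearsonr(a, b)
    return BlandAltmanResult(md, md - 1.96 * sd, md + 1.96 * sd, float(r), float(p))


def roi_statistics(
    volume: np.ndarray, rois: list[np.ndarray], erosion: int = 0
) -> list[dict]:
    """Per-ROI mean, standard deviation and voxel count.

    ``erosion`` > 0 erodes each mask by that many voxels first, the
    standard way to exclude values near material edges from the
    average.  An ROI that is empty (or erodes away) raises.
    """
    vol = np.asarray(volume)
    out = []
    for k, roi in enumerate(rois):
        mask = np.asarray(roi, dtype=bool)
        if mask.shape != vol.shape:
            raise ValueError(f"ROI {k} shape {mask.shape} != volume shape {vol.shape}")
        if erosion > 0:
            mask = ndimage.binary_erosion(mask, iterations=erosion)
        if not mask.any():
            raise ValueError(f"ROI {k} is empty (after erosion by {erosion})")
        vals = vol[mask]
        out.append(
            {"mean": float(vals.mean()), "std": float(vals.std()), "count": int(vals.size)}
        )
    return out
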