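"""Parallel-beam filtered backprojection and offset-axis stitching.

The built-in reconstructor is a plain ramp-filtered backprojection
(Ram-Lak filter by default, optional Hann apodization) with the
rotation axis vertical and at the central detector column.  It exists
so the whole pipeline runs with no optional backend; an established
library implementation can be substituted behind the same contract
(and serves as a cross-check in the test suite).

For samples wider than the detector, offset-rotation-axis scans cover
the full width over 360 degrees; opposing views are mirrored and
linearly blended across the overlap:

    stitched(x) = alpha(x) * view_f(x) + (1 - alpha(x)) * view_b(x)

with alpha falling linearly from 1 to 0 across the overlap columns.
For the x-differential phase signal the mirrored view's sign flips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StitchSpec",
    "blending_weights",
    "stitch_offset_projections",
    "fbp_reconstruct",
    "attenuation_to_optical_density",
]


@dataclass(frozen=True)
class StitchSpec:
    """Overlap description: first overlap column and overlap width (px)."""

    x_start: int
    overlap_width: int

    def __post_init__(self):
        if self.x_start < 0 or self.overlap_width < 1:
            raise ValueError("need x_start >= 0 and overlap_width >= 1")


def blending_weights(width: int, spec: StitchSpec) -> np.ndarray:
    """alpha(x) over ``width`` columns: 1 before the overlap, linear
    descent across it, 0 after."""
    if spec.x_start + spec.overlap_width > width:
        raise ValueError("overlap region exceeds image width")
    x = np.arange(width, dtype=float)
    alpha = 1.0 - (x - spec.x_start) / spec.overlap_width
    return np.clip(alpha, 0.0, 1.0)


def stitch_offset_projections(
    view_f: np.ndarray,
    view_b: np.ndarray,
    spec: StitchSpec,
    signal: str = "tau",
) -> np.ndarray:
    """Blend a view with its horizontally mirrored opposing view.

    ``view_f`` and ``view_b`` are projections of the same height taken
    180 degrees apart with the rotation axis offset toward the
    right-hand detector edge.  ``view_b`` is mirrored internally; for
    ``signal="phase_x"`` its sign is flipped as well.  The stitched
    frame is ``x_start + W`` columns wide: view_f occupies the left
    columns, the mirrored view_b the right columns, with the linear
    blend across ``[x_start, x_start + overlap_width)``.
    """
    if signal not in ("tau", "attenuation", "phase_x", "phase_y"):
        raise ValueError(f"unknown signal {signal!r}")
    f = np.asarray(view_f, dtype=float)
    b = np.asarray(view_b, dtype=float)
    if f.shape != b.shape or f.ndim != 2:
        raise ValueError("views must be 2D arrays of one shape")
    h, w = f.shape
    if spec.x_start + spec.overlap_width > w:
        raise ValueError("overlap region exceeds the view width")
    b = b[:, ::-1]
    if signal == "phase_x":
        b = -b
    out_w = spec.x_start + w
    alpha = blending_weights(out_w, spec)
    fa = np.zeros((h, out_w))
    ba = np.zeros((h, out_w))
    fa[:, :w] = f
    ba[:, spec.x_start :] = b
    # outside each view's footprint the other view carries full weight
    alpha_map = np.broadcast_to(alpha, (h, out_w)).copy()
    alpha_map[:, : spec.x_start] = 1.0
    alpha_map[:, w:] = 0.0
    return alpha_map * fa + (1.0 - alpha_map) * ba


def _ramp_filter(n_fft: int, apodization: str) -> np.ndarray:
    # frequency response of the discrete spatial-domain Ram-Lak kernel
    # (h[0] = 1/4, h[odd n] = -1/(pi n)^2); unlike a plain 2|f| ramp its
    # DC sample is non-zero, so projection means are not discarded and
    # homogeneous interiors reconstruct without a constant offset
    h = np.zeros(n_fft)
    h[0] = 0.25
    odd = np.arange(1, n_fft // 2, 2)
    h[odd] = -1.0 / (np.pi * odd) ** 2
    h[-odd] = -1.0 / (np.pi * odd) ** 2
    filt = 2.0 * np.real(np.fft.fft(h))
    if apodization == "hann":
        freq = np.fft.fftfreq(n_fft)
        filt *= 0.5 * (1.0 + np.cos(2.0 * np.pi * freq))
    elif apodization != "ramlak":
        raise ValueError("apodization must be 'ramlak' or 'hann'")
    return filt


def fbp_reconstruct(
    projections: np.ndarray,
    angles_rad: np.ndarray,
    voxel_um: float,
    signal: str | None = None,
    apodization: str = "ramlak",
) -> np.ndarray:
    """Ram-Lak filtered backprojection of a projection stack.

    Parameters
    ----------
    projections : (n_angles, H, W) line-integral stack in per-voxel
        units (each value = sum of the voxel quantity along the ray).
        For attenuation pass -ln(tau'); for electron density pass the
        projected density map converted to per-voxel units upstream or
        use ``signal`` to rescale (see below).
    angles_rad : projection angles.
    voxel_um : voxel edge length, µm.
    signal : if ``"attenuation"`` the input is interpreted as
        -ln tau = integral mu dz (dimensionless) and the output is
        rescaled to 1/cm; if ``"electron_density"`` the input is
        rho_e_perp in 1/nm^2 and the output is rescaled to 1/nm^3;
        ``None`` performs no unit rescaling (per-voxel units in/out).
    Returns
    -------
    volume : (H, W, W) array; axis order (y, x, z) matching the
        simulator's phantom convention.
    """
    proj = np.asarray(projections, dtype=float)
    if proj.ndim != 3:
        raise ValueError("projections must be a (n_angles, H, W) stack")
    angles = np.asarray(angles_rad, dtype=float)
    if len(angles) != proj.shape[0] or len(angles) < 1:
        raise ValueError("need one angle per projection")
    n_ang, h, w = proj.shape

    n_fft = int(2 ** np.ceil(np.log2(max(64, 2 * w))))
    filt = _ramp_filter(n_fft, apodization)
    padded = np.zeros((n_ang, h, n_fft))
    padded[:, :, :w] = proj
    filtered = np.fft.ifft(np.fft.fft(padded, axis=2) * filt, axis=2).real[:, :, :w]

    c = (w - 1) / 2.0
    xi, zi = np.meshgrid(np.arange(w) - c, np.arange(w) - c, indexing="ij")
    volume = np.zeros((h, w, w), dtype=np.float64)
    for a, theta in enumerate(angles):
        # detector coordinate of voxel (x, z) after rotating the sample
        # by theta (matches the simulator's line-integral convention)
        t = xi * np.cos(theta) - zi * np.sin(theta) + c
        t0 = np.floor(t).astype(int)
        frac = t - t0
        t0c = np.clip(t0, 0, w - 1)
        t1c = np.clip(t0 + 1, 0, w - 1)
        inside = (t >= 0) & (t <= w - 1)
        sl = filtered[a]  # (h, w)
        contrib = sl[:, t0c.ravel()] * (1.0 - frac.ravel()) + sl[:, t1c.ravel()] * frac.ravel()
        contrib *= inside.ravel()
        volume += contrib.reshape(h, w, w)
    volume *= np.pi / (2.0 * n_ang)

    if signal == "attenuation":
        volume /= voxel_um * 1e-4  # per-voxel -> 1/cm
    elif signal == "electron_density":
        volume /= voxel_um * 1e3  # 1/nm^2 per voxel -> 1/nm^3
    elif signal is not None:
        raise ValueError("signal must be None, 'attenuation' or 'electron_density'")
    return volume


def attenuation_to_optical_density(mu_per_cm, voxel_um: float):
    """Unitless voxel optical density OD = mu * voxel size.

    Maps mu in [0, 14] 1/cm to OD in [0, 0.002] at a 1.44 µm voxel.
    """
    if voxel_um <= 0:
        raise ValueError("voxel size must be positive")
    return np.multiply(mu_per_cm, voxel_um * 1e-4)
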