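"""Signal retrieval from multi-position modulated frames.

A modulation-based scan records, for each modulator position i, a
sample frame I_i and a reference frame I0_i.  Two signals are pulled
out of such a set:

* the transmission ratio tau(x, y), obtained by averaging I_i/I0_i over
  modulator positions (the pattern cancels on average), and
* sub-pixel pattern displacements (ux, uy), obtained by a local
  least-squares tracker, which map to the transverse gradients of the
  X-ray phase via

      phi_x, phi_y = (2 pi / lambda) * (ux, uy) * p / Delta

  with p the detector pixel pitch and Delta the propagation distance.

The tracker is a windowed implementation of the explicit
pattern-tracking model: per pixel, minimise
sum_i sum_window [I_i - T * I0_i(x - ux, y - uy)]^2 over a discrete
displacement search with sub-pixel refinement (quadratic
interpolation followed by a Gauss-Newton polish on the continuous
cost).  It carries no dark-field channel and is validated against the
simulator round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import ScanGeometry

__all__ = [
    "ModulatedFrameSet",
    "RetrievedProjection",
    "average_transmission",
    "track_pattern",
    "displacements_to_angles",
]


@dataclass
class ModulatedFrameSet:
    """Per-modulator-position sample and reference frames (counts)."""

    sample: np.ndarray  # (n_positions, H, W)
    reference: np.ndarray  # (n_positions, H, W)
    geometry: ScanGeometry = field(default_factory=ScanGeometry)

    def __post_init__(self):
        self.sample = np.asarray(self.sample, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.sample.ndim != 3 or self.sample.shape != self.reference.shape:
            raise ValueError("sample and reference stacks must share one (n, H, W) shape")
        if self.sample.shape[0] < 1:
            raise ValueError("at least one modulator position is required")

    @property
    def n_positions(self) -> int:
        return self.sample.shape[0]


@dataclass
class RetrievedProjection:
    """Per-view retrieval output.

    ``tau`` is the plain intensity ratio (the logarithm is applied only
    when forming attenuation line integrals for reconstruction).
    ``ux, uy`` are pattern displacements in pixels; ``phi_x, phi_y`` the
    derived phase gradients in rad per effective pixel.  ``mask`` flags
    pixels where the tracking window stayed inside the image.
    """

    tau: np.ndarray
    ux: np.ndarray
    uy: np.ndarray
    phi_x: np.ndarray
    phi_y: np.ndarray
    mask: np.ndarray


def average_transmission(frames: ModulatedFrameSet, on_nonpositive: str = "raise") -> np.ndarray:
    """Transmission map tau = mean_i I_i / I0_i.

    Averaging (rather than summing) over modulator positions keeps
    tau ~ 1 in air for any number of positions.  Non-positive reference
    pixels either raise (default) or are masked to NaN
    (``on_nonpositive="mask"``).
    """
    ref = frames.reference
    bad = ref <= 0
    if bad.any():
        if on_nonpositive == "raise":
            raise ValueError(f"{int(bad.sum())} non-positive reference pixels")
        if on_nonpositive != "mask":
            raise ValueError("on_nonpositive must be 'raise' or 'mask'")
        ref = np.where(bad, np.nan, ref)
    return np.mean(frames.sample / ref, axis=0)


def _fourier_shift(img: np.ndarray, sy: float, sx: float) -> np.ndarray:
    """Sub-pixel shift via the Fourier shift theorem: out(x) = img(x - s)."""
    fy = np.fft.fftfreq(img.shape[0])[:, None]
    fx = np.fft.fftfreq(img.shape[1])[None, :]
    phase = np.exp(-2j * np.pi * (fy * sy + fx * sx))
    return np.fft.ifft2(np.fft.fft2(img) * phase).real


class PatternTracker:
    """Reusable windowed least-squares tracker for one reference stack.

    The displacement search runs on a regular grid of shifts with
    spacing ``step`` pixels covering ``[-search, search]`` in each
    direction (ties broken toward zero displacement), followed by
    three-point quadratic sub-pixel refinement of the cost surface
    along each axis, a Gauss-Newton polish on the continuous cost, and
    a per-pixel re-fit of the transmission (see ``_polish``).
    Sub-integer grid shifts of the reference use the Fourier shift
    theorem (unitary, so the pattern-energy normalisation is
    unbiased); since references do not change between projection
    angles of a scan, the shifted stacks and their window energies are
    precomputed once, which makes tracking a full tomographic series
    cheap.  ``tau_smooth_px`` sets the low-pass width applied to the
    displacement field for the final transmission fit.
    """

    def __init__(
        self,
        reference: np.ndarray,
        geometry: ScanGeometry,
        window: int = 1,
        search: float = 2.0,
        step: float = 0.5,
        tau_smooth_px: float = 1.5,
    ):
        if window < 0 or search < 0 or step <= 0:
            raise ValueError("window and search must be >= 0 and step > 0")
        reference = np.asarray(reference, dtype=float)
        if reference.ndim != 3 or reference.shape[0] < 2:
            raise ValueError("pattern tracking needs at least two modulator positions")
        if reference.std() == 0:
            raise ValueError("flat reference pattern: tracking problem is ill-posed")
        self.geometry = geometry
        self.window = window
        self.search = search
        self.step = step
        self._size = 2 * window + 1
        self.tau_smooth_px = tau_smooth_px
        self._reference = reference
        self._dref_dy = [np.gradient(r, axis=0) for r in reference]
        self._dref_dx = [np.gradient(r, axis=1) for r in reference]

        n_steps = int(round(search / step))
        grid = step * np.arange(-n_steps, n_steps + 1)
        shifts = [(sy, sx) for sy in grid for sx in grid]
        # stable tie-break toward zero displacement: visit small |s| first
        shifts.sort(key=lambda s: (abs(s[0]) + abs(s[1]), abs(s[0]), abs(s[1])))
        self.shifts = shifts
        self._index_of = {(round(sy, 6), round(sx, 6)): j for j, (sy, sx) in enumerate(shifts)}
        self._sy = np.asarray([s[0] for s in shifts])
        self._sx = np.asarray([s[1] for s in shifts])

        self._ref_shifted = []
        self._c_term = []
        for sy, sx in shifts:
            if sy == int(sy) and sx == int(sx):
                # integer shifts: exact replicate-padded sampling
                ref_s = np.stack(
                    [
                        ndimage.shift(r, (sy, sx), order=0, mode="nearest")
                        for r in reference
                    ]
                )
            else:
                # fractional shifts: Fourier shift — unitary, so the
                # pattern variance entering the normalisation term is
                # preserved exactly (interpolating kernels attenuate it
                # and would bias the fitted transmission)
                ref_s = np.stack([_fourier_shift(r, sy, sx) for r in reference])
            self._ref_shifted.append(ref_s)
            self._c_term.append(self._wsum(ref_s**2))

    def _polish(
        self, sam: np.ndarray, uy: np.ndarray, ux: np.ndarray, iterations: int = 2
    ):
        """Gauss-Newton refinement of (T, uy, ux) on the continuous cost.

        Each iteration warps the reference stack to the current
        displacement field (cubic-spline resampling), re-fits T in
        closed form, and takes one damped Newton step for (uy, ux)
        from the windowed normal equations.  Steps are clamped to half
        a grid step so the polish cannot leave the basin found by the
        discrete search.
        """
        h, w = sam.shape[1:]
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        clamp = self.step / 2.0
        uy = uy.astype(float).copy()
        ux = ux.astype(float).copy()
        flt = lambda img: ndimage.uniform_filter(img, size=self._size, mode="nearest")
        tau = None
        for it in range(iterations + 1):
            final = it == iterations
            if final:
                # pixel-to-pixel displacement noise rectifies into a
                # downward transmission bias (the warped pattern decor-
                # relates quadratically in the displacement error), so
                # the physically smooth displacement field is low-pass
                # filtered before the final fit
                uy_fit = ndimage.gaussian_filter(uy, self.tau_smooth_px)
                ux_fit = ndimage.gaussian_filter(ux, self.tau_smooth_px)
            else:
                uy_fit, ux_fit = uy, ux
            coords = np.stack([yy - uy_fit, xx - ux_fit])
            b = np.zeros((h, w))
            c = np.zeros((h, w))
            warped = []
            for i, r in enumerate(self._reference):
                r_w = ndimage.map_coordinates(r, coords, order=3, mode="nearest")
                warped.append(r_w)
                if final:
                    # final T: per-pixel fit over modulator positions
                    # only — the spatial window would re-introduce a
                    # bias where transmission or displacement curve
                    # within it
                    b += sam[i] * r_w
                    c += r_w * r_w
                else:
                    b += flt(sam[i] * r_w)
                    c += flt(r_w * r_w)
            tau = b / c
            if final:
                break
            a_yy = np.zeros((h, w)); a_yx = np.zeros((h, w)); a_xx = np.zeros((h, w))
            g_y = np.zeros((h, w)); g_x = np.zeros((h, w))
            for i, r_w in enumerate(warped):
                gy_i = ndimage.map_coordinates(self._dref_dy[i], coords, order=3, mode="nearest")
                gx_i = ndimage.map_coordinates(self._dref_dx[i], coords, order=3, mode="nearest")
                resid = sam[i] - tau * r_w
                # d resid / d u = +T * (d ref/d coordinate)
                g_y += flt(resid * tau * gy_i)
                g_x += flt(resid * tau * gx_i)
                a_yy += flt((tau * gy_i) ** 2)
                a_yx += flt(tau * tau * gy_i * gx_i)
                a_xx += flt((tau * gx_i) ** 2)
            det = a_yy * a_xx - a_yx * a_yx
            det = np.where(np.abs(det) < 1e-12, np.inf, det)
            dy = (a_xx * g_y - a_yx * g_x) / det
            dx = (a_yy * g_x - a_yx * g_y) / det
            uy -= np.clip(dy, -clamp, clamp)
            ux -= np.clip(dx, -clamp, clamp)
        return tau, uy, ux

    def _wsum(self, stack: np.ndarray) -> np.ndarray:
        acc = ndimage.uniform_filter(stack[0], size=self._size, mode="nearest")
        for frame in stack[1:]:
            acc = acc + ndimage.uniform_filter(frame, size=self._size, mode="nearest")
        return acc

    def track(self, sample: np.ndarray) -> RetrievedProjection:
        sam = np.asarray(sample, dtype=float)
        h, w = sam.shape[1:]
        n_sh = len(self.shifts)
        cost = np.empty((n_sh, h, w))
        t_of = np.empty_like(cost)
        a_term = self._wsum(sam**2)
        for j in range(n_sh):
            b = self._wsum(sam * self._ref_shifted[j])
            c = self._c_term[j]
            t_of[j] = b / c
            cost[j] = a_term - b * b / c

        best = np.zeros((h, w), dtype=int)
        best_cost = cost[0].copy()
        for j in range(1, n_sh):
            better = cost[j] < best_cost
            best_cost = np.where(better, cost[j], best_cost)
            best = np.where(better, j, best)

        uy = self._sy[best]
        ux = self._sx[best]
        tau = np.take_along_axis(t_of, best[None], axis=0)[0]

        # separable three-point quadratic refinement of the cost surface;
        # the transmission T is interpolated to the refined minimum as
        # well (T at the nearest grid shift is biased low by the
        # residual pattern mismatch)
        half = self.step / 2.0
        for axis in (0, 1):
            u_arr = uy if axis == 0 else ux
            for j, (sy, sx) in enumerate(self.shifts):
                if axis == 0:
                    sm, sp = (sy - self.step, sx), (sy + self.step, sx)
                else:
                    sm, sp = (sy, sx - self.step), (sy, sx + self.step)
                jm = self._index_of.get((round(sm[0], 6), round(sm[1], 6)), None)
                jp = self._index_of.get((round(sp[0], 6), round(sp[1], 6)), None)
                if jm is None or jp is None:
                    continue
                sel = best == j
                if not sel.any():
                    continue
                cm, c0, cp = cost[jm][sel], cost[j][sel], cost[jp][sel]
                denom = cm - 2.0 * c0 + cp
                du = np.where(
                    denom > 0,
                    self.step * 0.5 * (cm - cp) / np.where(denom == 0, 1.0, denom),
                    0.0,
                )
                u_arr[sel] += np.clip(du, -half, half)

        # polish the grid estimate on the continuous cost surface:
        # Gauss-Newton steps against spline-warped references remove
        # the residual bias tied to the search-grid period, and the
        # transmission is re-fitted at the converged displacement
        # (T at the nearest grid shift is biased low by the pattern
        # mismatch)
        tau, uy, ux = self._polish(sam, uy, ux)

        mask = np.zeros((h, w), dtype=bool)
        m = int(np.ceil(self.search)) + self.window
        if h > 2 * m and w > 2 * m:
            mask[m : h - m, m : w - m] = True

        g = self.geometry.displacement_to_phase_gradient
        return RetrievedProjection(
            tau=tau, ux=ux, uy=uy, phi_x=g * ux, phi_y=g * uy, mask=mask
        )


def track_pattern(
    frames: ModulatedFrameSet,
    window: int = 1,
    search: float = 2.0,
    step: float = 0.5,
) -> RetrievedProjection:
    """Windowed least-squares pattern tracking of one frame set.

    Per pixel, the local transmission T and the displacement (ux, uy)
    minimising ``sum_i sum_w [I_i - T I0_i(x-ux, y-uy)]^2`` are found
    by an exhaustive search over a shift grid of spacing ``step``
    covering ``[-search, search]^2`` (ties toward zero displacement)
    with quadratic sub-pixel refinement.  ``window`` is the half-width
    of the analysis window (window parameter 1 = effective 3x3).
    For tracking many views against one reference stack, build a
    :class:`PatternTracker` once and call ``track`` per view.
    """
    tracker = PatternTracker(
        frames.reference, frames.geometry, window=window, search=search, step=step
    )
    return tracker.track(frames.sample)


def displacements_to_angles(ux, uy, geometry: ScanGeometry):
    """Convert pixel displacements to phase-gradient maps.

    Returns (phi_x, phi_y) in rad per effective pixel:
    (2 pi / lambda) * u * p / Delta, with the grid spacing of the
    Fourier-integration stage (the effective pixel) absorbed, so that
    the downstream 2D integration can use frequencies in rad/pixel.
    Linear in (ux, uy); requires a non-zero propagation distance.
    """
    g = geometry.displacement_to_phase_gradient  # raises if Delta == 0
    return np.asarray(ux) * g, np.asarray(uy) * g
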