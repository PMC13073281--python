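"""Synthetic phantoms and forward simulation of modulation-based scans.

No raw beamline data ship with the package, so every downstream stage
is exercised against scenes generated here:

* a calibration phantom — an ethanol-filled cylinder holding POM, PVC,
  PMMA and PTFE rods (materials with known X-ray properties),
* a stained-kidney-like phantom — a soft-tissue ellipsoid in ethanol
  with seeded blob-shaped inclusions carrying a few-per-mille lead
  volume fraction (emulating nuclear uptake of a hematein-lead stain),
  an optional excess-stain rim, and a PMMA rod for electron-density
  calibration.

The forward model is parallel-beam: per projection angle the phantom's
mu and rho_e volumes are line-integrated, giving the exit-plane
transmission tau = exp(-integral mu dz) and phase
phi = -r_e * lambda * integral rho_e dz.  Propagation to the detector
is the finite-difference transport-of-intensity step
I(Delta) = [1 - (delta/mu) Delta Laplacian] I(0), which is what creates
the edge artifact the correction filter later removes.  The modulator
is rendered as an intensity pattern at the detector plane (not
wave-propagated from the mask): the pipeline only tracks pattern
distortions, so a high-contrast periodic (or speckle) intensity
pattern is sufficient.  Refraction shifts the pattern locally by
(ux, uy) pixels obtained by inverting the displacement-to-phase-
gradient relation; the periodic pattern is evaluated analytically at
the displaced coordinates, avoiding interpolation bias.  Photon noise
is Poisson with a configurable mean count and mandatory seed.

Simplifications versus real data (documented, deliberate): no partial
coherence, no detector point-spread function beyond optional Gaussian
blur of the pattern, no Fresnel wave optics, intensity conservation is
exact on the periodic grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import ScanGeometry, ratio_cm_to_px2
from .materials import MaterialProperties, get_material, material_from_values, soft_tissue
from .retrieval import ModulatedFrameSet

__all__ = [
    "PhantomSpec",
    "ModulatorSpec",
    "ExitWave",
    "build_calibration_phantom",
    "build_stained_tissue_phantom",
    "phantom_volumes",
    "project_phantom",
    "propagate_tie",
    "modulator_pattern",
    "render_modulated_frames",
]

_GOLDEN = (1.0 + 5.0**0.5) / 2.0


@dataclass
class PhantomSpec:
    """Voxelised two-component scene.

    ``labels`` assigns each voxel a background material index;
    ``fraction`` is the volume fraction of the stain replacing that
    material (0 everywhere for unstained phantoms).  Axes are
    (y, x, z): y is the vertical rotation axis, the beam runs along z.
    """

    labels: np.ndarray
    fraction: np.ndarray
    voxel_um: float
    material_names: dict[int, str]
    stain_name: str | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.labels.shape != self.fraction.shape or self.labels.ndim != 3:
            raise ValueError("labels and fraction must be 3D arrays of one shape")
        if self.fraction.min() < 0 or self.fraction.max() > 1:
            raise ValueError("fraction map must lie in [0, 1]")
        unknown = set(np.unique(self.labels)) - set(self.material_names)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} have no material assigned")

    def materials_at(self, energy_kev: float) -> dict[int, MaterialProperties]:
        """Resolve the label -> material map at one energy."""
        out = {}
        for idx, name in self.material_names.items():
            if name == "air":
                out[idx] = material_from_values("air", energy_kev, mu=0.0, rho_e=0.0)
            elif name == "soft_tissue":
                out[idx] = soft_tissue(energy_kev)
            else:
                out[idx] = get_material(name, energy_kev)
        return out

    def stain_at(self, energy_kev: float) -> MaterialProperties | None:
        if self.stain_name is None:
            return None
        return get_material(self.stain_name, energy_kev)


@dataclass
class ModulatorSpec:
    """Periodic (Talbot-array-illuminator-like) or speckle modulator.

    ``offsets_um`` holds one transverse (x, y) pattern offset per
    modulator position; the default is a low-discrepancy golden-ratio
    sequence of ``n_positions`` distinct offsets within one period.
    """

    kind: str = "tai"  # "tai" | "speckle"
    period_um: float = 10.0
    phase_shift: float = 2.0 * np.pi / 3.0
    # measured pattern visibility at the detector; Talbot self-images
    # of a 2pi/3 mask are high-contrast in theory but detector blur
    # brings realised visibility to a few tens of percent
    contrast: float = 0.4
    n_positions: int = 9
    offsets_um: np.ndarray | None = None
    seed: int = 0  # speckle realisation only

    def __post_init__(self):
        if self.n_positions < 1:
            raise ValueError("need at least one modulator position")
        if self.kind not in ("tai", "speckle"):
            raise ValueError("modulator kind must be 'tai' or 'speckle'")
        if self.offsets_um is None:
            i = np.arange(self.n_positions)
            self.offsets_um = np.stack(
                [
                    (i * self.period_um / _GOLDEN) % self.period_um,
                    (i * self.period_um / _GOLDEN**2) % self.period_um,
                ],
                axis=1,
            )
        self.offsets_um = np.asarray(self.offsets_um, dtype=float)
        if len(np.unique(self.offsets_um, axis=0)) != self.n_positions:
            raise ValueError("modulator position offsets must be distinct")


@dataclass
class ExitWave:
    """Exit-plane transmission ratio and phase map (rad)."""

    tau: np.ndarray
    phi: np.ndarray
    pixel_um: float

    def __post_init__(self):
        self.tau = np.asarray(self.tau, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.tau.shape != self.phi.shape:
            raise ValueError("tau and phi must share one shape")
        if not np.all(self.tau > 0):
            raise ValueError("transmission must be strictly positive")
        if not np.all(np.isfinite(self.phi)):
            raise ValueError("phase map must be finite")


def _cylinder_mask(n: int, cy: float, cx: float, radius: float) -> np.ndarray:
    y, x = np.mgrid[0:n, 0:n]
    return (y - cy) ** 2 + (x - cx) ** 2 <= radius**2


def build_calibration_phantom(
    n: int = 128,
    voxel_um: float = 1.44,
    container_radius_frac: float = 0.44,
    rod_radius_frac: float = 0.11,
    rod_offset_frac: float = 0.24,
    rod_materials: tuple[str, ...] = ("POM", "PVC", "PMMA", "PTFE"),
) -> PhantomSpec:
    """Multi-material cylinder phantom: polymer rods in ethanol.

    Deterministic given its parameters.  Labels: 0 air, 1 ethanol,
    2.. one per rod.  Rods sit on the diagonals at ``rod_offset_frac``
    of the grid size from the centre; a rod that would cross the
    container wall raises a layout error.
    """
    if rod_offset_frac * n + rod_radius_frac * n > container_radius_frac * n:
        raise ValueError("rod layout overlaps the container boundary")
    c = (n - 1) / 2.0
    labels = np.zeros((n, n), dtype=np.uint8)
    labels[_cylinder_mask(n, c, c, container_radius_frac * n)] = 1
    names = {0: "air", 1: "ethanol"}
    d = rod_offset_frac * n / np.sqrt(2.0)
    corners = [(-d, -d), (-d, d), (d, -d), (d, d)]
    for k, mat in enumerate(rod_materials):
        dy, dx = corners[k % 4]
        if rod_radius_frac > 0:
            labels[_cylinder_mask(n, c + dy, c + dx, rod_radius_frac * n)] = 2 + k
        names[2 + k] = mat
    # axis 0 (y) is vertical: the cross-section is constant along y
    labels3 = np.broadcast_to(labels, (n, n, n)).copy()
    return PhantomSpec(
        labels=labels3,
        fraction=np.zeros((n, n, n), dtype=np.float32),
        voxel_um=voxel_um,
        material_names=names,
    )


def build_stained_tissue_phantom(
    seed: int,
    n: int = 128,
    voxel_um: float = 1.44,
    n_nuclei: int = 100,
    lead_fraction_range: tuple[float, float] = (0.0, 0.013),
    rim: bool = False,
    rim_fraction: float | None = None,
    blob_radius_px: float = 4.0,
    include_calibration_rod: bool = True,
) -> PhantomSpec:
    """Stained-kidney-like phantom, reproducible for a fixed seed.

    A soft-tissue ellipsoid in ethanol carries ``n_nuclei`` randomly
    placed spherical blob inclusions whose lead volume fractions are
    drawn uniformly from ``lead_fraction_range``; physiological stain
    levels cap the upper bound at 0.05.  The default blob radius
    (4 voxels, ~12 µm diameter at the default voxel size) models
    stained nuclear clusters large enough that their interiors are
    resolved at the pipeline's few-micrometre resolution; pass
    ``blob_radius_px~2.5`` for single-nucleus-scale features at the
    resolution limit.  ``rim=True`` adds a high-fraction shell at the
    tissue boundary, emulating excess stain not removed in the washing
    step.  A PMMA rod (label 3) is placed in the ethanol for
    electron-density calibration.
    """
    lo, hi = lead_fraction_range
    if not 0.0 <= lo <= hi:
        raise ValueError("lead_fraction_range must satisfy 0 <= lo <= hi")
    if hi > 0.05:
        raise ValueError("lead fractions above 0.05 are not physiological stain levels")
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be non-negative")
    rng = np.random.default_rng(seed)
    c = (n - 1) / 2.0
    y, x, z = np.mgrid[0:n, 0:n, 0:n].astype(float)

    labels = np.zeros((n, n, n), dtype=np.uint8)
    container = (x - c) ** 2 + (z - c) ** 2 <= (0.46 * n) ** 2
    labels[container] = 1

    axes = np.array([0.34, 0.26, 0.30]) * n  # (y, x, z) semi-axes
    centre = np.array([c, c - 0.08 * n, c])
    r2 = (
        ((y - centre[0]) / axes[0]) ** 2
        + ((x - centre[1]) / axes[1]) ** 2
        + ((z - centre[2]) / axes[2]) ** 2
    )
    tissue = (r2 <= 1.0) & container
    labels[tissue] = 2
    names = {0: "air", 1: "ethanol", 2: "soft_tissue"}

    if include_calibration_rod:
        rod = ((x - (c + 0.33 * n)) ** 2 + (z - c) ** 2 <= (0.08 * n) ** 2) & container
        rod &= labels != 2
        labels[rod] = 3
        names[3] = "PMMA"

    fraction = np.zeros((n, n, n), dtype=np.float32)
    if n_nuclei > 0:
        # rejection-sample blob centres well inside the tissue ellipsoid
        placed = 0
        while placed < n_nuclei:
            cand = centre + (rng.random(3) * 2.0 - 1.0) * axes * 0.85
            rr2 = float(np.sum(((cand - centre) / (0.85 * axes)) ** 2))
            if rr2 > 1.0:
                continue
            radius = max(1.5, rng.normal(blob_radius_px, 0.5))
            frac = rng.uniform(lo, hi)
            d2 = (
                (y - cand[0]) ** 2 + (x - cand[1]) ** 2 + (z - cand[2]) ** 2
            )
            fraction[(d2 <= radius**2) & tissue] = frac
            placed += 1
    if rim:
        shell = tissue & ~(r2 <= 0.90)
        fraction[shell] = rim_fraction if rim_fraction is not None else min(1.5 * hi, 0.05)
    if fraction.any():
        fraction = ndimage.gaussian_filter(fraction, sigma=0.6)
        fraction[~tissue] = 0.0
    return PhantomSpec(
        labels=labels,
        fraction=fraction,
        voxel_um=voxel_um,
        material_names=names,
        stain_name="lead",
    )


def phantom_volumes(
    phantom: PhantomSpec, energy_kev: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel (mu [1/cm], rho_e [1/nm^3]) volumes at one energy.

    Voxels mix the stain into the labelled background material with the
    local volume fraction f: property = (1-f)*background + f*stain.
    """
    mats = phantom.materials_at(energy_kev)
    stain = phantom.stain_at(energy_kev)
    mu = np.zeros(phantom.labels.shape, dtype=np.float32)
    rho = np.zeros(phantom.labels.shape, dtype=np.float32)
    for idx, m in mats.items():
        sel = phantom.labels == idx
        mu[sel] = m.mu
        rho[sel] = m.rho_e
    if stain is not None and phantom.fraction.any():
        f = phantom.fraction
        mu = (1.0 - f) * mu + f * stain.mu
        rho = (1.0 - f) * rho + f * stain.rho_e
    return np.asarray(mu, dtype=np.float32), np.asarray(rho, dtype=np.float32)


def _line_integral(volume: np.ndarray, angle_rad: float) -> np.ndarray:
    """Parallel-beam line integral along z after rotating about y.

    Output units: (volume units) * voxel, to be scaled by the caller.
    """
    if angle_rad == 0.0:
        rot = volume
    else:
        rot = ndimage.rotate(
            volume,
            np.degrees(angle_rad),
            axes=(1, 2),
            reshape=False,
            order=1,
            mode="constant",
            cval=0.0,
        )
    return rot.sum(axis=2)


def project_phantom(
    phantom: PhantomSpec,
    angle_rad: float,
    geometry: ScanGeometry,
    volumes: tuple[np.ndarray, np.ndarray] | None = None,
) -> ExitWave:
    """Exit wave for one projection angle.

    tau = exp(-integral mu dz), phi = -r_e lambda integral rho_e dz.
    ``volumes`` may carry precomputed (mu, rho_e) volumes so that a scan
    over many angles resolves materials only once.
    """
    from .constants import R_E_NM

    mu_vol, rho_vol = (
        volumes if volumes is not None else phantom_volumes(phantom, geometry.energy_kev)
    )
    dz_cm = phantom.voxel_um * 1e-4
    dz_nm = phantom.voxel_um * 1e3
    mu_proj = _line_integral(mu_vol, angle_rad) * dz_cm  # dimensionless
    rho_proj = _line_integral(rho_vol, angle_rad) * dz_nm  # 1/nm^2
    tau = np.exp(-mu_proj)
    phi = -R_E_NM * geometry.wavelength_nm * rho_proj
    return ExitWave(tau=tau, phi=phi, pixel_um=phantom.voxel_um)


def propagate_tie(
    intensity: np.ndarray,
    geometry: ScanGeometry,
    ratio_cm: float,
    method: str = "fourier",
) -> np.ndarray:
    """Finite-difference transport-of-intensity propagation.

    I(Delta) = [1 - (delta/mu) * Delta * Laplacian] I(0), with the
    Laplacian either spectral (periodic, conserves total intensity
    exactly) or a 5-point stencil with replicate boundaries.
    """
    img = np.asarray(intensity, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("non-finite intensity input")
    a = ratio_cm_to_px2(ratio_cm, geometry)  # (delta/mu) Delta in px^2
    if a == 0.0:
        return img.copy()
    if method == "fourier":
        ky = 2.0 * np.pi * np.fft.fftfreq(img.shape[0])
        kx = 2.0 * np.pi * np.fft.fftfreq(img.shape[1])
        k2 = ky[:, None] ** 2 + kx[None, :] ** 2
        return np.fft.ifft2(np.fft.fft2(img) * (1.0 + a * k2)).real
    if method == "stencil":
        lap = (
            np.pad(img, 1, mode="edge")[:-2, 1:-1]
            + np.pad(img, 1, mode="edge")[2:, 1:-1]
            + np.pad(img, 1, mode="edge")[1:-1, :-2]
            + np.pad(img, 1, mode="edge")[1:-1, 2:]
            - 4.0 * img
        )
        return img - a * lap
    raise ValueError("method must be 'fourier' or 'stencil'")


def modulator_pattern(
    modulator: ModulatorSpec,
    geometry: ScanGeometry,
    shape: tuple[int, int],
    position: int,
    ux: np.ndarray | None = None,
    uy: np.ndarray | None = None,
) -> np.ndarray:
    """Modulator intensity pattern at the detector, optionally warped.

    (ux, uy) are displacement maps in pixels; the pattern is evaluated
    at the displaced coordinates, i.e. positive ux moves pattern
    features toward +x.  The periodic pattern is analytic, so warping is
    exact; speckle patterns are warped by cubic-spline interpolation of
    a band-limited random field.
    """
    p_eff = geometry.effective_pixel_um
    if modulator.period_um / p_eff < 3.0:
        raise ValueError("modulator period must span at least 3 effective pixels")
    h, w = shape
    ox, oy = modulator.offsets_um[position]
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    if ux is not None:
        xx = xx - ux
    if uy is not None:
        yy = yy - uy
    if modulator.kind == "tai":
        tx = 2.0 * np.pi * (xx * p_eff - ox) / modulator.period_um
        ty = 2.0 * np.pi * (yy * p_eff - oy) / modulator.period_um
        return 1.0 + modulator.contrast * np.cos(tx) * np.cos(ty)
    # speckle: fixed band-limited field, shifted per position then warped
    rng = np.random.default_rng(modulator.seed)
    base = rng.random((h, w))
    sigma = modulator.period_um / (2.355 * p_eff)
    base = ndimage.gaussian_filter(base, sigma, mode="wrap")
    base = 1.0 + modulator.contrast * (base - base.mean()) / (np.abs(base - base.mean()).max())
    coords = np.stack([yy - oy / p_eff, xx - ox / p_eff])
    return ndimage.map_coordinates(base, coords, order=3, mode="mirror")


def render_modulated_frames(
    exit_wave: ExitWave,
    modulator: ModulatorSpec,
    geometry: ScanGeometry,
    ratio_cm: float = 0.0,
    noise_counts: float | None = None,
    seed: int | None = None,
    reference: np.ndarray | None = None,
    psf_sigma_px: float = 0.7,
) -> ModulatedFrameSet:
    """Forward-render one view into per-position sample/reference frames.

    Chain per modulator position: the reference frame is the pattern;
    the sample frame is the transport-of-intensity-propagated
    transmission (edge term controlled by ``ratio_cm``) times the
    pattern locally shifted by the refraction displacements implied by
    the exit-plane phase.  Poisson noise at ``noise_counts`` mean counts
    per pixel is applied to sample and reference frames alike and
    requires a seed.

    A tomographic scan measures the reference frames once per modulator
    position, not once per angle; pass ``reference`` (an already
    rendered, possibly noisy (n_positions, H, W) stack) to reuse it —
    noise is then applied to the sample frames only.

    ``psf_sigma_px`` applies a Gaussian blur to the sample-induced
    structure (transmission and phase) before rendering, emulating the
    finite detector point-spread function and source size: real optics
    never deliver voxel-sharp edges, and sub-pixel blur keeps interface
    refraction within the regime explicit tracking can follow.  Set 0
    to disable.
    """
    if noise_counts is not None and seed is None:
        raise ValueError("a seed is mandatory when photon noise is enabled")
    tau_exit, phi_exit = exit_wave.tau, exit_wave.phi
    if psf_sigma_px > 0:
        tau_exit = ndimage.gaussian_filter(tau_exit, psf_sigma_px)
        phi_exit = ndimage.gaussian_filter(phi_exit, psf_sigma_px)
    tau_prop = (
        propagate_tie(tau_exit, geometry, ratio_cm) if ratio_cm else tau_exit
    )
    gy, gx = np.gradient(phi_exit)  # rad per pixel
    g = geometry.displacement_to_phase_gradient
    ux, uy = gx / g, gy / g
    shape = exit_wave.tau.shape
    sample = np.empty((modulator.n_positions, *shape))
    own_reference = reference is None
    if own_reference:
        reference = np.empty_like(sample)
    for i in range(modulator.n_positions):
        if own_reference:
            reference[i] = modulator_pattern(modulator, geometry, shape, i)
        warped = modulator_pattern(modulator, geometry, shape, i, ux=ux, uy=uy)
        sample[i] = tau_prop * warped
    if noise_counts is not None:
        rng = np.random.default_rng(seed)
        sample = rng.poisson(np.clip(sample, 0, None) * noise_counts) / noise_counts
        if own_reference:
            reference = rng.poisson(reference * noise_counts) / noise_counts
    return ModulatedFrameSet(sample=sample, reference=reference, geometry=geometry)
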