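"""Phantom construction and forward simulation."""

import numpy as np
import pytest

from stainmap.geometry import ScanGeometry, ratio_cm_to_px2
from stainmap.materials import get_material
from stainmap.retrieval import average_transmission
from stainmap.synthetic import (
    ExitWave,
    ModulatorSpec,
    PhantomSpec,
    build_calibration_phantom,
    build_stained_tissue_phantom,
    modulator_pattern,
    phantom_volumes,
    project_phantom,
    propagate_tie,
    render_modulated_frames,
)


class TestCalibrationPhantom:
    def test_six_labels(self):
        ph = build_calibration_phantom(n=48)
        assert set(np.unique(ph.labels)) == {0, 1, 2, 3, 4, 5}

    def test_zero_radius_rod_absent(self):
        ph = build_calibration_phantom(n=48, rod_radius_frac=0.0)
        assert set(np.unique(ph.labels)) == {0, 1}

    def test_voxel_count_conserved(self):
        ph = build_calibration_phantom(n=32)
        counts = np.bincount(ph.labels.ravel())
        assert counts.sum() == 32**3

    def test_overlapping_layout_rejected(self):
        with pytest.raises(ValueError, match="layout|boundary"):
            build_calibration_phantom(n=48, rod_offset_frac=0.4, rod_radius_frac=0.2)

    def test_deterministic(self):
        a = build_calibration_phantom(n=32)
        b = build_calibration_phantom(n=32)
        assert np.array_equal(a.labels, b.labels)


class TestStainedTissuePhantom:
    def test_seed_reproducibility(self):
        a = build_stained_tissue_phantom(seed=5, n=48)
        b = build_stained_tissue_phantom(seed=5, n=48)
        assert np.array_equal(a.fraction, b.fraction)
        assert not np.array_equal(
            a.fraction, build_stained_tissue_phantom(seed=6, n=48).fraction
        )

    def test_no_nuclei_no_rim_is_unstained(self):
        ph = build_stained_tissue_phantom(seed=1, n=48, n_nuclei=0, rim=False)
        assert not ph.fraction.any()

    def test_blob_fractions_within_range(self):
        lo, hi = 0.002, 0.013
        ph = build_stained_tissue_phantom(seed=3, n=48, lead_fraction_range=(lo, hi))
        blobs = ph.fraction[ph.fraction > 0]
        assert blobs.size > 0
        assert blobs.max() <= hi + 1e-9
        interior = ph.fraction[ph.fraction > 0.5 * lo]
        assert lo * 0.5 <= interior.mean() <= hi

    def test_rim_adds_fraction_at_boundary(self):
        ph = build_stained_tissue_phantom(seed=3, n=48, n_nuclei=0, rim=True)
        assert ph.fraction.max() > 0

    def test_unphysiological_fraction_rejected(self):
        with pytest.raises(ValueError, match="physiological"):
            build_stained_tissue_phantom(seed=1, n=32, lead_fraction_range=(0.0, 0.2))
        with pytest.raises(ValueError):
            build_stained_tissue_phantom(seed=1, n=32, n_nuclei=-1)


class TestProjection:
    def test_empty_phantom(self, geometry):
        labels = np.zeros((16, 16, 16), dtype=np.uint8)
        ph = PhantomSpec(labels, np.zeros_like(labels, dtype=float), 1.44, {0: "air"})
        ew = project_phantom(ph, 0.0, geometry)
        assert np.allclose(ew.tau, 1.0)
        assert np.allclose(ew.phi, 0.0)

    def test_uniform_slab_closed_form(self, geometry):
        labels = np.zeros((8, 16, 16), dtype=np.uint8)
        labels[:, :, 4:12] = 1  # slab 8 voxels thick along the beam
        ph = PhantomSpec(labels, np.zeros_like(labels, dtype=float), 1.44, {0: "air", 1: "water"})
        ew = project_phantom(ph, 0.0, geometry)
        mu = get_material("water", geometry.energy_kev).mu
        expected = np.exp(-mu * 8 * 1.44e-4)
        assert ew.tau[4, 8] == pytest.approx(expected, abs=1e-6)

    def test_cylinder_chord_oracle(self, geometry):
        n = 64
        labels = np.zeros((4, n, n), dtype=np.uint8)
        y, x, z = np.mgrid[0:4, 0:n, 0:n]
        c = (n - 1) / 2
        r = 20.0
        labels[((x - c) ** 2 + (z - c) ** 2) <= r**2] = 1
        ph = PhantomSpec(labels, np.zeros_like(labels, dtype=float), 1.44, {0: "air", 1: "water"})
        ew = project_phantom(ph, 0.0, geometry)
        rho_e = get_material("water", geometry.energy_kev).rho_e
        from stainmap.constants import R_E_NM

        rho_perp = -ew.phi[2] / (geometry.wavelength_nm * R_E_NM)
        # compare against 2*sqrt(r^2-d^2)*rho_e on interior chords
        cols = np.arange(n)
        d = np.abs(cols - c)
        sel = d < 0.7 * r
        expected = 2.0 * np.sqrt(r**2 - d[sel] ** 2) * 1.44e3 * rho_e
        assert np.abs(rho_perp[sel] / expected - 1).mean() < 0.02

    def test_mixture_linearity(self, geometry):
        labels = np.ones((8, 12, 12), dtype=np.uint8)
        f = np.full(labels.shape, 0.3, dtype=float)
        ph_mix = PhantomSpec(labels, f, 1.44, {1: "soft_tissue"}, stain_name="lead")
        mu_mix, rho_mix = phantom_volumes(ph_mix, 25.0)
        ph_t = PhantomSpec(labels, np.zeros_like(f), 1.44, {1: "soft_tissue"})
        mu_t, rho_t = phantom_volumes(ph_t, 25.0)
        lead = get_material("lead", 25.0)
        assert np.allclose(mu_mix, 0.7 * mu_t + 0.3 * lead.mu, rtol=1e-6)
        assert np.allclose(rho_mix, 0.7 * rho_t + 0.3 * lead.rho_e, rtol=1e-6)


class TestPropagateTie:
    def test_zero_distance_identity(self, geometry):
        img = np.random.default_rng(0).random((32, 32)) + 0.5
        from dataclasses import replace

        g0 = replace(geometry, sample_to_detector_m=0.0)
        assert np.array_equal(propagate_tie(img, g0, 1e-8), img)

    def test_uniform_unchanged(self, geometry):
        img = np.full((32, 32), 0.7)
        out = propagate_tie(img, geometry, 1e-8)
        assert np.allclose(out, img, atol=1e-12)

    def test_stencil_matches_dense_laplacian(self, geometry):
        rng = np.random.default_rng(2)
        yy, xx = np.mgrid[0:32, 0:32]
        img = 1.0 + 0.3 * np.exp(-((yy - 16) ** 2 + (xx - 16) ** 2) / 30.0)
        ratio = 4.8e-9
        out = propagate_tie(img, geometry, ratio, method="stencil")
        # brute-force replicate-padded 5-point Laplacian
        pad = np.pad(img, 1, mode="edge")
        lap = pad[:-2, 1:-1] + pad[2:, 1:-1] + pad[1:-1, :-2] + pad[1:-1, 2:] - 4 * img
        a = ratio_cm_to_px2(ratio, geometry)
        assert np.allclose(out, img - a * lap, atol=1e-12)

    def test_conserves_total_intensity(self, geometry, rng):
        for _ in range(5):
            img = rng.random((40, 40)) + 0.5
            out = propagate_tie(img, geometry, 4.8e-9, method="fourier")
            assert out.sum() == pytest.approx(img.sum(), rel=1e-10)

    def test_nonfinite_rejected(self, geometry):
        img = np.ones((8, 8))
        img[0, 0] = np.nan
        with pytest.raises(ValueError):
            propagate_tie(img, geometry, 1e-8)


class TestModulator:
    def test_distinct_offsets_required(self):
        with pytest.raises(ValueError, match="distinct"):
            ModulatorSpec(n_positions=2, offsets_um=np.zeros((2, 2)))

    def test_period_sampling_guard(self, geometry):
        mod = ModulatorSpec(period_um=2.0)
        with pytest.raises(ValueError, match="3 effective pixels"):
            modulator_pattern(mod, geometry, (16, 16), 0)

    def test_pattern_mean_near_one(self, geometry, modulator):
        p = modulator_pattern(modulator, geometry, (64, 64), 0)
        assert p.mean() == pytest.approx(1.0, abs=0.02)
        assert p.min() > 0


class TestRenderFrames:
    def test_flat_exit_wave_frames_equal_reference(self, geometry, modulator):
        ew = ExitWave(np.ones((32, 32)), np.zeros((32, 32)), 1.44)
        fr = render_modulated_frames(ew, modulator, geometry, psf_sigma_px=0.0)
        assert np.allclose(fr.sample, fr.reference, atol=1e-12)

    def test_pure_attenuator_ratio(self, geometry, modulator):
        tau = np.full((32, 32), 0.6)
        ew = ExitWave(tau, np.zeros_like(tau), 1.44)
        fr = render_modulated_frames(ew, modulator, geometry, psf_sigma_px=0.0)
        assert np.allclose(average_transmission(fr), tau, atol=1e-12)

    def test_linear_phase_ramp_shifts_pattern(self, geometry, modulator):
        """A linear phase ramp shifts the pattern uniformly by the
        displacement implied by the gradient-to-displacement relation;
        checked by cross-correlating sample against reference."""
        n = 64
        u_true = 1.0
        g = geometry.displacement_to_phase_gradient
        phi = np.arange(n)[None, :] * np.ones((n, 1)) * u_true * g
        ew = ExitWave(np.ones((n, n)), phi, 1.44)
        fr = render_modulated_frames(ew, modulator, geometry, psf_sigma_px=0.0)
        # integer-shift cross-correlation oracle on the central region
        s, r = fr.sample[0][8:-8, 8:-8], fr.reference[0]
        scores = [
            np.corrcoef(s.ravel(), r[8:-8, 8 - k:-8 - k].ravel())[0, 1] for k in (-1, 0, 1)
        ]
        assert np.argmax(scores) == 2  # pattern moved toward +x by ~1 px

    def test_noise_requires_seed(self, geometry, modulator):
        ew = ExitWave(np.ones((16, 16)), np.zeros((16, 16)), 1.44)
        with pytest.raises(ValueError, match="seed"):
            render_modulated_frames(ew, modulator, geometry, noise_counts=1000.0)

    def test_noise_reproducible(self, geometry, modulator):
        ew = ExitWave(np.ones((16, 16)), np.zeros((16, 16)), 1.44)
        a = render_modulated_frames(ew, modulator, geometry, noise_counts=1000.0, seed=3)
        b = render_modulated_frames(ew, modulator, geometry, noise_counts=1000.0, seed=3)
        assert np.array_equal(a.sample, b.sample)
        assert np.array_equal(a.reference, b.reference)
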