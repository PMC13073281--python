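"""Basis decomposition, concentration conversion, K-edge subtraction."""

import numpy as np
import pytest

from stainmap.decomposition import (
    BasisPair,
    KEdgePair,
    compose,
    decompose,
    kedge_target_attenuations,
    kedge_volume_fraction,
    stain_concentration_map,
)
from stainmap.materials import (
    get_material,
    material_from_values,
    molar_concentration,
    soft_tissue,
)


@pytest.fixture(scope="module")
def tissue_lead_basis():
    return BasisPair(soft_tissue(25.0), get_material("lead", 25.0))


class TestDecompose:
    def test_pure_basis_voxels(self, tissue_lead_basis):
        b = tissue_lead_basis
        res = decompose(np.array([b.m1.mu]), np.array([b.m1.rho_e]), b)
        assert res.v1[0] == pytest.approx(1.0, abs=1e-12)
        assert res.v2[0] == pytest.approx(0.0, abs=1e-12)

    def test_known_mixture_round_trip(self, tissue_lead_basis):
        mu, rho = compose(0.3, 0.7, tissue_lead_basis)
        res = decompose(np.array([mu]), np.array([rho]), tissue_lead_basis)
        assert res.v1[0] == pytest.approx(0.3, abs=1e-12)
        assert res.v2[0] == pytest.approx(0.7, abs=1e-12)

    def test_random_round_trip_bulk(self, rng):
        """decompose(compose(v)) is the identity to 1e-12 for 10^4
        random voxels and random non-singular bases."""
        for _ in range(10):
            m1 = material_from_values("a", 25.0, mu=rng.uniform(0.1, 10), rho_e=rng.uniform(100, 500))
            m2 = material_from_values("b", 25.0, mu=rng.uniform(20, 600), rho_e=rng.uniform(1000, 3000))
            basis = BasisPair(m1, m2)
            v1 = rng.uniform(-0.5, 1.5, size=1000)
            v2 = rng.uniform(-0.5, 1.5, size=1000)
            mu, rho = compose(v1, v2, basis)
            res = decompose(mu, rho, basis)
            assert np.allclose(res.v1, v1, atol=1e-12, rtol=1e-12)
            assert np.allclose(res.v2, v2, atol=1e-12, rtol=1e-12)

    def test_ptfe_exceeds_unity_in_pom_pvc_basis(self):
        """PTFE's high electron density makes its volume fraction
        exceed 1 when expressed in a POM/PVC basis; the exact value
        comes from an independent 2x2 solve."""
        pom = get_material("POM", 25.0)
        pvc = get_material("PVC", 25.0)
        ptfe = get_material("PTFE", 25.0)
        basis = BasisPair(pom, pvc)
        res = decompose(np.array([ptfe.mu]), np.array([ptfe.rho_e]), basis)
        expected = np.linalg.solve(basis.matrix, [ptfe.mu, ptfe.rho_e])
        assert res.v1[0] == pytest.approx(expected[0], rel=1e-12)
        assert res.v2[0] == pytest.approx(expected[1], rel=1e-12)
        assert max(expected) > 1.0

    def test_no_clipping_of_negative_fractions(self, tissue_lead_basis):
        res = decompose(np.array([0.0]), np.array([0.0]), tissue_lead_basis)
        # air decomposes to ~zero of both, slightly negative allowed
        assert res.v1[0] == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_basis_rejected(self):
        m = material_from_values("a", 25.0, mu=1.0, rho_e=100.0)
        m2 = material_from_values("b", 25.0, mu=2.0, rho_e=200.0)  # collinear
        with pytest.raises(ValueError, match="degenerate|singular"):
            BasisPair(m, m2)

    def test_misregistered_volumes_rejected(self, tissue_lead_basis):
        with pytest.raises(ValueError, match="co-registered"):
            decompose(np.zeros((2, 2)), np.zeros((2, 3)), tissue_lead_basis)


class TestConcentration:
    def test_zero_fraction_zero_map(self, tissue_lead_basis):
        res = decompose(
            np.full((3, 3), tissue_lead_basis.m1.mu),
            np.full((3, 3), tissue_lead_basis.m1.rho_e),
            tissue_lead_basis,
        )
        conc = stain_concentration_map(res)
        assert np.allclose(conc, 0.0, atol=1e-9)

    def test_uniform_fraction_scalar_oracle(self, tissue_lead_basis):
        mu, rho = compose(0.99, 0.01, tissue_lead_basis)
        res = decompose(np.full((2, 2), mu), np.full((2, 2), rho), tissue_lead_basis)
        conc = stain_concentration_map(res)
        assert np.allclose(conc, molar_concentration(0.01, 11.34, 207.2), rtol=1e-9)
        assert conc[0, 0] == pytest.approx(0.01 * 11.34 / 207.2 * 1000.0, rel=1e-6)

    def test_missing_molar_mass_rejected(self):
        m1 = material_from_values("t", 25.0, mu=0.567, rho_e=299.0)
        m2 = material_from_values("s", 25.0, mu=550.0, rho_e=2703.0)  # no molar mass
        res = decompose(np.zeros((2,)), np.zeros((2,)), BasisPair(m1, m2))
        with pytest.raises(ValueError, match="molar mass|mass density"):
            stain_concentration_map(res)


class TestKEdge:
    def test_exact_inversion_with_equal_background(self):
        """Voxels built from the two-energy mixture model with equal
        background attenuation invert exactly."""
        mu_x_low, mu_x_high = kedge_target_attenuations("Pb", 11.34, 1.0)
        v = np.array([[0.0, 0.05], [0.1, 0.013]])
        mu_b = 0.18  # background equal at both energies
        mu_low = v * mu_x_low + (1 - v) * mu_b
        mu_high = v * mu_x_high + (1 - v) * mu_b
        pair = KEdgePair(mu_low=mu_low, mu_high=mu_high, element="Pb", delta_e_kev=1.0)
        vx = kedge_volume_fraction(pair, mass_density=11.34)
        assert np.allclose(vx, v, atol=1e-12)

    def test_zero_everywhere(self):
        pair = KEdgePair(np.full((3, 3), 0.2), np.full((3, 3), 0.2), "Pb")
        assert not kedge_volume_fraction(pair).any()

    def test_edge_jump_is_positive(self):
        lo, hi = kedge_target_attenuations("Pb", 11.34, 1.0)
        assert hi > 2 * lo  # the K edge is a large upward jump

    def test_misregistered_rejected(self):
        with pytest.raises(ValueError):
            KEdgePair(np.zeros((2, 2)), np.zeros((3, 2)), "Pb")


class TestBasisRobustness:
    def test_tissue_perturbation_bounds_stain_error(self):
        """Decomposing voxels whose true tissue component deviates by
        up to +/-5% in mu and rho_e from the basis tissue changes the
        recovered stain concentration by < 2% relative; the tissue
        fraction absorbs the mismatch."""
        basis = BasisPair(soft_tissue(25.0), get_material("lead", 25.0))
        v_true = 0.01
        worst = 0.0
        for eps_mu in (-0.05, 0.0, 0.05):
            for eps_rho in (-0.05, 0.0, 0.05):
                mu_t = basis.m1.mu * (1 + eps_mu)
                rho_t = basis.m1.rho_e * (1 + eps_rho)
                mu = v_true * basis.m2.mu + (1 - v_true) * mu_t
                rho = v_true * basis.m2.rho_e + (1 - v_true) * rho_t
                res = decompose(np.array([mu]), np.array([rho]), basis)
                rel = abs(res.v2[0] - v_true) / v_true
                worst = max(worst, rel)
                # the tissue channel absorbs the perturbation
                assert abs(res.v1[0] - (1 - v_true)) >= abs(res.v2[0] - v_true) * 0.9
        assert worst < 0.02
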