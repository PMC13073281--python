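"""Material-property algebra: composition, cross sections, mixtures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stainmap.constants import R_E_NM, wavelength_nm
from stainmap import materials as M


class TestElectronDensity:
    @pytest.mark.parametrize(
        "formula, density, expected",
        [
            ("C5H8O2", 1.18, 383),  # PMMA at tabulated density
            ("C2F4", 2.2, 636),  # PTFE bulk
            ("Pb", 11.34, 2703),  # elemental lead
        ],
    )
    def test_reference_materials(self, formula, density, expected):
        rho_e = M.electron_density_from_composition(formula, density)
        assert round(rho_e) == expected

    def test_homogeneous_in_density(self):
        assert M.electron_density_from_composition("H2O", 2.0) == pytest.approx(
            2.0 * M.electron_density_from_composition("H2O", 1.0)
        )

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="unknown element"):
            M.electron_density_from_composition("Xq2", 1.0)

    def test_formula_parser(self):
        assert M.parse_formula("C2H6O") == {"C": 2.0, "H": 6.0, "O": 1.0}
        with pytest.raises(ValueError):
            M.parse_formula("2CH")


class TestAttenuation:
    def test_lead_at_25_kev(self):
        mu = M.attenuation_from_composition("Pb", 11.34, 25.0)
        assert mu == pytest.approx(550, rel=0.01)

    def test_water_at_20_kev(self):
        mu = M.attenuation_from_composition("H2O", 1.0, 20.0)
        assert mu == pytest.approx(0.81, abs=0.005)

    def test_water_monotone_without_edge(self):
        energies = np.linspace(15, 30, 16)
        mus = [M.attenuation_from_composition("H2O", 1.0, e) for e in energies]
        assert all(a > b for a, b in zip(mus, mus[1:]))

    def test_homogeneous_in_density(self):
        assert M.attenuation_from_composition("C5H8O2", 2.36, 25.0) == pytest.approx(
            2.0 * M.attenuation_from_composition("C5H8O2", 1.18, 25.0)
        )

    def test_energy_out_of_range(self):
        with pytest.raises(ValueError, match="outside tabulated range"):
            M.attenuation_from_composition("H2O", 1.0, 0.5)


class TestDelta:
    def test_zero_density(self):
        assert M.delta_from_electron_density(0.0, 25.0) == 0.0

    def test_scalar_formula_oracle(self):
        # independent hand evaluation of r_e lambda^2 rho_e / (2 pi)
        lam = wavelength_nm(25.0)
        expected = R_E_NM * lam**2 * 2703.0 / (2.0 * np.pi)
        assert M.delta_from_electron_density(2703.0, 25.0) == pytest.approx(expected, rel=1e-12)

    def test_linear_in_density(self):
        assert M.delta_from_electron_density(600.0, 20.0) == pytest.approx(
            2.0 * M.delta_from_electron_density(300.0, 20.0)
        )


class TestMixtures:
    def test_endpoints(self):
        m1 = M.get_material("PMMA", 25.0)
        m2 = M.get_material("lead", 25.0)
        assert M.mix_properties(m1, m2, 1.0).mu == pytest.approx(m1.mu)
        assert M.mix_properties(m1, m2, 0.0).rho_e == pytest.approx(m2.rho_e)

    def test_midpoint_linearity(self):
        m1 = M.material_from_values("a", 25.0, mu=1.0, rho_e=100.0)
        m2 = M.material_from_values("b", 25.0, mu=3.0, rho_e=300.0)
        mix = M.mix_properties(m1, m2, 0.5)
        assert mix.mu == pytest.approx(2.0)
        assert mix.rho_e == pytest.approx(200.0)
        assert mix.delta == pytest.approx((m1.delta + m2.delta) / 2)

    def test_energy_mismatch_rejected(self):
        m1 = M.get_material("PMMA", 25.0)
        m2 = M.get_material("lead", 30.0)
        with pytest.raises(ValueError, match="energy"):
            M.mix_properties(m1, m2, 0.5)
        with pytest.raises(ValueError):
            M.mix_properties(m1, M.get_material("lead", 25.0), 1.5)


class TestRelativeRatio:
    def test_degenerate_basis(self):
        m = M.get_material("PMMA", 25.0)
        with pytest.raises(ValueError, match="degenerate"):
            M.relative_delta_mu(m, m)

    def test_scalar_oracle_tissue_lead(self):
        # hand-evaluated from the measured kidney values and lead tables
        tissue = M.material_from_values("kidney", 25.0, mu=0.567, rho_e=299.0)
        lead = M.material_from_values(
            "lead", 25.0, mu=550.0, rho_e=2703.0
        )
        expected = (tissue.delta - lead.delta) / (0.567 - 550.0)
        assert M.relative_delta_mu(tissue, lead) == pytest.approx(expected, rel=1e-12)
        assert expected > 0  # low-pass, not amplifying

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        f1=st.floats(0.0, 1.0),
        f2=st.floats(0.0, 1.0),
        mu1=st.floats(0.1, 600.0),
        mu2=st.floats(0.1, 600.0),
        rho1=st.floats(50.0, 3000.0),
        rho2=st.floats(50.0, 3000.0),
    )
    def test_mixture_independence(self, f1, f2, mu1, mu2, rho1, rho2):
        """The relative ratio of any two distinct mixtures of a pair
        equals that of the pure pair."""
        m1 = M.material_from_values("m1", 25.0, mu=mu1, rho_e=rho1)
        m2 = M.material_from_values("m2", 25.0, mu=mu2, rho_e=rho2)
        a = M.mix_properties(m1, m2, f1)
        b = M.mix_properties(m1, m2, f2)
        if m1.mu == m2.mu or abs(f1 - f2) * abs(m1.mu - m2.mu) < 1e-9:
            return
        assert M.relative_delta_mu(a, b) == pytest.approx(
            M.relative_delta_mu(m1, m2), rel=1e-9
        )


class TestKEdge:
    @pytest.mark.parametrize(
        "element, expected",
        [("Os", 73.9), ("Pb", 88.0), ("Bi", 90.5), ("Fe", 7.1)],
    )
    def test_tabulated_edges(self, element, expected):
        assert M.kedge_energy(element) == pytest.approx(expected, abs=0.06)

    def test_unknown_element(self):
        with pytest.raises(KeyError):
            M.kedge_energy("Xx")


class TestMolarConcentration:
    def test_zero_fraction(self):
        assert M.molar_concentration(0.0, 11.34, 207.2) == 0.0

    def test_hand_unit_conversion(self):
        # pure lead: 11.34 g/cm^3 / 207.2 g/mol * 1000 cm^3/L
        assert M.molar_concentration(1.0, 11.34, 207.2) == pytest.approx(54.73, abs=0.01)

    def test_linear(self):
        assert M.molar_concentration(0.02, 11.34, 207.2) == pytest.approx(
            2.0 * M.molar_concentration(0.01, 11.34, 207.2)
        )

    def test_bad_molar_mass(self):
        with pytest.raises(ValueError):
            M.molar_concentration(1.0, 11.34, 0.0)


def test_silicon_tai_design_height():
    """Silicon thickness giving a 2pi/3 phase shift at 30 keV."""
    si = M.get_material("silicon", 30.0)
    lam = wavelength_nm(30.0)
    t_um = lam / (3.0 * si.delta) * 1e-3  # (2pi/3) * lam / (2 pi delta)
    assert t_um == pytest.approx(25.7, abs=0.1)


def test_registry_density_override():
    ptfe = M.get_material("PTFE", 25.0, mass_density=2.15)
    assert ptfe.rho_e == pytest.approx(
        M.electron_density_from_composition("C2F4", 2.15)
    )
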