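"""Physical constants in the package's unit system.

Units used throughout: photon energy in keV, wavelength and electron
densities in nm (1/nm^3), linear attenuation in 1/cm, mass density in
g/cm^3, molar mass in g/mol.  CODATA values, read-only.
"""

# classical electron radius, nm
R_E_NM: float = 2.8179403262e-6

# conversion factor: wavelength[nm] = HC_KEV_NM / energy[keV]
HC_KEV_NM: float = 1.2398419843

# Avogadro constant, 1/mol
N_AVOGADRO: float = 6.02214076e23


def wavelength_nm(energy_kev: float) -> float:
    """Photon wavelength in nm for an energy in keV."""
    if energy_kev <= 0:
        raise ValueError("photon energy must be positive")
    return HC_KEV_NM / energy_kev
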