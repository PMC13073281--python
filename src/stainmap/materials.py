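"""X-ray material-property algebra.

Everything downstream of the scan — transport-of-intensity edge
correction, electron-density calibration and two-material decomposition
— is driven by three per-material quantities evaluated at the working
energy: the refractive index decrement delta, the linear attenuation
coefficient mu (1/cm) and the electron number density rho_e (1/nm^3).
This module computes them from chemical composition and mass density
using the embedded photon cross-section table, and provides the mixture
rules for two-material systems:

    delta_mix = f*delta1 + (1-f)*delta2
    mu_mix    = f*mu1    + (1-f)*mu2

together with the relative delta/mu ratio

    (delta/mu)_rel = (delta1 - delta2) / (mu1 - mu2)

which is invariant under replacing the pure pair by any two distinct
mixtures of the pair — the property that makes a single low-pass filter
valid for arbitrary two-material tissue/stain compositions.

Unit system: keV, nm (wavelength, rho_e), cm (mu), g/cm^3, g/mol.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np

from . import xray_tables as xt
from .constants import N_AVOGADRO, R_E_NM, wavelength_nm

__all__ = [
    "MaterialProperties",
    "MATERIAL_REGISTRY",
    "parse_formula",
    "electron_density_from_composition",
    "attenuation_from_composition",
    "delta_from_electron_density",
    "material_from_composition",
    "material_from_values",
    "get_material",
    "soft_tissue",
    "mix_properties",
    "relative_delta_mu",
    "kedge_energy",
    "molar_concentration",
]


@dataclass(frozen=True)
class MaterialProperties:
    """One material at one photon energy.

    Attributes
    ----------
    name : text label
    energy : photon energy, keV
    delta : refractive index decrement (dimensionless)
    mu : linear attenuation coefficient, 1/cm
    rho_e : electron number density, 1/nm^3
    mass_density : g/cm^3 (nan if unknown)
    molar_mass : g/mol (nan if unknown)
    """

    name: str
    energy: float
    delta: float
    mu: float
    rho_e: float
    mass_density: float = float("nan")
    molar_mass: float = float("nan")

    def __post_init__(self):
        if self.energy <= 0:
            raise ValueError("energy must be positive")
        if self.delta < 0 or self.mu < 0 or self.rho_e < 0:
            raise ValueError("delta, mu and rho_e must be non-negative")

    def at_density(self, mass_density: float) -> "MaterialProperties":
        """Rescale all density-proportional quantities to a new mass density."""
        if not np.isfinite(self.mass_density) or self.mass_density <= 0:
            raise ValueError("original mass density unknown; cannot rescale")
        s = mass_density / self.mass_density
        return replace(
            self, delta=self.delta * s, mu=self.mu * s, rho_e=self.rho_e * s,
            mass_density=mass_density,
        )


#: Shipped compound registry: name -> (formula, density g/cm^3).
#: Literature bulk densities; all overridable (real samples may differ,
#: e.g. porous PTFE parts run a few percent below bulk density).
MATERIAL_REGISTRY: dict[str, tuple[str, float]] = {
    "PMMA": ("C5H8O2", 1.18),
    "PTFE": ("C2F4", 2.20),
    "POM": ("CH2O", 1.41),
    "PVC": ("C2H3Cl", 1.40),
    "ethanol": ("C2H6O", 0.789),
    "water": ("H2O", 1.00),
    "paraffin": ("C25H52", 0.90),
    "lead": ("Pb", 11.34),
    "silicon": ("Si", 2.33),
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def parse_formula(formula: str) -> dict[str, float]:
    """Parse a chemical formula like ``C5H8O2`` into element counts.

    Fractional counts are allowed (useful for average compositions).
    Unknown element symbols raise ``ValueError``.
    """
    pos = 0
    counts: dict[str, float] = {}
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
        pos = m.end()
        sym, n = m.group(1), m.group(2)
        if sym not in xt.ATOMIC_NUMBER:
            raise ValueError(f"unknown element symbol {sym!r} in {formula!r}")
        counts[sym] = counts.get(sym, 0.0) + (float(n) if n else 1.0)
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def _molar_mass(counts: dict[str, float]) -> float:
    return sum(n * xt.ATOMIC_WEIGHT[el] for el, n in counts.items())


def electron_density_from_composition(formula: str, mass_density: float) -> float:
    """Electron number density in 1/nm^3 from formula and density (g/cm^3).

    rho_e = rho * (sum n_i Z_i / sum n_i A_i) * N_A, converted from
    1/cm^3 to 1/nm^3 (factor 1e-21).
    """
    if mass_density <= 0:
        raise ValueError("mass density must be positive")
    counts = parse_formula(formula)
    z_over_a = sum(n * xt.ATOMIC_NUMBER[el] for el, n in counts.items()) / _molar_mass(counts)
    return mass_density * z_over_a * N_AVOGADRO * 1e-21


def attenuation_from_composition(formula: str, mass_density: float, energy_kev: float) -> float:
    """Linear attenuation coefficient in 1/cm at ``energy_kev``.

    Elemental total mass attenuation coefficients (coherent scattering
    included) are combined by mass fraction and scaled by density.
    """
    if mass_density <= 0:
        raise ValueError("mass density must be positive")
    counts = parse_formula(formula)
    mm = _molar_mass(counts)
    mu_rho = sum(
        n * xt.ATOMIC_WEIGHT[el] / mm * xt.mass_attenuation(el, energy_kev)
        for el, n in counts.items()
    )
    return mu_rho * mass_density


def delta_from_electron_density(rho_e: float, energy_kev: float) -> float:
    """Refractive index decrement delta = r_e * lambda^2 * rho_e / (2 pi).

    ``rho_e`` in 1/nm^3; wavelength from the photon energy in keV.  Far
    from absorption edges delta is set by the electron density alone.
    """
    if rho_e < 0:
        raise ValueError("rho_e must be non-negative")
    lam = wavelength_nm(energy_kev)
    return R_E_NM * lam * lam * rho_e / (2.0 * np.pi)


def material_from_composition(
    name: str, formula: str, mass_density: float, energy_kev: float
) -> MaterialProperties:
    """Full property set for a compound at one energy."""
    rho_e = electron_density_from_composition(formula, mass_density)
    return MaterialProperties(
        name=name,
        energy=energy_kev,
        delta=delta_from_electron_density(rho_e, energy_kev),
        mu=attenuation_from_composition(formula, mass_density, energy_kev),
        rho_e=rho_e,
        mass_density=mass_density,
        molar_mass=_molar_mass(parse_formula(formula)),
    )


def material_from_values(
    name: str,
    energy_kev: float,
    mu: float,
    rho_e: float,
    mass_density: float = float("nan"),
    molar_mass: float = float("nan"),
) -> MaterialProperties:
    """Material defined by measured (mu, rho_e) rather than composition.

    Used for empirical basis materials such as unstained tissue, whose
    attenuation and electron density come from a companion scan.
    """
    return MaterialProperties(
        name=name,
        energy=energy_kev,
        delta=delta_from_electron_density(rho_e, energy_kev),
        mu=mu,
        rho_e=rho_e,
        mass_density=mass_density,
        molar_mass=molar_mass,
    )


def get_material(name: str, energy_kev: float, mass_density: float | None = None) -> MaterialProperties:
    """Registry lookup (falls back to treating ``name`` as a formula)."""
    if name in MATERIAL_REGISTRY:
        formula, density = MATERIAL_REGISTRY[name]
        return material_from_composition(
            name, formula, mass_density if mass_density is not None else density, energy_kev
        )
    if mass_density is None:
        raise ValueError(f"{name!r} not in registry; pass mass_density to use it as a formula")
    return material_from_composition(name, name, mass_density, energy_kev)


# Unstained mouse-kidney reference values measured at 25 keV:
# rho_e = 299 /nm^3, mu = 0.567 /cm.  At other energies the attenuation
# is scaled along the water curve (soft tissue is water-like in this
# range); the electron density is energy-independent.
_TISSUE_RHO_E = 299.0
_TISSUE_MU_25 = 0.567
_TISSUE_REF_ENERGY = 25.0


def soft_tissue(energy_kev: float = _TISSUE_REF_ENERGY) -> MaterialProperties:
    """Soft-tissue (kidney) basis material at the requested energy."""
    scale = attenuation_from_composition("H2O", 1.0, energy_kev) / attenuation_from_composition(
        "H2O", 1.0, _TISSUE_REF_ENERGY
    )
    return material_from_values(
        "soft tissue (kidney)",
        energy_kev,
        mu=_TISSUE_MU_25 * scale,
        rho_e=_TISSUE_RHO_E,
        mass_density=1.05,
    )


def mix_properties(m1: MaterialProperties, m2: MaterialProperties, f: float) -> MaterialProperties:
    """Linear two-material mixture with volume fraction ``f`` of ``m1``.

    delta, mu and rho_e are all volume-fraction-weighted averages; the
    two inputs must be evaluated at the same energy.
    """
    if not np.isclose(m1.energy, m2.energy):
        raise ValueError(
            f"mixture requires a common energy ({m1.energy} keV vs {m2.energy} keV)"
        )
    if not 0.0 <= f <= 1.0:
        raise ValueError("physical mixture fraction must lie in [0, 1]")
    g = 1.0 - f
    return MaterialProperties(
        name=f"{f:g}*{m1.name} + {g:g}*{m2.name}",
        energy=m1.energy,
        delta=f * m1.delta + g * m2.delta,
        mu=f * m1.mu + g * m2.mu,
        rho_e=f * m1.rho_e + g * m2.rho_e,
        mass_density=f * m1.mass_density + g * m2.mass_density,
    )


def relative_delta_mu(m1: MaterialProperties, m2: MaterialProperties) -> float:
    """Relative ratio (delta1 - delta2)/(mu1 - mu2) in cm.

    Invariant under replacing (m1, m2) by any two distinct mixtures of
    the same pair, so knowledge of the per-voxel composition is not
    needed.  Raises on a degenerate basis (mu1 == mu2).
    """
    if not np.isclose(m1.energy, m2.energy):
        raise ValueError("basis materials must share one energy")
    dmu = m1.mu - m2.mu
    if dmu == 0.0:
        raise ValueError("degenerate basis: equal attenuation coefficients")
    return (m1.delta - m2.delta) / dmu


def kedge_energy(element: str) -> float:
    """Tabulated K-shell binding energy in keV."""
    try:
        return xt.K_EDGE_KEV[element]
    except KeyError:
        raise KeyError(f"no tabulated K edge for element {element!r}") from None


def molar_concentration(v, mass_density: float, molar_mass: float):
    """Convert a volume fraction into a molar concentration in mol/L.

    c = v * rho / M with rho in g/cm^3 and M in g/mol; the factor 1000
    converts from mol/cm^3-density units to mol per liter.  ``v`` may be
    a scalar or an array (voxelwise concentration maps).
    """
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    return np.multiply(v, mass_density / molar_mass * 1000.0)
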