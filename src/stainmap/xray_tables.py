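"""Embedded photon-interaction reference data.

Compact elemental data tables for the photon-energy range used in
micro-CT virtual histology (roughly 1--200 keV):

* atomic number ``Z`` and standard atomic weight ``A`` (g/mol),
* total mass attenuation coefficients mu/rho (cm^2/g, coherent
  scattering included), tabulated on a sparse energy grid in the style
  of the NIST XCOM standard reference database and interpolated
  log-log between grid points,
* K-shell binding (K-edge) energies in keV.

Absorption edges inside the tabulated range (the Si K edge and the Pb
L3/K edges) are represented as duplicated grid energies offset by a
tiny epsilon, so that interpolation never crosses an edge.  The Pb
table is coarse between the L edges (15--16 keV); quantities in that
narrow band should not be relied on to better than ~10%.  Anomalous
dispersion fine structure near edges is out of scope throughout.

Only elements needed by the shipped compound registry are included;
extending the table is a matter of adding rows.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ATOMIC_NUMBER",
    "ATOMIC_WEIGHT",
    "K_EDGE_KEV",
    "mass_attenuation",
    "tabulated_elements",
]

ATOMIC_NUMBER: dict[str, int] = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "Na": 11, "Al": 13, "Si": 14,
    "P": 15, "S": 16, "Cl": 17, "K": 19, "Ca": 20, "Fe": 26, "I": 53,
    "Gd": 64, "Os": 76, "Pt": 78, "Au": 79, "Pb": 82, "Bi": 83,
}

ATOMIC_WEIGHT: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "Na": 22.990, "Al": 26.982, "Si": 28.085, "P": 30.974, "S": 32.06,
    "Cl": 35.45, "K": 39.098, "Ca": 40.078, "Fe": 55.845, "I": 126.904,
    "Gd": 157.25, "Os": 190.23, "Pt": 195.084, "Au": 196.967,
    "Pb": 207.2, "Bi": 208.980,
}

# K-shell binding energies, keV (standard X-ray data booklet values).
K_EDGE_KEV: dict[str, float] = {
    "H": 0.0136, "C": 0.284, "N": 0.410, "O": 0.543, "F": 0.697,
    "Na": 1.071, "Al": 1.560, "Si": 1.839, "P": 2.146, "S": 2.472,
    "Cl": 2.822, "K": 3.608, "Ca": 4.039, "Fe": 7.112, "I": 33.169,
    "Gd": 50.239, "Os": 73.871, "Pt": 78.395, "Au": 80.725,
    "Pb": 88.005, "Bi": 90.526,
}

_EDGE_EPS = 1e-4  # keV offset separating below/above-edge branch points

# Total mass attenuation coefficients with coherent scattering, cm^2/g,
# on sparse (keV, mu/rho) grids; log-log interpolated between points.
_MU_RHO: dict[str, list[tuple[float, float]]] = {
    "H": [
        (1.0, 7.217), (1.5, 2.148), (2.0, 1.059), (3.0, 0.5612),
        (4.0, 0.4546), (5.0, 0.4193), (6.0, 0.4042), (8.0, 0.3914),
        (10.0, 0.3854), (15.0, 0.3764), (20.0, 0.3695), (30.0, 0.3570),
        (40.0, 0.3458), (50.0, 0.3355), (60.0, 0.3260), (80.0, 0.3091),
        (100.0, 0.2944), (150.0, 0.2651), (200.0, 0.2429),
    ],
    "C": [
        (1.0, 2211.0), (1.5, 700.2), (2.0, 302.6), (3.0, 90.33),
        (4.0, 37.78), (5.0, 19.12), (6.0, 10.95), (8.0, 4.576),
        (10.0, 2.373), (15.0, 0.8071), (20.0, 0.4420), (30.0, 0.2562),
        (40.0, 0.2076), (50.0, 0.1871), (60.0, 0.1753), (80.0, 0.1610),
        (100.0, 0.1514), (150.0, 0.1347), (200.0, 0.1229),
    ],
    "N": [
        (1.0, 3311.0), (1.5, 1083.0), (2.0, 476.9), (3.0, 145.6),
        (4.0, 61.66), (5.0, 31.44), (6.0, 18.09), (8.0, 7.562),
        (10.0, 3.879), (15.0, 1.236), (20.0, 0.6178), (30.0, 0.3066),
        (40.0, 0.2288), (50.0, 0.1980), (60.0, 0.1817), (80.0, 0.1639),
        (100.0, 0.1529), (150.0, 0.1353), (200.0, 0.1233),
    ],
    "O": [
        (1.0, 4590.0), (1.5, 1549.0), (2.0, 694.9), (3.0, 217.1),
        (4.0, 93.15), (5.0, 47.90), (6.0, 27.70), (8.0, 11.63),
        (10.0, 5.952), (15.0, 1.836), (20.0, 0.8651), (30.0, 0.3779),
        (40.0, 0.2585), (50.0, 0.2132), (60.0, 0.1907), (80.0, 0.1678),
        (100.0, 0.1551), (150.0, 0.1361), (200.0, 0.1237),
    ],
    "F": [
        (1.0, 5649.0), (1.5, 1979.0), (2.0, 904.6), (3.0, 290.7),
        (4.0, 125.6), (5.0, 65.14), (6.0, 37.89), (8.0, 16.02),
        (10.0, 8.205), (15.0, 2.492), (20.0, 1.133), (30.0, 0.4487),
        (40.0, 0.2828), (50.0, 0.2214), (60.0, 0.1920), (80.0, 0.1639),
        (100.0, 0.1496), (150.0, 0.1298), (200.0, 0.1176),
    ],
    "Si": [
        (1.0, 1570.0), (1.5, 535.5),
        (1.839 - _EDGE_EPS, 309.2), (1.839 + _EDGE_EPS, 3192.0),
        (2.0, 2777.0), (3.0, 978.4), (4.0, 452.9), (5.0, 245.0),
        (6.0, 147.0), (8.0, 64.68), (10.0, 33.89), (15.0, 10.34),
        (20.0, 4.464), (30.0, 1.436), (40.0, 0.7012), (50.0, 0.4385),
        (60.0, 0.3207), (80.0, 0.2228), (100.0, 0.1835), (150.0, 0.1448),
        (200.0, 0.1275),
    ],
    # Chlorine grid above its K edge (2.822 keV); accuracy ~10%, used
    # only for polymer phantoms internally consistent with this table.
    "Cl": [
        (3.0, 1620.0), (4.0, 760.0), (5.0, 410.0), (6.0, 246.0),
        (8.0, 108.0), (10.0, 56.3), (15.0, 17.1), (20.0, 7.35),
        (30.0, 2.31), (40.0, 1.07), (50.0, 0.65), (60.0, 0.47),
        (80.0, 0.33), (100.0, 0.27), (150.0, 0.205), (200.0, 0.175),
    ],
    "Pb": [
        (4.0, 1251.0), (5.0, 730.4), (6.0, 467.2), (8.0, 228.7),
        (10.0, 130.6),
        (13.0352 - _EDGE_EPS, 67.01), (13.0352 + _EDGE_EPS, 162.1),
        (15.0, 111.6), (16.0, 151.0),
        (20.0, 86.36), (30.0, 30.32), (40.0, 14.36), (50.0, 8.041),
        (60.0, 5.021), (80.0, 2.419),
        (88.005 - _EDGE_EPS, 1.910), (88.005 + _EDGE_EPS, 7.683),
        (100.0, 5.549), (150.0, 2.014), (200.0, 0.9985),
    ],
}

TABLE_PROVENANCE = "embedded NIST/XCOM-style elemental table (stainmap.xray_tables)"


def tabulated_elements() -> list[str]:
    """Element symbols with a mass-attenuation table."""
    return sorted(_MU_RHO)


def mass_attenuation(element: str, energy_kev) -> np.ndarray | float:
    """Total mass attenuation coefficient mu/rho in cm^2/g.

    Log-log interpolation on the embedded grid.  ``energy_kev`` may be a
    scalar or array; energies outside the tabulated range raise
    ``ValueError``.
    """
    try:
        table = _MU_RHO[element]
    except KeyError:
        raise KeyError(
            f"no mass-attenuation table for element {element!r}; "
            f"available: {tabulated_elements()}"
        ) from None
    e = np.asarray(table, dtype=float)[:, 0]
    m = np.asarray(table, dtype=float)[:, 1]
    energy = np.asarray(energy_kev, dtype=float)
    if np.any(energy < e[0]) or np.any(energy > e[-1]):
        raise ValueError(
            f"energy outside tabulated range [{e[0]:.4g}, {e[-1]:.4g}] keV "
            f"for element {element}"
        )
    out = np.exp(np.interp(np.log(energy), np.log(e), np.log(m)))
    return float(out) if np.isscalar(energy_kev) else out
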