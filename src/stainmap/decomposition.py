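"""Two-material basis decomposition and K-edge subtraction.

A voxel's measured pair (mu, rho_e) is expressed as a linear
combination of two basis materials,

    [mu; rho_e] = A [v1; v2],   A = [[mu1, mu2], [rho_e1, rho_e2]],

so the volume fractions follow from the inverse basis-change matrix.
Fractions are reported raw: negative values and values above 1 are
physically meaningful diagnostics (a material denser than both basis
materials shows up as an excess fraction) and are never clipped here —
display clipping is a rendering choice.  Volume conservation
(v1 + v2 = 1) is not enforced: soft-tissue density varies.

The stain fraction converts to a molar concentration via
c = v * rho / M with the stain's mass density and molar mass.

K-edge subtraction is the independent cross-check: two absorption
volumes bracketing the target element's K edge give

    v_X = (mu_high - mu_low) / (mu_X(E_K + dE) - mu_X(E_K - dE))

under the assumption that the background attenuation is equal at the
two energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .materials import (
    MaterialProperties,
    attenuation_from_composition,
    kedge_energy,
    molar_concentration,
)

__all__ = [
    "BasisPair",
    "DecompositionResult",
    "KEdgePair",
    "decompose",
    "compose",
    "stain_concentration_map",
    "kedge_target_attenuations",
    "kedge_volume_fraction",
]


@dataclass(frozen=True)
class BasisPair:
    """Two basis materials at a common energy; columns of the matrix A."""

    m1: MaterialProperties
    m2: MaterialProperties

    def __post_init__(self):
        if not np.isclose(self.m1.energy, self.m2.energy):
            raise ValueError("basis materials must share one energy")
        if self.determinant == 0.0:
            raise ValueError("degenerate basis: singular change-of-basis matrix")

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [[self.m1.mu, self.m2.mu], [self.m1.rho_e, self.m2.rho_e]], dtype=float
        )

    @property
    def determinant(self) -> float:
        return self.m1.mu * self.m2.rho_e - self.m2.mu * self.m1.rho_e


@dataclass
class DecompositionResult:
    """Raw volume-fraction maps for the two basis materials."""

    v1: np.ndarray
    v2: np.ndarray
    basis: BasisPair
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.valid is None:
            self.valid = np.isfinite(self.v1) & np.isfinite(self.v2)


def decompose(mu: np.ndarray, rho_e: np.ndarray, basis: BasisPair) -> DecompositionResult:
    """Invert the basis change voxelwise: (v1, v2) = A^-1 (mu, rho_e).

    Inputs are co-registered arrays in 1/cm and 1/nm^3.  The 2x2 solve
    is exact; no clipping of negative or >1 fractions.
    """
    mu = np.asarray(mu, dtype=float)
    rho = np.asarray(rho_e, dtype=float)
    if mu.shape != rho.shape:
        raise ValueError("mu and rho_e volumes must be co-registered (same shape)")
    det = basis.determinant
    a = basis.matrix
    v1 = (a[1, 1] * mu - a[0, 1] * rho) / det
    v2 = (-a[1, 0] * mu + a[0, 0] * rho) / det
    return DecompositionResult(v1=v1, v2=v2, basis=basis)


def compose(v1, v2, basis: BasisPair) -> tuple[np.ndarray, np.ndarray]:
    """Forward basis change: (mu, rho_e) = A (v1, v2)."""
    a = basis.matrix
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    return a[0, 0] * v1 + a[0, 1] * v2, a[1, 0] * v1 + a[1, 1] * v2


def stain_concentration_map(result: DecompositionResult, stain: MaterialProperties | None = None):
    """Molar concentration (mol/L) of the stain component.

    The stain is the second basis material by convention; pass
    ``stain`` explicitly to override the material metadata (its mass
    density and molar mass must be known).
    """
    stain = stain if stain is not None else result.basis.m2
    if not np.isfinite(stain.molar_mass) or not np.isfinite(stain.mass_density):
        raise ValueError(f"stain {stain.name!r} lacks mass density or molar mass")
    return molar_concentration(result.v2, stain.mass_density, stain.molar_mass)


@dataclass
class KEdgePair:
    """Co-registered attenuation volumes bracketing a K edge (1/cm)."""

    mu_low: np.ndarray
    mu_high: np.ndarray
    element: str
    delta_e_kev: float = 1.0

    def __post_init__(self):
        self.mu_low = np.asarray(self.mu_low, dtype=float)
        self.mu_high = np.asarray(self.mu_high, dtype=float)
        if self.mu_low.shape != self.mu_high.shape:
            raise ValueError("K-edge volumes must be co-registered (same shape)")
        if self.delta_e_kev <= 0:
            raise ValueError("energy increment must be positive")

    @property
    def e_k(self) -> float:
        return kedge_energy(self.element)


def kedge_target_attenuations(
    element: str, mass_density: float, delta_e_kev: float = 1.0
) -> tuple[float, float]:
    """Target-material mu (1/cm) just below and above its K edge."""
    ek = kedge_energy(element)
    return (
        attenuation_from_composition(element, mass_density, ek - delta_e_kev),
        attenuation_from_composition(element, mass_density, ek + delta_e_kev),
    )


def kedge_volume_fraction(pair: KEdgePair, mass_density: float = 11.34) -> np.ndarray:
    """Target volume fraction from the attenuation jump across the edge.

    v_X = (mu_high - mu_low) / (mu_X(E_K+dE) - mu_X(E_K-dE)); exact
    when the background attenuation is equal at the two energies.
    """
    mu_x_low, mu_x_high = kedge_target_attenuations(
        pair.element, mass_density, pair.delta_e_kev
    )
    denom = mu_x_high - mu_x_low
    if denom == 0.0:
        raise ValueError("degenerate K-edge pair: equal target attenuations")
    return (pair.mu_high - pair.mu_low) / denom
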