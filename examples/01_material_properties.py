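"""X-ray material properties from composition: the numbers the whole
pipeline is built on.

Computes electron number densities, attenuation coefficients and the
relative delta/mu ratio of the soft-tissue/lead basis pair, and shows
the mixture identity that lets one filter serve every voxel
composition.
"""

from stainmap import (
    attenuation_from_composition,
    electron_density_from_composition,
    get_material,
    kedge_energy,
    mix_properties,
    molar_concentration,
    relative_delta_mu,
    soft_tissue,
)

print("Electron number densities (1/nm^3):")
for name, formula, density in [("PMMA", "C5H8O2", 1.18), ("PTFE", "C2F4", 2.2), ("lead", "Pb", 11.34)]:
    print(f"  {name:5s} {electron_density_from_composition(formula, density):7.1f}")

print("\nLinear attenuation coefficients (1/cm):")
print(f"  lead  @ 25 keV: {attenuation_from_composition('Pb', 11.34, 25.0):6.1f}")
print(f"  water @ 20 keV: {attenuation_from_composition('H2O', 1.0, 20.0):6.3f}")
print(f"\nPb K edge: {kedge_energy('Pb'):.1f} keV")

tissue = soft_tissue(25.0)
lead = get_material("lead", 25.0)
ratio = relative_delta_mu(tissue, lead)
print(f"\nRelative delta/mu ratio (tissue/lead basis): {ratio:.3e} cm")

# any two distinct mixtures of the pair give the same ratio
mix_a = mix_properties(tissue, lead, 0.98)
mix_b = mix_properties(tissue, lead, 0.90)
print(f"Same ratio from 98%/90% tissue mixtures:     {relative_delta_mu(mix_a, mix_b):.3e} cm")

print(f"\nMolarity of pure lead: {molar_concentration(1.0, 11.34, 207.2):.1f} mol/L")
print("A voxel with 1% lead volume fraction therefore holds "
      f"{molar_concentration(0.01, 11.34, 207.2):.2f} mol/L of stain metal.")
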