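"""Physical constants and unit conversions used across the package.

Public functions accept and return quantities in the units conventional for
droplet-interface-bilayer (DIB) and lipid-calorimetry work: micrometres and
seconds for droplet trajectories, mN/m for tensions, degrees for contact
angles, kcal/mol for transition enthalpies, cm^-1 for vibrational bands and
mM for solute concentrations.  All internal computation is in SI; every
conversion lives in this module and nowhere else.
"""

N_AVOGADRO = 6.02214076e23  # mol^-1

#: Molar volume of liquid water, m^3/mol (18.0 cm^3/mol).
WATER_MOLAR_VOLUME = 1.8e-5

#: Van't Hoff factor for fully dissociated NaCl.
NACL_VANT_HOFF = 2.0

#: Molal osmotic coefficient of NaCl near 0.1 M and room temperature.
NACL_OSMOTIC_COEFF = 0.932

#: Effective osmole multiplier converting molar NaCl to osmolarity.
NACL_OSMOTIC_MULTIPLIER = NACL_VANT_HOFF * NACL_OSMOTIC_COEFF

#: DOPC molar mass, g/mol.
DOPC_MOLAR_MASS = 786.1

#: PFAS-free DOPC DIB contact angle (degrees) — default half-angle used when
#: the bilayer contact area has to be reconstructed from droplet radii.
DOPC_CONTACT_ANGLE_DEG = 32.41

#: Mean area per DOPC lipid in a monolayer, Angstrom^2.
DOPC_AREA_PER_LIPID_A2 = 70.0

# Length/area/volume conversions
UM_TO_M = 1e-6
M_TO_UM = 1e6
UM2_TO_M2 = 1e-12
M2_TO_UM2 = 1e12
UM3_TO_M3 = 1e-18
M3_TO_UM3 = 1e18
A2_TO_M2 = 1e-20  # Angstrom^2 -> m^2

#: 1 mM == 1 mol/m^3, a convenient identity for osmolarity bookkeeping.
MM_TO_MOL_M3 = 1.0

CAL_TO_J = 4.184
KCAL_TO_J = 4184.0


def nacl_osmolarity_mol_m3(molarity_M: float,
                           multiplier: float = NACL_OSMOTIC_MULTIPLIER) -> float:
    """Osmolarity (osmol/m^3) of a NaCl solution of the given molarity (mol/L)."""
    return molarity_M * 1e3 * multiplier
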