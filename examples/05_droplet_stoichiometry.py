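"""Lipid vs dissolved-amphiphile stoichiometry of the assay geometries."""

from memphys.composition import (DropletSpec, SuspensionSpec,
                                 lipid_pfas_ratio, suspension_pfas_molarity)

for conc in (0.1, 1.0):
    ratio = lipid_pfas_ratio(DropletSpec(diameter_um=100.0,
                                         area_per_lipid_A2=70.0,
                                         pfas_conc_mM=conc))
    print(f"100 um droplet, 70 A^2/lipid, {conc:4.1f} mM solute: "
          f"lipid:solute = {ratio:.2f}")

mM = suspension_pfas_molarity(SuspensionSpec(lipid_mass_conc_mg_ml=16.0,
                                             lipid_molar_mass_g_mol=786.1,
                                             mole_ratio_lipid_to_pfas=10.0))
print(f"16 mg/mL vesicle suspension at 10:1 lipid:solute: {mM:.2f} mM solute")
print()
print("The droplet ratio scales as 1/(c r): at 1 mM the dissolved solute")
print("outnumbers the monolayer lipids sevenfold, so the bilayer assay and")
print("the vesicle experiments probe comparable molecular ratios.")
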