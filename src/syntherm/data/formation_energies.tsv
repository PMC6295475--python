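# Standard Gibbs free energies of formation at 298.15 K.
# Conventions: pH 0 reference (dGf0 of H+ is zero), 1 atm standard state for
# gases, 1 mol/L ideal solution for aqueous species, pure liquid for water.
# Values after Thauer, Jungermann & Decker (1977), Bacteriol. Rev. 41:100-180.
name	formula	charge	phase	dgf0_kJ_per_mol
acetate	C2H3O2	-1	aqueous	-369.41
H2O	H2O	0	water	-237.17
HCO3-	CHO3	-1	aqueous	-586.85
CO3-2	CO3	-2	aqueous	-527.90
CO2	CO2	0	gas	-394.36
H2	H2	0	gas	0.0
H+	H	1	aqueous	0.0
CH4	CH4	0	gas	-50.75
SO4-2	SO4	-2	aqueous	-744.60
HS-	HS	-1	aqueous	12.05
formate	CHO2	-1	aqueous	-351.04
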