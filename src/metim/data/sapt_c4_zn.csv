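# SAPT-derived C4 parameters for Zn(imidazole)(6-n)(H2O)n mixed complexes,
# n = 0..5.  Column 2: C4 from the total induction energy at the equilibrium
# distance; column 3: C4 fitted over the 1.7-3.0 A distance scan.
# Units: kcal/mol*A^4.
system,c4_equilibrium_kcal_mol_A4,c4_scan_fit_kcal_mol_A4
Zn-Im6-Wat0,397.6,339.1
Zn-Im5-Wat1,411.9,347.5
Zn-Im4-Wat2,438.3,370.1
Zn-Im3-Wat3,490.3,428.3
Zn-Im2-Wat4,525.5,473.6
Zn-Im1-Wat5,561.4,512.9
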