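Synthetic LJ + C4 parameter block for the HID imidazole toy (generic AMBER-style LJ values; Zn-NB C4 from the 12-6-4 metal-imidazole parameter set)
NONBON
  NA      1.824000    0.17000000
  NB      1.824000    0.17000000
  CC      1.908000    0.08600000
  CR      1.908000    0.08600000
  CW      1.908000    0.08600000
  HN      0.600000    0.01570000
  HA      1.459000    0.01500000
  Zn      1.395000    0.01491700

C4  (ion  atom_type  C4_kcal_mol_A4)
  Zn2+  NB        424.000000
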