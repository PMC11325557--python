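# Synthetic HID-tautomer imidazole: idealized planar pentagon geometry and
# round-number partial charges that sum to the neutral formal charge.
# These are stand-in values for testing the mol2 subset reader and the toy
# engine, NOT a RESP-fitted charge model.
@<TRIPOS>MOLECULE
HID_imidazole_synthetic
9 9 1 0 0
SMALL
USER_CHARGES
@<TRIPOS>ATOM
      1 ND1         0.0000    1.1650    0.0000 NA     1 HID     -0.360000
      2 CE1        -1.1080    0.3600    0.0000 CR     1 HID      0.200000
      3 NE2        -0.6848   -0.9425    0.0000 NB     1 HID     -0.560000
      4 CD2         0.6848   -0.9425    0.0000 CC     1 HID      0.120000
      5 CG          1.1080    0.3600    0.0000 CW     1 HID     -0.100000
      6 HD1         0.0000    2.1650    0.0000 HN     1 HID      0.320000
      7 HE1        -2.0591    0.6690    0.0000 HA     1 HID      0.140000
      8 HD2         1.2726   -1.7515    0.0000 HA     1 HID      0.110000
      9 HG          2.0591    0.6690    0.0000 HA     1 HID      0.130000
@<TRIPOS>BOND
     1     1     2 1
     2     2     3 1
     3     3     4 1
     4     4     5 1
     5     5     1 1
     6     1     6 1
     7     2     7 1
     8     4     8 1
     9     5     9 1
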