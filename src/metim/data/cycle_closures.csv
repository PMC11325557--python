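# Thermodynamic-cycle closure deviations |DDG| (kcal/mol) for the
# Co(II)-Ni(II) mutation cycle with 1..6 coordinating imidazoles, under
# three parameter sets: extended-sampling multiple-imidazole parameters,
# the earlier one-imidazole-compatible set (extended-sampling PMF), and the
# one-imidazole-compatible set with regular-length PMF sampling.
parameter_set,cycle_index,closure_kcal_mol
extended_sampling,1,0.33
extended_sampling,2,0.18
extended_sampling,3,0.03
extended_sampling,4,0.37
extended_sampling,5,1.11
extended_sampling,6,1.64
one_imidazole_compatible,1,1.40
one_imidazole_compatible,2,2.53
one_imidazole_compatible,3,3.31
one_imidazole_compatible,4,2.62
one_imidazole_compatible,5,0.11
one_imidazole_compatible,6,3.72
one_imidazole_regular_sampling,1,2.05
one_imidazole_regular_sampling,2,3.49
one_imidazole_regular_sampling,3,4.45
one_imidazole_regular_sampling,4,4.45
one_imidazole_regular_sampling,5,1.76
one_imidazole_regular_sampling,6,0.32
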