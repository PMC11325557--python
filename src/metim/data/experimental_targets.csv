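# Experimental metal-imidazole (one imidazole, aqueous) binding free energies
# derived from experimental logK values; units: kcal/mol.
# alpha_seed_A3 is a generic starting polarizability for the parametrization
# loop (a seed choice of this package, not an experimental or literature value).
ion,electronic_configuration,effective_ionic_radius_A,dg_exp_kcal_mol,alpha_seed_A3,source
Ag(I),[Kr]4d10,1.15,-3.98,0.20,thermodynamic compilation
Ca(II),[Ar],1.00,0.16,0.50,thermodynamic compilation
Cd(II),[Kr]4d10,0.95,-3.63,0.50,thermometric titration
Co(II),[Ar]3d7,0.75,-3.36,0.50,potentiometric titration
Cu(I),[Ar]3d10,1.40,-7.89,0.20,thermodynamic compilation
Cu(II),[Ar]3d9,0.73,-5.70,0.50,UV-vis ligand exchange
Fe(II),[Ar]3d6,0.78,-2.46,0.50,thermodynamic compilation
Mg(II),[Ne],0.72,-0.10,0.50,thermodynamic compilation
Mn(II),[Ar]3d5,0.83,-1.64,0.50,thermometric titration
Ni(II),[Ar]3d7,0.69,-4.12,0.50,thermometric titration
Zn(II),[Ar]3d10,0.74,-3.48,0.50,thermometric titration
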