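# CIRS electron-density calibration phantom: assumed molecular compositions
# (mass fractions), manufacturer mass density, manufacturer-derived relative
# electron density, and measured mean HU at 120 kVp kVCT and 3.5 MV MVCT.
# The rho_e column derives from undisclosed manufacturer elemental data and
# is carried as a fixture value only -- it is never recomputed here.
# hu_rho columns are the rounded mass-density-normalized HU as printed; the
# package recomputes them (unrounded) from hu and rho.
name,omega_water,omega_lipid,omega_protein,omega_mineral,rho,rho_e,hu_kv,hu_rho_kv,hu_mv,hu_rho_mv
Adipose,0.30,0.55,0.15,0.00,0.958,0.947,-63,-22,-50,-9
Breast,0.50,0.25,0.25,0.00,0.989,0.974,-31,-20,-24,-13
Liquid Water,1.00,0.00,0.00,0.00,1.000,1.000,0,0,0,0
Solid Water,1.00,0.00,0.00,0.00,1.016,1.000,2,-14,4,-12
Muscle,0.75,0.05,0.20,0.00,1.067,1.047,49,-17,55,-12
Liver,0.75,0.05,0.20,0.00,1.069,1.050,54,-14,58,-11
Trab Bone,0.10,0.40,0.30,0.20,1.164,1.119,247,71,134,-26
Dense Bone (800),0.05,0.20,0.35,0.40,1.613,1.515,910,184,534,-49
Dense Bone (1750),0.03,0.02,0.40,0.55,2.150,1.968,1865,333,1008,-66
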