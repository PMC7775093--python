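# In-house tissue-mimicking phantom: materials mixed from distilled water,
# coconut oil (lipid), porcine gelatin (protein) and hydroxyapatite powder
# (mineral). Ground-truth rho from precision mass/volume measurement
# (+/- 0.002 g/cc), ground-truth rho_e from measured density and CHNO
# combustion elemental analysis. The *_kv1/_mv1 columns are the clinical
# piecewise-linear estimates, *_kv5/_mv5 the molecular-composition-method
# estimates, both from CT imaging of the phantom.
name,omega_water,omega_lipid,omega_protein,omega_mineral,rho,rho_unc,rho_e,rho_e_unc,rho_kv1,rho_e_kv1,rho_kv5,rho_e_kv5,rho_mv1,rho_e_mv1,rho_mv5,rho_e_mv5
Skin,0.75,0.00,0.25,0.00,1.060,0.002,1.048,0.002,1.052,1.033,1.053,1.042,1.065,1.045,1.068,1.057
Muscle,0.75,0.05,0.20,0.00,1.045,0.002,1.036,0.002,1.034,1.017,1.035,1.027,1.051,1.032,1.051,1.042
Adipose,0.47,0.49,0.04,0.00,0.953,0.002,0.955,0.002,0.941,0.931,0.946,0.947,0.970,0.958,0.960,0.961
Spongiosa,0.27,0.47,0.13,0.13,1.060,0.002,1.044,0.002,1.099,1.071,1.065,1.046,1.055,1.036,1.059,1.041
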