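# Reference human tissues with both elemental and molecular (four-component)
# compositions, for regressing the beta coefficients of the electron-ratio
# model and for spectrum-based alpha cross-checks.
# Elemental mass fractions follow the ICRU Report 44 / Woodard & White adult
# tissue compilations; the water/lipid/protein/mineral mass fractions are
# representative literature assignments for the same tissues (the mineral
# axis is hydroxyapatite). Mass fractions are dimensionless and sum to 1
# within rounding of the published tables.
name,omega_water,omega_lipid,omega_protein,omega_mineral,H,C,N,O,Na,Mg,P,S,Cl,K,Ca,Fe
Adipose tissue,0.15,0.80,0.05,0.00,0.114,0.598,0.007,0.278,0.001,0.000,0.000,0.001,0.001,0.000,0.000,0.000
Yellow marrow,0.15,0.80,0.05,0.00,0.115,0.644,0.007,0.231,0.001,0.000,0.000,0.001,0.001,0.000,0.000,0.000
Red marrow,0.40,0.40,0.20,0.00,0.105,0.414,0.034,0.439,0.000,0.000,0.001,0.002,0.002,0.002,0.000,0.001
Skeletal muscle,0.75,0.05,0.19,0.01,0.102,0.143,0.034,0.710,0.001,0.000,0.002,0.003,0.001,0.004,0.000,0.000
Liver,0.71,0.07,0.21,0.01,0.102,0.139,0.030,0.716,0.002,0.000,0.003,0.003,0.002,0.003,0.000,0.000
Skin,0.65,0.10,0.25,0.00,0.100,0.204,0.042,0.645,0.002,0.000,0.001,0.002,0.003,0.001,0.000,0.000
Whole blood,0.80,0.01,0.19,0.00,0.102,0.110,0.033,0.745,0.001,0.000,0.001,0.002,0.003,0.002,0.000,0.001
Brain,0.77,0.11,0.11,0.01,0.107,0.145,0.022,0.712,0.002,0.000,0.004,0.002,0.003,0.003,0.000,0.000
Mammary gland,0.51,0.33,0.15,0.01,0.106,0.332,0.030,0.527,0.001,0.000,0.001,0.002,0.001,0.000,0.000,0.000
Cortical bone,0.10,0.00,0.30,0.60,0.034,0.155,0.042,0.435,0.001,0.002,0.103,0.003,0.000,0.000,0.225,0.000
Spongiosa,0.28,0.35,0.18,0.19,0.085,0.404,0.028,0.367,0.001,0.001,0.034,0.002,0.002,0.001,0.074,0.001
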