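# Default mean / standard deviation for the 12 CEHS helical parameters,
# representative of B-form DNA dimer steps in crystal-structure surveys.
# Translations in Angstrom, rotations in degrees. Override with a user
# table (HelicalParamTable.from_yaml) for any other regime.
shear:     {mean: 0.00,  sd: 0.21}
stretch:   {mean: -0.15, sd: 0.12}
stagger:   {mean: 0.09,  sd: 0.19}
buckle:    {mean: 0.5,   sd: 6.7}
propeller: {mean: -11.4, sd: 5.3}
opening:   {mean: 0.6,   sd: 3.1}
shift:     {mean: 0.00,  sd: 0.45}
slide:     {mean: 0.23,  sd: 0.81}
rise:      {mean: 3.32,  sd: 0.19}
tilt:      {mean: 0.0,   sd: 2.5}
roll:      {mean: 0.6,   sd: 5.2}
twist:     {mean: 36.0,  sd: 5.9}
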