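# Registered synthetic scenarios encoding the pH x NaCl phase behaviour of
# HUaa-80bp DNA (and the E34K charge mutant) in solution.
#
# kind = "lamellar":  lamellar-stack Caille curve with repeat spacing d_A
# kind = "filament":  Debye curve of a saturated HU-coated 80 bp duplex
# kind = "aggregate": featureless steep power-law decay (exponent -3.5)
#
# Shared lamellar nuisance parameters (the experiments constrain only the
# spacing and the phase label): n_plates = 20, eta = 0.1, delta_A = 20,
# poly_delta = 0.05. Default relative noise 1 %.

[defaults]
n_plates = 20
eta = 0.1
delta_A = 20.0
poly_delta = 0.05
noise_frac = 0.01
aggregate_exponent = -3.5

[scenarios.pH4_5_50mM]
expected_label = "lamellar"
kind = "lamellar"
d_A = 42.0
seed = 110450

[scenarios.pH4_5_100mM]
expected_label = "lamellar"
kind = "lamellar"
d_A = 42.0
seed = 110451

[scenarios.pH4_5_150mM]
expected_label = "lamellar"
kind = "lamellar"
d_A = 42.0
seed = 110452

[scenarios.pH4_5_300mM]
expected_label = "filament"
kind = "filament"
seed = 110453

[scenarios.pH5_5_50mM]
expected_label = "lamellar"
kind = "lamellar"
d_A = 60.0
seed = 110454

[scenarios.pH5_5_100mM]
expected_label = "lamellar"
kind = "lamellar"
d_A = 70.0
seed = 110455

[scenarios.pH5_5_150mM]
expected_label = "lamellar"
kind = "lamellar"
d_A = 42.0
seed = 110456

[scenarios.pH5_5_300mM]
expected_label = "filament"
kind = "filament"
seed = 110457

[scenarios.pH6_5_50mM]
expected_label = "lamellar"
kind = "lamellar"
d_A = 60.0
seed = 110458

[scenarios.pH6_5_150mM]
expected_label = "filament"
kind = "filament"
seed = 110459

[scenarios.pH6_5_300mM]
expected_label = "filament"
kind = "filament"
seed = 110460

[scenarios.pH7_5_50mM]
expected_label = "lamellar"
kind = "lamellar"
d_A = 60.0
seed = 110461

[scenarios.E34K_pH4_5]
expected_label = "aggregate"
kind = "aggregate"
seed = 110462

[scenarios.E34K_pH5_5]
expected_label = "aggregate"
kind = "aggregate"
seed = 110463

[scenarios.E34K_pH6_5]
expected_label = "filament"
kind = "filament"
seed = 110464
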