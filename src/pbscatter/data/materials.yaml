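# Built-in material definitions for the collimated scanning-nozzle model.
#
# Fields per material:
#   density                  [g/cm^3]   bulk density (ABS density is recalibrated
#                                       at runtime against the range-energy
#                                       anchors of the energy absorber; the value
#                                       below is the nominal starting point)
#   mean_excitation_energy   [eV]       I-value entering the Bethe formula
#   Z_over_A                 [mol/g]    ratio of atomic number to atomic mass,
#                                       mass-averaged over the composition
#   radiation_length         [g/cm^2]   X0, mass-averaged (1/X0 = sum w_i/X0_i)
#   nuclear_interaction_length [g/cm^2] mass length for primary-proton removal
#                                       by nonelastic nuclear reactions
#   composition                         informational only
#
# Brass is modelled as Cu70/Zn30 by mass; the collimator alloy is not a
# published machine constant.  ABS is C15H17N.  Air is dry air at NTP.
water:
  density: 1.0
  mean_excitation_energy: 75.0
  Z_over_A: 0.55509
  radiation_length: 36.08
  nuclear_interaction_length: 85.0
  composition: H2O
air:
  density: 1.205e-3
  mean_excitation_energy: 85.7
  Z_over_A: 0.49919
  radiation_length: 36.62
  nuclear_interaction_length: 85.0
  composition: N2/O2/Ar (NTP)
abs_plastic:
  density: 1.05
  mean_excitation_energy: 63.5
  Z_over_A: 0.53950
  radiation_length: 43.48
  nuclear_interaction_length: 85.0
  composition: C15H17N
brass:
  density: 8.52
  mean_excitation_energy: 324.4
  Z_over_A: 0.45711
  radiation_length: 12.73
  nuclear_interaction_length: 85.0
  composition: Cu70/Zn30 by mass
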