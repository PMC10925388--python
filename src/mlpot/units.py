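"""Energy-unit constants for the physical priors.

The learned part of a potential is unit-agnostic (it matches whatever unit
the training energies carry), but the analytic priors need explicit
constants.  Defaults are given in eV / Å / elementary charge; datasets in
other units supply their own constants through the prior configuration.
"""

#: Coulomb constant e^2 / (4 pi eps0), in eV * Angstrom / e^2
COULOMB_CONSTANT_EV = 14.399645

#: conversion of Grimme C6 tables (J nm^6 mol^-1) to eV Angstrom^6
D2_C6_JNM6_TO_EV = 1.0e6 / 96485.33212
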