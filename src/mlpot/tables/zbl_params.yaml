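# Ziegler-Biersack-Littmark universal screening function parameters.
# phi(x) = sum_i c_i * exp(-e_i * x); screening length a = a0 / (Zi^p + Zj^p)
coefficients: [0.18175, 0.50986, 0.28022, 0.02817]
exponents: [3.19980, 0.94229, 0.40290, 0.20162]
length_prefactor: 0.46850   # Angstrom (0.8854 * Bohr radius)
length_exponent: 0.23
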