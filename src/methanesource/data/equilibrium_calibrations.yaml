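# Equilibrium clumped-methane calibrations.
#
# Each entry gives polynomial coefficients (ascending powers of 1/T, T in
# kelvin, constant term first) for the equilibrium clumped anomalies
# Delta-13CH3D and Delta-12CH2D2 in permil, i.e.
#   Delta(T) = c0 + c1/T + c2/T^2 + ...
# equal to 1000*ln(K) for the respective isotope-exchange equilibrium.
#
# eldridge2019: polynomial fits to theoretical (Bigeleisen-Mayer with
# corrections) equilibrium constants for the exchange reactions
#   13CH4 + 12CH3D = 13CH3D + 12CH4   and
#   2 12CH3D = 12CH2D2 + 12CH4,
# as published by Eldridge et al., ACS Earth Space Chem. 3 (2019) 2747-2764.
# Anchor values: Delta13CH3D(25 C) = 5.81 permil, Delta12CH2D2(25 C) = 19.36
# permil, both -> 0 as T -> infinity. Fit range 270-1300 K; values above
# 1000 K are a smooth extrapolation of the fit.
eldridge2019:
  citation: "Eldridge et al. 2019, ACS Earth & Space Chemistry 3:2747-2764"
  valid_T_range_K: [273.15, 1273.15]
  coefficients_13CH3D:
    [0.0, 8.89370e2, -3.49294e6, 5.54476e9, -3.54757e12, 1.19810e15,
     -2.08648e17, 1.47348e19]
  coefficients_12CH2D2:
    [0.0, 1.86258e3, -4.48660e6, 4.30283e9, -1.24819e12, 1.71917e14,
     -9.67634e15]
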