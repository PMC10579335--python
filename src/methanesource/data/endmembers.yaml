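# Default methane source endmembers for the two-endmember mixing models.
#
# These are RECONSTRUCTIONS placed at the centroids of literature source
# fields for sedimentary basins (microbial: CO2-reduction-dominated marine
# sediment methane, e.g. Whiticar 1999; thermogenic: early-to-late maturity
# sedimentary gas, e.g. Milkov & Etiope 2018; abiotic: serpentinization /
# geothermal gas fields, e.g. Young et al. 2017, Etiope & Sherwood Lollar
# 2013). Clumped (Delta) centrals follow the observed pattern of
# near-equilibrium low-temperature microbial methane vs. higher-temperature
# thermogenic equilibrium vs. frequently anti-clumped abiotic methane.
# All values permil; ranges bound the uniform Monte-Carlo sampling box.
microbial:
  central: {d13C: -75.0, dD: -200.0, D13CH3D: 4.8, D12CH2D2: 10.0}
  low:     {d13C: -90.0, dD: -240.0, D13CH3D: 3.0, D12CH2D2: 4.0}
  high:    {d13C: -60.0, dD: -170.0, D13CH3D: 6.0, D12CH2D2: 18.0}
thermogenic:
  central: {d13C: -42.0, dD: -160.0, D13CH3D: 2.2, D12CH2D2: 6.0}
  low:     {d13C: -50.0, dD: -200.0, D13CH3D: 1.0, D12CH2D2: 3.0}
  high:    {d13C: -32.0, dD: -120.0, D13CH3D: 3.2, D12CH2D2: 9.0}
abiotic:
  central: {d13C: -30.0, dD: -130.0, D13CH3D: 0.5, D12CH2D2: -8.0}
  low:     {d13C: -40.0, dD: -160.0, D13CH3D: -1.5, D12CH2D2: -20.0}
  high:    {d13C: -20.0, dD: -100.0, D13CH3D: 2.0, D12CH2D2: 2.0}
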