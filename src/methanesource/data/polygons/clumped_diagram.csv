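# Genetic source fields in clumped-isotopologue space:
# x = Delta-13CH3D (permil), y = Delta-12CH2D2 (permil).
# Approximate RECONSTRUCTIONS of fields compiled from natural and laboratory
# methane (Young et al. 2017; Giunta et al. 2019; Taenzer et al. 2020):
# microbial methane spans near-equilibrium low-T values down to strongly
# anti-clumped culture values; thermogenic gas clusters near 100-250 C
# equilibrium; abiotic gas trends to low / negative values of both.
label,x,y
microbial,-6.0,-50.0
microbial,6.5,-50.0
microbial,6.5,22.0
microbial,-6.0,22.0
thermogenic-EMT,1.8,3.0
thermogenic-EMT,4.2,3.0
thermogenic-EMT,4.2,14.0
thermogenic-EMT,1.8,14.0
thermogenic-LMT,0.5,1.0
thermogenic-LMT,2.5,1.0
thermogenic-LMT,2.5,8.0
thermogenic-LMT,0.5,8.0
abiotic-SA,-4.0,-25.0
abiotic-SA,2.0,-25.0
abiotic-SA,2.0,5.0
abiotic-SA,-4.0,5.0
abiotic-GA,-1.0,-10.0
abiotic-GA,3.0,-10.0
abiotic-GA,3.0,6.0
abiotic-GA,-1.0,6.0
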