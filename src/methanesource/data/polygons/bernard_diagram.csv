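# Genetic source fields on the Bernard diagram: x = d13C (permil VPDB),
# y = log10(C1/(C2+C3)). Approximate RECONSTRUCTIONS of the classic
# empirical fields (Bernard et al. 1978; Milkov & Etiope 2018).
label,x,y
microbial,-90,2.0
microbial,-55,2.0
microbial,-55,5.0
microbial,-90,5.0
thermogenic-EMT,-55,0.0
thermogenic-EMT,-40,0.0
thermogenic-EMT,-40,2.3
thermogenic-EMT,-55,2.3
thermogenic-LMT,-40,0.0
thermogenic-LMT,-20,0.0
thermogenic-LMT,-20,1.8
thermogenic-LMT,-40,1.8
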