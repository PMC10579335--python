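# Genetic source fields in bulk-isotope (CD) space: x = d13C (permil VPDB),
# y = dD (permil VSMOW). Vertices are ordered; each label forms one simple
# polygon. These are approximate RECONSTRUCTIONS of published empirical
# fields (Whiticar 1999; Milkov & Etiope 2018), digitized coarsely for
# classification, not for display fidelity.
label,x,y
microbial,-110,-450
microbial,-50,-450
microbial,-50,-150
microbial,-110,-150
thermogenic-EMT,-60,-320
thermogenic-EMT,-44,-320
thermogenic-EMT,-44,-180
thermogenic-EMT,-60,-180
thermogenic-LMT,-45,-250
thermogenic-LMT,-25,-250
thermogenic-LMT,-25,-100
thermogenic-LMT,-45,-100
abiotic-SA,-42,-470
abiotic-SA,-5,-470
abiotic-SA,-5,-290
abiotic-SA,-42,-290
abiotic-GA,-30,-250
abiotic-GA,-10,-250
abiotic-GA,-10,-100
abiotic-GA,-30,-100
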