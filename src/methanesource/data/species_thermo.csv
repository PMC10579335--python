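# Standard-state thermodynamic properties of aqueous species at 25 C, 1 bar.
# dGf_kJ / dHf_kJ: standard Gibbs energy / enthalpy of formation, kJ/mol.
# Sources: AS01 = Amend & Shock (2001) FEMS Microbiol Rev 25:175-243;
# CODATA = Cox, Wagman & Medvedev (1989); NBS = Wagman et al. (1982);
# est = estimated from gas-phase values and analogue Henry corrections.
species,phase,charge,dGf_kJ,dHf_kJ,source
H2,aq,0,17.72,-4.04,AS01
CO2,aq,0,-385.97,-413.80,AS01
CH4,aq,0,-34.45,-87.91,AS01
H2O,l,0,-237.18,-285.83,CODATA
H+,aq,1,0.0,0.0,convention
acetate,aq,-1,-369.32,-486.01,AS01
formate,aq,-1,-350.88,-425.43,AS01
methanol,aq,0,-175.31,-246.00,AS01
methylamine,aq,0,20.77,-70.17,NBS
dimethylamine,aq,0,38.90,-72.40,est
trimethylamine,aq,0,43.10,-76.00,est
NH4+,aq,1,-79.37,-133.26,CODATA
DMS,aq,0,6.50,-60.00,est
HS-,aq,-1,12.05,-16.30,AS01
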