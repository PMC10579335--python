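# Concentration ranges (mol/kg) for catabolic substrates that are not
# routinely measured in porewater. Minimums are typical limits of detection;
# maximums are from published porewater studies of organic-rich marine
# sediments (acetate/formate: e.g. Glombitza et al. 2015; methanol and
# methylamines: e.g. Zhuang et al. 2014, 2017; DMS: Zhuang et al. 2017).
acetate:        {min: 1.0e-6, max: 4.0e-3}
formate:        {min: 1.0e-7, max: 1.0e-4}
methanol:       {min: 1.0e-8, max: 6.9e-5}
methylamine:    {min: 1.0e-8, max: 1.0e-5}
dimethylamine:  {min: 1.0e-8, max: 1.0e-5}
trimethylamine: {min: 1.0e-8, max: 1.0e-5}
DMS:            {min: 1.0e-9, max: 1.0e-6}
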