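species,tautomer,gas_rel_free_energy_kJmol,hydration_free_energy_kJmol
1a1,a,0,-72.0
1a2,a,-0.7,-67.8
1a3,a,3.2,-62.3
1b1,b,-3.8,-75.3
1b2,b,-3.6,-71.1
1b3,b,6.5,-76.6
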