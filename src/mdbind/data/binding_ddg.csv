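system,ddg_300K_kJmol,se_300K_kJmol,ddg_323K_kJmol,se_323K_kJmol
1a,16,12,11,16
1b,0,0,3,16
2,79,26,75,26
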