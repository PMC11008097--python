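dimer_id,energy_kJ_mol
0,-0.3563708140143724
1,-0.717725732219946
2,-0.3563708140143724
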