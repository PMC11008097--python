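dimer_id,mol_i,mol_j,tx,ty,tz,min_distance_A,multiplicity,pair_energy_kJ_mol
0,0,0,-1,0,0,5.0,6,-0.3563708140143724
1,0,1,-1,-1,-1,4.330127018922194,16,-0.717725732219946
2,1,1,-1,0,0,5.0,6,-0.3563708140143724
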