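# level: high
# z_molecules: 4
# units: kJ/mol
volume_A3,energy
828.0,34.394032876454276
874.0000000000001,7.683845146104204
920.0,0.0
966.0,6.289004944664839
1012.0000000000001,22.996260806391774
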