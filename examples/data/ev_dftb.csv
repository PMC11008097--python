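# level: low
# z_molecules: 4
# units: kJ/mol
volume_A3,energy
753.48,46.94785487636
795.3400000000001,10.488448624432294
837.2,0.0
879.0600000000001,8.584491749467588
920.9200000000001,31.389896000725457
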