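substrate,SMD,PCM,COSMO
QD-01,18.2,18.5,18.7
QD-03,17.6,17.9,18.1
QD-05,16.9,17.2,17.4
QD-07,17.2,17.5,17.7
QD-09,18.4,18.7,18.9
QD-11,16.5,16.8,17.0
QD-13,17.4,17.7,17.9
QD-15,18.9,19.2,19.4
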