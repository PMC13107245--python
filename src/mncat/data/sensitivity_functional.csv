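substrate,B3LYP,M06-2X,PBE0,B97XD
QD-01,18.2,18.5,18.8,19.1
QD-03,17.6,17.9,18.2,18.5
QD-05,16.9,17.3,17.7,17.9
QD-07,17.2,17.6,18.0,18.3
QD-09,18.4,18.7,19.1,19.4
QD-11,16.5,16.8,17.2,17.5
QD-13,17.4,17.7,18.1,18.4
QD-15,18.9,19.2,19.6,19.9
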