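substrate,+1,+2,+3
QD-01,19.8,18.2,20.5
QD-03,19.1,17.6,19.8
QD-05,18.3,16.9,19.0
QD-07,18.7,17.2,19.4
QD-09,20.1,18.4,20.8
QD-11,18.5,16.5,19.2
QD-13,19.0,17.4,19.7
QD-15,20.5,18.9,21.2
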