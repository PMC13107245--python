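substrate,"6-311++G(d,p)",def2-TZVP,cc-pVTZ
QD-01,18.2,18.3,18.4
QD-03,17.6,17.7,17.8
QD-05,16.9,17.0,17.1
QD-07,17.2,17.3,17.4
QD-09,18.4,18.5,18.6
QD-11,16.5,16.6,16.7
QD-13,17.4,17.5,17.6
QD-15,18.9,19.0,19.1
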