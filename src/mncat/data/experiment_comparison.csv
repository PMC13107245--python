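substrate,calculated,experimental,absolute_error,relative_error_pct
QD-01,18.2,18.5,0.3,1.6
QD-03,17.6,17.9,0.3,1.7
QD-05,16.9,17.3,0.4,2.3
QD-07,17.2,17.6,0.4,2.3
QD-09,18.4,18.8,0.4,2.1
QD-11,16.5,16.9,0.4,2.4
QD-13,17.4,17.8,0.4,2.2
QD-15,18.9,19.3,0.4,2.1
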