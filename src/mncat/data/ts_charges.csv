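substrate,C,N,Mn,O
QD-01,0.12,-0.31,1.82,-0.42
QD-03,0.09,-0.28,1.79,-0.39
QD-05,0.15,-0.33,1.85,-0.45
QD-07,0.11,-0.29,1.81,-0.41
QD-09,0.08,-0.27,1.78,-0.38
QD-11,0.13,-0.30,1.83,-0.43
QD-13,0.10,-0.26,1.80,-0.40
QD-15,0.07,-0.25,1.77,-0.37
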