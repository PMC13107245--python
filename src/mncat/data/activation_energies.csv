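substrate,enzyme_only,metal_only,synergistic,reduction_pct
QD-01,28.5,23.7,18.2,36.1
QD-02,31.2,25.9,19.8,36.5
QD-03,29.8,24.3,17.6,40.9
QD-04,30.1,26.4,20.3,32.6
QD-05,27.9,22.8,16.9,39.4
QD-06,32.4,27.1,21.5,33.6
QD-07,28.7,23.5,17.2,40.1
QD-08,31.5,26.8,20.7,34.3
QD-09,29.3,24.1,18.4,37.2
QD-10,30.9,25.6,19.1,38.2
QD-11,27.6,22.3,16.5,40.2
QD-12,31.8,26.5,20.9,34.3
QD-13,28.2,23.1,17.4,38.3
QD-14,30.5,25.2,19.6,35.7
QD-15,29.7,24.6,18.9,36.4
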