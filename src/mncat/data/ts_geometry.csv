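parameter,minimum,maximum,average,standard_deviation
C-N bond length (A),1.78,2.05,1.92,0.07
Mn-O bond length (A),1.95,2.18,2.06,0.05
Bond angle theta (deg),108.3,122.7,115.4,3.2
Dihedral angle phi (deg),-45.6,52.3,8.7,24.1
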