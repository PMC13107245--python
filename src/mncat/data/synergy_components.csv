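substrate,electrostatic,hydrogen_bond,van_der_waals,total
QD-01,-15.2,-8.3,-4.1,-27.6
QD-03,-14.7,-7.9,-3.8,-26.4
QD-05,-16.1,-8.7,-4.3,-29.1
QD-07,-15.8,-8.5,-4.2,-28.5
QD-09,-14.9,-7.8,-3.7,-26.4
QD-11,-15.5,-8.4,-4.0,-27.9
QD-13,-15.0,-7.7,-3.6,-26.3
QD-15,-14.6,-7.5,-3.5,-25.6
Average value,-15.3,-8.2,-4.0,-27.5
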