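mode,calculated,experimental,deviation
C-N stretching,1725,1718,7
Mn-O stretching,480,475,5
Substrate C-H bending,1450,1443,7
Enzyme backbone vibration,1250,1245,5
Substrate O-H stretching,3650,3642,8
Metal coordination vibration,620,615,5
Aromatic ring breathing vibration,1580,1575,5
Hydrogen bond vibration,3200,3192,8
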