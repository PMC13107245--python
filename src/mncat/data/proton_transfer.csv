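path,donor_acceptor_distance,transfer_rate_1e3_per_s,barrier
PT-01,2.8,1.2,3.5
PT-02,3.1,0.98,4.1
PT-03,2.9,1.1,3.8
PT-04,3.0,1.0,3.9
PT-05,2.7,1.3,3.3
PT-06,3.2,0.95,4.2
PT-07,2.6,1.4,3.1
PT-08,3.3,0.92,4.3
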