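element,monoisotopic_mass,nominal_mass,valence
C,12.0,12,4
H,1.00782503,1,1
N,14.00307401,14,3
O,15.99491462,16,2
S,31.97207117,32,2
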