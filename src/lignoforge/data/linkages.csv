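name,left_vertex,bridge,right_vertex,symmetric,directions,endgroup_requires,monomer_requires,endgroup_consumes,monomer_consumes,deltaC,deltaH,deltaN,deltaO,deltaS,terminator
b-O-4,b,O,4,false,both,vinyl_available,phenol4_available,vinyl_available,phenol4_available,0,0,0,1,0,false
a-O-4,a,O,4,false,both,vinyl_available,phenol4_available,vinyl_available,phenol4_available,0,0,0,1,0,false
b-b,b,,b,true,forward,vinyl_available,vinyl_available,vinyl_available,vinyl_available,0,-2,0,0,0,false
b-5,b,,5,false,both,vinyl_available,ring5_open;phenol4_available,vinyl_available,ring5_open;phenol4_available,0,-2,0,0,0,false
5-5,5,,5,true,forward,ring5_open,ring5_open,ring5_open,ring5_open,0,-2,0,0,0,false
5-O-4,5,O,4,false,both,ring5_open,phenol4_available,ring5_open,phenol4_available,0,-2,0,0,0,false
b-1,b,,1,false,forward,vinyl_available,sidechain_intact,vinyl_available,sidechain_intact;vinyl_available,-3,-4,0,0,0,true
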