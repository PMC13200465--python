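symbol,name,C,H,N,O,S,vinyl_available,phenol4_available,ring5_open,sidechain_intact,tags,ring_pattern,sidechain_class,substituent_class
HYpeol,p-coumaryl alcohol residue,9,10,0,2,0,true,true,true,true,H;canonical,HY,pe,ol
GUpeol,coniferyl alcohol residue,10,12,0,3,0,true,true,true,true,G;canonical,GU,pe,ol
SYpeol,sinapyl alcohol residue,11,14,0,4,0,true,true,false,true,S;canonical,SY,pe,ol
HYpeal,p-coumaraldehyde residue,9,8,0,2,0,true,true,true,true,H;modified,HY,pe,al
GUpeal,coniferaldehyde residue,10,10,0,3,0,true,true,true,true,G;modified,GU,pe,al
SYpeal,sinapaldehyde residue,11,12,0,4,0,true,true,false,true,S;modified,SY,pe,al
HYpeac,p-coumaric acid residue,9,8,0,3,0,true,true,true,true,H;modified,HY,pe,ac
GUpeac,ferulic acid residue,10,10,0,4,0,true,true,true,true,G;modified,GU,pe,ac
SYpeac,sinapic acid residue,11,12,0,5,0,true,true,false,true,S;modified,SY,pe,ac
GUmeal,vanillin residue,8,8,0,3,0,false,true,true,false,G;modified,GU,me,al
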