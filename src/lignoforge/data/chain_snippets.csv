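role,chain_class,substituent,template
free,pe,*,C({R})=C{T}
free,me,ol,C({R})O
free,me,al,C({R})=O
free,me,ac,C({R})(=O)O
bO4,pe,*,C({R})(O)C{b1}{T}
aO4,pe,*,C{b1}({R})C(O){T}
bb_left,pe,ol,C({R})(O{b3})C{b1}C{b2}
bb_right,pe,ol,C({R})(O{b2})C{b1}C{b3}
b5,pe,*,C{b2}({R})C{b1}{T}
b1,pe,*,C({R})(O)C{b1}{T}
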