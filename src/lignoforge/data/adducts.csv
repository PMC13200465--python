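label,charge,mass_shift
[M+H]+,1,1.00727646
[M+Na]+,1,22.98922070
[M-H]-,-1,-1.00727646
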