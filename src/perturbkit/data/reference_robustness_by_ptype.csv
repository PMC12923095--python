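ptype,increase,stable,decrease,catastrophic
typographical,4,11,9,0
homophone,1,16,7,0
redaction,0,8,12,4
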