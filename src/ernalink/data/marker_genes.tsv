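gene	state
Cd38	ifng
Cxcl9	ifng
Cxcl10	ifng
Cxcl11	ifng
Nos2	ifng
Ptgs2	ifng
Socs3	ifng
Tnf	ifng
Arg1	il4il13
Ccl24	il4il13
Egr2	il4il13
Fn1	il4il13
Igf1	il4il13
Irf4	il4il13
Mrc1	il4il13
Socs2	il4il13
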