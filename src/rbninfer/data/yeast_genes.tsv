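gene	self_degradation
Cln3	1
MBF	0
SBF	0
Cln1	1
Cdh1	0
Swi5	1
Cdc20	1
Clb5	0
Sic1	0
Clb1	0
Mcm1	1
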