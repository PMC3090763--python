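target	regulator	sign
MBF	Cln3	1
MBF	Clb1	-1
SBF	Cln3	1
SBF	Clb1	-1
Cln1	SBF	1
Cdh1	Cln1	-1
Cdh1	Cdc20	1
Cdh1	Clb5	-1
Cdh1	Clb1	-1
Swi5	Cdc20	1
Swi5	Clb1	-1
Swi5	Mcm1	1
Cdc20	Clb1	1
Cdc20	Mcm1	1
Clb5	MBF	1
Clb5	Cdc20	-1
Clb5	Sic1	-1
Sic1	Cln1	-1
Sic1	Swi5	1
Sic1	Cdc20	1
Sic1	Clb5	-1
Sic1	Clb1	-1
Clb1	Cdh1	-1
Clb1	Cdc20	-1
Clb1	Clb5	1
Clb1	Sic1	-1
Clb1	Mcm1	1
Mcm1	Clb5	1
Mcm1	Clb1	1
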