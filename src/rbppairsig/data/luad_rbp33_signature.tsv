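gene_a	gene_b	coefficient
WDR46	RAE1	-0.29314
SNRPA1	PABPC1L	0.248844
INTS8	SKIV2L	0.039139
DCAF13	SMAD9	0.048633
WDR4	PARS2	0.622802
MRPS12	DCP1A	0.019737
IGF2BP1	PABPC3	0.04353
IGF2BP1	SRSF12	0.214354
IGF2BP1	ZC3H12D	0.047965
IGF2BP3	RPP40	0.030426
IGF2BP3	OASL	0.098828
SLU7	DDX24	0.295423
MAGOHB	PARS2	0.207791
MRPL38	TSEN54	0.1538
DDX52	STRBP	0.012441
MRPL54	OAS1	-0.05311
MRPL54	DDX56	-0.20468
MRPL54	BZW2	-0.12583
SKIV2L	MRPS24	-0.22893
SKIV2L	DCPS	-0.11877
OAS1	POP7	0.014735
RNPC3	ERI2	-0.05978
DNMT3B	ZC3H8	0.139235
SMAD9	ERI2	-0.09502
TDRKH	URB1	-0.13488
TDRKH	ZC3HAV1L	-0.01879
TDRKH	ZC3H12C	-0.25482
PPIL4	DARS2	-0.37219
TFB2M	RBPMS	0.029924
DARS2	HINT3	0.126521
PABPC3	ZC3H12D	0.157939
FASTK	SPATS2	-0.04858
FASTKD3	ZC3H12C	-0.06448
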