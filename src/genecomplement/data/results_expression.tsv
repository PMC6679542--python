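gene	nucleus	assay	call	sparse
SCN1A	RA	ish	higher	0
SCN1A	HVC	ish	higher	0
SCN1A	LMAN	ish	higher	0
SCN1A	AreaX	ish	higher	0
SCN1A	DLM	ish	higher	0
SCN2A	RA	ish	lower	0
SCN2A	AreaX	ish	lower	0
SCN2A	LMAN	ish	lower	0
SCN2A	DLM	ish	lower	0
SCN2A	HVC	ish	nondifferential	0
SCN3A	RA	ish	lower	0
SCN3A	HVC	ish	lower	0
SCN3A	LMAN	ish	lower	0
SCN8A	RA	ish	higher	0
SCN8A	HVC	ish	higher	0
SCN5A	RA	ish	nondifferential	0
SCN5A	HVC	ish	nondifferential	0
SCN5A	AreaX	ish	nondifferential	0
SCN5A	LMAN	ish	nondifferential	0
SCN5A	nXIIts	ish	nondifferential	0
SCN9A	RA	ish	nondifferential	0
SCN9A	HVC	ish	nondifferential	0
SCN9A	AreaX	ish	nondifferential	0
SCN9A	LMAN	ish	nondifferential	0
SCN9A	nXIIts	ish	higher	0
SCN1B	HVC	ish	higher	0
SCN1B	RA	ish	higher	0
SCN1B	AreaX	ish	higher	0
SCN1B	LMAN	ish	higher	0
SCN1B	NIf	ish	higher	0
SCN1B	DLM	ish	higher	0
SCN2B	RA	ish	nondifferential	0
SCN2B	AreaX	ish	nondifferential	0
SCN2B	LMAN	ish	nondifferential	0
SCN2B	HVC	ish	higher	0
SCN3B	HVC	ish	lower	0
SCN3B	RA	ish	lower	0
SCN3B	AreaX	ish	lower	1
SCN3B	LMAN	ish	lower	0
SCN3B	nXIIts	ish	higher	0
SCN4B	RA	ish	higher	0
SCN4B	HVC	ish	higher	0
SCN4B	LMAN	ish	higher	0
ASIC1	AreaX	ish	lower	0
ASIC4	AreaX	ish	lower	0
ASIC2	nXIIts	ish	lower	0
NALCN	AreaX	ish	lower	0
CACNA1C	AreaX	ish	higher	0
CACNA1C	nXIIts	ish	higher	0
CACNA1D	RA	ish	lower	0
CACNA1D	AreaX	ish	lower	0
CACNA1D	LMAN	ish	lower	0
CACNA1E	RA	ish	lower	0
CACNA1E	LMAN	ish	lower	0
CACNA1B	HVC	ish	higher	0
CACNA1B	AreaX	ish	higher	1
CACNA1G	RA	ish	lower	0
CACNA1H	RA	ish	lower	0
CACNA1I	RA	ish	lower	0
CACNA1I	HVC	ish	higher	0
CACNA2D1	HVC	ish	lower	0
CACNA2D1	LMAN	ish	lower	0
CACNA2D2	HVC	ish	higher	0
CACNA2D2	LMAN	ish	higher	0
CACNA2D2	RA	ish	higher	0
CACNA2D2	AreaX	ish	nondifferential	1
CACNA2D3	AreaX	ish	higher	0
CACNB2	RA	ish	lower	0
CACNB2	HVC	ish	lower	0
CACNB2	LMAN	ish	lower	0
CACNB2	DLM	ish	higher	0
CACNB3	HVC	ish	higher	0
CACNB3	LMAN	ish	higher	0
CACNB4	HVC	ish	higher	0
CACNB4	AreaX	ish	higher	0
CACNG5	LMAN	ish	lower	0
CACNG5	AreaX	ish	higher	1
CACNG5	Uva	ish	higher	0
CACNG3	AreaX	ish	lower	0
CACNG3	LMAN	ish	lower	0
CACNG4	HVC	ish	lower	0
CACNG4	LMAN	ish	lower	0
CACNG4	AreaX	ish	lower	0
CACNG4	nXIIts	ish	higher	0
CACNG7	RA	ish	higher	0
CACNG7	HVC	ish	higher	0
CACNG7	AreaX	ish	higher	0
RYR2	HVC	ish	higher	0
RYR2	AreaX	ish	higher	0
RYR2	LMAN	ish	higher	0
RYR3	HVC	ish	higher	0
TPCN1	HVC	ish	higher	0
TPCN2	HVC	ish	higher	0
ITPR1	nXIIts	ish	lower	0
ITPR2	nXIIts	ish	lower	0
ITPR3	nXIIts	ish	lower	0
ANO5	HVC	ish	higher	0
ANO5	RA	ish	higher	0
CLIC4	HVC	ish	higher	0
CLIC4	RA	ish	higher	0
CLNS1A	HVC	ish	higher	0
LRRC8A	RA	ish	lower	0
LRRC8A	AreaX	ish	lower	0
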