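family	gene	annotated_models	novel_models	taegut_coords	pacbio_locus	found_via	synteny	aligned_fraction	scaffold_gapless	completeness_flag	markers
sodium	SCN1A		ENSTGUG00000007356			human-query	direct	0.95	0	0	caret
sodium	SCN2A		ENSTGUG00000007152			human-query	direct	0.95	0	1	caret,star
sodium	SCN3A	ENSTGUG00000007034				human-query	direct	0.95	0	0
sodium	SCN4A	ENSTGUG00000003230				human-query	direct	0.95	0	0
sodium	SCN5A		ENSTGUG00000000531;ENSTGUG00000000533			human-query	direct	0.95	0	0	caret
sodium	SCN8A	ENSTGUG00000003307				human-query	direct	0.95	0	0
sodium	SCN9A		ENSTGUG00000007470			human-query	direct	0.95	0	1	caret,star
sodium	SCN10A		ENSTGUG00000000476			human-query	direct	0.95	0	1	caret,star
sodium	SCN11A			chr2:5686797-5719627		human-query	direct	0.95	0	0
sodium	SCN1B				MUGN01000920.1:818309-818447	human-query	phylo-linked	0.95	1	0	dollar
sodium	SCN2B	ENSTGUG00000017358			MUGN01000074.1:2766152-2766960	human-query	direct	0.95	1	0
sodium	SCN3B		ENSTGUG00000000607			human-query	direct	0.95	0	0	caret
sodium	SCN4B	ENSTGUG00000000230			MUGN01000074.1:2777132-2778696	human-query	direct	0.95	1	0
sodium	ASIC1	ENSTGUG00000003637				human-query	direct	0.95	0	0
sodium	ASIC2		ENSTGUG00000003212;ENSTGUG00000003215			human-query	unresolved	0.95	0	1	caret,star,hash
sodium	ASIC3		ENSTGUG00000016020		MUGN01000217.1:876923-883599	other-species-query	direct	0.95	1	1	caret,star,diamond
sodium	ASIC4	ENSTGUG00000006157				human-query	direct	0.95	0	1	star
sodium	ASIC5	ENSTGUG00000005392				other-species-query	direct	0.95	0	0	diamond
sodium	NALCN	ENSTGUG00000010876				human-query	direct	0.95	0	0
sodium	SCNN1A	ENSTGUG00000013342				other-species-query	phylo-linked	0.95	0	1	star,diamond,dollar
sodium	SCNN1B	ENSTGUG00000005936				human-query	direct	0.95	0	0
sodium	SCNN1D	ENSTGUG00000004091				other-species-query	direct	0.95	0	0	diamond
sodium	SCNN1G			chr14:8747853-8755433		human-query	direct	0.95	0	0
calcium	CACNA1S	ENSTGUG00000001142				human-query	direct	0.95	0	1	star
calcium	CACNA1C		ENSTGUG00000012529;ENSTGUG00000012538			human-query	direct	0.95	0	0	caret
calcium	CACNA1D	ENSTGUG00000006839				human-query	direct	0.95	0	1	star
calcium	CACNA1F				MUGN01000244.1:40490-59194	human-query	direct	0.95	1	0
calcium	CACNA1A				MUGN01001147.1:274884-306034	human-query	direct	0.95	1	0
calcium	CACNA1B	ENSTGUG00000002855				human-query	direct	0.95	0	1	star
calcium	CACNA1E	ENSTGUG00000017352				human-query	direct	0.95	0	0
calcium	CACNA1G	ENSTGUG00000009049				human-query	direct	0.95	0	1	star
calcium	CACNA1H	ENSTGUG00000006881				human-query	direct	0.95	0	1	star
calcium	CACNA1I	ENSTGUG00000010198				human-query	direct	0.95	0	1	star
calcium	CACNA2D1		ENSTGUG00000002536;ENSTGUG00000002533			human-query	direct	0.95	0	1	caret,star
calcium	CACNA2D2		ENSTGUG00000004703;ENSTGUG00000004711;ENSTGUG00000004714			human-query	direct	0.95	0	1	caret,star
calcium	CACNA2D3		ENSTGUG00000006966			human-query	direct	0.95	0	1	caret,star
calcium	CACNA2D4		ENSTGUG00000012579			human-query	direct	0.95	0	0	caret
calcium	CACNB1				MUGN01000261.1:2481145-2492038	human-query	direct	0.95	1	0
calcium	CACNB2	ENSTGUG00000001247				human-query	direct	0.95	0	1	star
calcium	CACNB3	ENSTGUG00000015546			MUGN01000394.1:996686-999415	human-query	direct	0.95	1	0
calcium	CACNB4		ENSTGUG00000012082			human-query	direct	0.95	0	1	caret,star
calcium	CACNG1		ENSTGUG00000004397			human-query	direct	0.95	0	0	caret
calcium	CACNG2	ENSTGUG00000010725				human-query	direct	0.95	0	0
calcium	CACNG3	ENSTGUG00000006208				human-query	direct	0.95	0	1	star
calcium	CACNG4	ENSTGUG00000004385				human-query	direct	0.95	0	1	star
calcium	CACNG5	ENSTGUG00000004375				human-query	direct	0.95	0	1	star
calcium	CACNG7				MUGN01000421.1:339861-356707	human-query	phylo-linked	0.95	1	0	dollar
calcium	CACNG8				MUGN01000421.1:325281-333090	human-query	phylo-linked	0.95	1	0	dollar
calcium	ITPR1		ENSTGUG00000010241			human-query	direct	0.95	0	0	caret
calcium	ITPR2		ENSTGUG00000012196			human-query	direct	0.95	0	0	caret
calcium	ITPR3	ENSTGUG00000001798				human-query	direct	0.95	0	0
calcium	RYR1		ENSTGUG00000016333		MUGN01000615.1:2737-83931	human-query	direct	0.95	1	0	caret
calcium	RYR2	ENSTGUG00000010491				human-query	direct	0.95	0	0
calcium	RYR3		ENSTGUG00000011653			human-query	direct	0.95	0	0	caret
calcium	TPCN1	ENSTGUG00000009086				human-query	direct	0.95	0	0
calcium	TPCN2	ENSTGUG00000005328				other-species-query	direct	0.95	0	0	diamond
calcium	TPCN3		ENSTGUG00000007338;ENSTGUG00000015038			other-species-query	direct	0.95	0	1	caret,star,diamond
calcium	CATSPERB				MUGN01001095.1:10976025-10976136	other-species-query	phylo-linked	0.01	1	0	nabla,diamond,dollar
calcium	CATSPERD				MUGN01000898.1:10200480-10200746	other-species-query	phylo-linked	0.02	1	0	nabla,diamond,dollar
calcium	CATSPERE		ENSTGUG00000008288		MUGN01000667.1:20007852-20020082	other-species-query	direct	0.05	1	1	caret,star,nabla,diamond
calcium	CATSPER3			chr13_random:2493868-2500983	MUGN01000154.1:512621-517332	other-species-query	direct	0.05	1	0	nabla,diamond
chloride	CLCN1	ENSTGUG00000013222				human-query	direct	0.95	0	1	star
chloride	CLCN2	ENSTGUG00000010323				human-query	direct	0.95	0	1	star
chloride	CLCN3	ENSTGUG00000006161				human-query	direct	0.95	0	0
chloride	CLCN4	ENSTGUG00000008365				human-query	direct	0.95	0	0
chloride	CLCN5	ENSTGUG00000005324				human-query	phylo-linked	0.95	0	0	dollar
chloride	CLCN6	ENSTGUG00000002366				human-query	direct	0.95	0	1	star
chloride	CLCN7	ENSTGUG00000004211				human-query	direct	0.95	0	1	star
chloride	CLCNK		ENSTGUG00000002023			human-query	direct	0.95	0	1	caret,star
chloride	BSND			chr8:22970234-22970413		human-query	direct	0.95	0	0
chloride	CLIC2	ENSTGUG00000004925				human-query	unresolved	0.95	0	0	hash
chloride	CLIC3	ENSTGUG00000002341				human-query	phylo-linked	0.95	0	1	star,dollar
chloride	CLIC4		ENSTGUG00000001132			human-query	direct	0.95	0	1	caret,star
chloride	CLIC5	ENSTGUG00000013246				human-query	direct	0.95	0	0
chloride	CLIC6	ENSTGUG00000004696			MUGN01000638.1:213150-238240	other-species-query	direct	0.95	1	0	diamond
chloride	CLCC1	ENSTGUG00000004508				other-species-query	direct	0.95	0	1	star,diamond
chloride	ANO1	ENSTGUG00000005385				human-query	direct	0.95	0	1	star
chloride	ANO2	ENSTGUG00000011938				human-query	direct	0.95	0	0
chloride	ANO3	ENSTGUG00000004669				human-query	direct	0.95	0	0
chloride	ANO4	ENSTGUG00000009008				human-query	direct	0.95	0	0
chloride	ANO5	ENSTGUG00000004532				human-query	direct	0.95	0	1	star
chloride	ANO6	ENSTGUG00000006024				human-query	direct	0.95	0	1	star
chloride	ANO7				MUGN01000068.1:571318-573272	human-query	direct	0.05	1	0	nabla
chloride	ANO8		ENSTGUG00000015909			human-query	direct	0.95	0	1	caret,star
chloride	ANO9	ENSTGUG00000006753				human-query	direct	0.95	0	0
chloride	ANO10	ENSTGUG00000003830				human-query	direct	0.95	0	0
chloride	BEST1		ENSTGUG00000005934			other-species-query	direct	0.95	0	1	caret,star,diamond
chloride	BEST3		ENSTGUG00000006968			human-query	direct	0.95	0	0	caret
chloride	LRRC8A	ENSTGUG00000004233				human-query	direct	0.95	0	0
chloride	LRRC8B	ENSTGUG00000006230				human-query	direct	0.95	0	1	star
chloride	LRRC8C	ENSTGUG00000006226				human-query	direct	0.95	0	0
chloride	LRRC8D	ENSTGUG00000006223				human-query	direct	0.95	0	0
chloride	CFTR	ENSTGUG00000004828				human-query	direct	0.95	0	0
chloride	CLNS1A		ENSTGUG00000013030			other-species-query	direct	0.95	0	0	caret,diamond
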