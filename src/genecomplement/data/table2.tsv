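gene	category	in_chicken	full_name
BEST2	Missing in finches	1	bestrophin 2
CATSPER2	Missing in Passeriformes	0	cation channel sperm associated 2
BEST4	Missing in Passeriformes	1	bestrophin 4
CLCA1	Missing in Passeriformes	1	chloride channel accessory 1
CLCA2	Missing in Passeriformes	1	chloride channel accessory 2
CLCA4	Missing in Passeriformes	0	chloride channel accessory 4
CATSPERG	Missing in Neognathae	0	cation channel sperm associated auxiliary subunit G
CATSPER1	Missing in Neognathae	0	cation channel sperm associated 1
CATSPER4	Missing in Neognathae	0	cation channel sperm associated 4
CLIC1	Missing in Neognathae	0	chloride intracellular channel 1
CACNG6	Missing in all birds	0	calcium voltage-gated channel auxiliary subunit gamma 6
LRRC8E	Missing in all birds	0	leucine rich repeat containing 8 VRAC subunit E
SCN7A	Unique to mammals	0	sodium channel voltage-gated type VII alpha subunit
CATSPERZ	Unique to mammals	0	catsper channel auxiliary subunit zeta
CLCNK-duplication	Unique to mammals	0	chloride voltage-gated channel K A or B
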