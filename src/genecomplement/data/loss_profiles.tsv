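gene	human	lizard	alligator	kiwi	tinamou	chicken	quail	falcon	budgie	great_tit	medium_ground_finch	bengalese_finch	zebra_finch
BEST2	present	present	present	unknown	unknown	present	unknown	unknown	unknown	present	unknown	unknown	absent:gapless
CATSPER2	present	present	present	present	present	present	unknown	unknown	present	absent:gappy	absent:gappy	absent:gappy	absent:gapless
BEST4	present	present	present	unknown	unknown	present	unknown	unknown	present	absent:gappy	unknown	absent:gappy	absent:gapless
CLCA1	present	present	present	unknown	present	present	unknown	unknown	present	absent:gappy	unknown	unknown	absent:gapless
CLCA2	present	present	present	unknown	present	present	unknown	unknown	present	absent:gappy	unknown	unknown	absent:gapless
CLCA4	present	present	present	unknown	present	present	unknown	unknown	present	absent:gappy	unknown	unknown	absent:gapless
CATSPERG	present	present	present	present	present	absent:gapless	unknown	unknown	unknown	unknown	unknown	unknown	absent:gapless
CATSPER1	present	present	present	present	present	absent:gapless	unknown	unknown	unknown	unknown	unknown	unknown	absent:gapless
CATSPER4	present	present	present	present	present	absent:gapless	unknown	unknown	unknown	unknown	unknown	unknown	absent:gapless
CLIC1	present	present	present	present	unknown	absent:fragmented	unknown	unknown	unknown	unknown	unknown	unknown	absent:fragmented
CACNG6	present	present	present	absent:gappy	absent:gappy	absent:gapless	absent:gappy	absent:gappy	absent:gappy	absent:gappy	absent:gappy	absent:gappy	absent:gapless
LRRC8E	present	present	present	absent:gappy	absent:gappy	absent:gapless	absent:gappy	absent:gappy	absent:gappy	absent:gappy	absent:gappy	absent:gappy	absent:gapless
SCN7A	present	absent:gappy	absent:gappy	absent:gappy	absent:gappy	absent:gapless	absent:gappy	absent:gappy	absent:gappy	absent:gappy	absent:gappy	absent:gappy	absent:gapless
CATSPERZ	present	absent:gappy	absent:gappy	absent:gappy	absent:gappy	absent:gapless	absent:gappy	absent:gappy	absent:gappy	absent:gappy	absent:gappy	absent:gappy	absent:gapless
CLCNK-duplication	present	absent:gappy	absent:gappy	absent:gappy	absent:gappy	absent:gapless	absent:gappy	absent:gappy	absent:gappy	absent:gappy	absent:gappy	absent:gappy	absent:gapless
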