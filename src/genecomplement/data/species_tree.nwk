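(human,(lizard,(alligator,((kiwi,tinamou)Palaeognathae,((chicken,quail)Galliformes,(falcon,(budgie,(great_tit,(medium_ground_finch,(bengalese_finch,zebra_finch))finches)Passeriformes)Psittacopasserae)Neoaves)Neognathae)Aves)Archosauria)Sauropsida)Amniota;
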