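((((((((Saccharomyces_cerevisiae,Saccharomyces_mikatae),(Saccharomyces_kudriavzevii,Saccharomyces_uvarum)),Candida_glabrata),(Kazachstania_africana,Kazachstania_naganishii)),(Naumovozyma_castellii,Naumovozyma_dairenensis)),((Tetrapisispora_blattae,Tetrapisispora_phaffii),Vanderwaltozyma_polyspora)),(Zygosaccharomyces_rouxii,Torulaspora_delbrueckii)),((Lachancea_kluyveri,(Lachancea_thermotolerans,Lachancea_waltii)),(Kluyveromyces_lactis,(Eremothecium_gossypii,Eremothecium_cymbalariae))));
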