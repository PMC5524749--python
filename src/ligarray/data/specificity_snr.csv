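probe_set,species,p_value,ssnr,nssnr
Streptococcus oralis and rel.,Streptococcus oralis,7.20e-9,168.65,1.61
Streptococcus mutans,Streptococcus mutans,2.49e-6,60.06,1.61
Lactobacillus acidophilus,Lactobacillus acidophilus,9.24e-7,51.45,1.56
Gemella,Gemella morbillorum,2.04e-4,100.48,1.52
Staphylococcus,Staphylococcus aureus,1.81e-4,55.16,1.23
Parvimonas micra,Parvimonas micra,2.85e-6,16.77,1.38
Selenomonas,Selenomonas noxia,1.17e-6,100.34,1.71
Veillonella,Veillonella parvula,4.27e-6,127.11,1.45
Leptotrichia,Leptotrichia buccalis,1.76e-8,12.94,0.89
Fusobacterium,Fusobacterium nucleatum subsp. polymorphum,5.56e-11,279.57,1.67
Propionibacterium,Propionibacterium acidifaciens,3.34e-12,143.65,1.32
Actinomyces,Actinomyces odontolyticus,5.14e-5,42.00,1.23
Treponema denticola and rel.,Treponema denticola,2.31e-8,34.89,1.50
Eikenella,Eikenella corrodens,2.17e-6,14.85,1.36
Haemophilus parainfluenzae and rel.,Haemophilus parainfluenzae,2.87e-4,44.89,1.17
Aggregatibacter actinomycetemcomitans,Aggregatibacter actinomycetemcomitans,4.77e-5,14.02,1.34
Campylobacter,Campylobacter sputorum subsp. sputorum,3.43e-5,40.55,1.32
Capnocytophaga,Capnocytophaga sputigena,3.60e-4,22.72,1.09
Porphyromonas gingivalis,Porphyromonas gingivalis,1.36e-6,30.22,1.15
Prevotella denticola and rel.,Prevotella denticola,3.86e-5,25.14,1.34
Prevotella intermedia and rel.,Prevotella intermedia,2.37e-7,26.10,1.33
Prevotella melaninogenica and rel.,Prevotella melaninogenica,1.09e-6,17.57,1.22
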