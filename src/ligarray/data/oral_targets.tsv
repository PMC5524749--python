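probe_set	taxonomic_level	phylum	zip_id
Streptococcus oralis and rel.	Cluster	Firmicutes	3
Streptococcus mutans	Species	Firmicutes	1
Lactobacillus acidophilus	Species	Firmicutes	23
Gemella	Genus	Firmicutes	5
Staphylococcus	Genus	Firmicutes	29
Parvimonas micra	Species	Firmicutes	9
Selenomonas	Genus	Firmicutes	7
Veillonella	Genus	Firmicutes	15B
Leptotrichia	Genus	Fusobacteria	8
Fusobacterium	Genus	Fusobacteria	15
Propionibacterium	Genus	Actinobacteria	17
Actinomyces	Genus	Actinobacteria	12
Treponema denticola and rel.	Cluster	Spirochaetes	1B
Eikenella	Genus	Proteobacteria	21
Haemophilus parainfluenzae and rel.	Cluster	Proteobacteria	27
Aggregatibacter actinomycetemcomitans	Species	Proteobacteria	31
Campylobacter	Genus	Proteobacteria	6
Capnocytophaga	Genus	Bacteroidetes	41
Porphyromonas gingivalis	Species	Bacteroidetes	39
Prevotella denticola and rel.	Cluster	Bacteroidetes	33
Prevotella intermedia and rel.	Cluster	Bacteroidetes	35
Prevotella melaninogenica and rel.	Cluster	Bacteroidetes	37
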