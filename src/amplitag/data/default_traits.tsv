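taxon	rank	nutrition	morphology	locomotion
Polymyxa graminis	species	plant parasite	naked amoeba	non-motile
Spongospora nasturtii	species	plant parasite	naked amoeba	non-motile
Woronina pythii	species	hyperparasite of Oomycota	naked amoeba	non-motile
Plasmodiophorida	order	plant parasite	naked amoeba	non-motile
Glissomonadida	order	bacterivore	naked flagellate	creeping/gliding
Cercomonadida	order	bacterivore	amoeboflagellate	creeping/gliding
Euglyphida	order	bacterivore	testate-siliceous	creeping/gliding
Cryomonadida	order	eukaryvore	testate-organic/agglutinated	creeping/gliding
Vampyrellida	order	eukaryvore	naked amoeba	creeping/gliding
Thaumatomonadida	order	bacterivore	naked flagellate	creeping/gliding
Pansomonadida	order	bacterivore	naked flagellate	swimming
Chlorarachnida	order	autotroph	naked flagellate	swimming
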