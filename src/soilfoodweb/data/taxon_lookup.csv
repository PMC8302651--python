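clade,rank,guild,group
Chlorophyta,phylum,,photosynthetic_protists
Bacillariophyta,phylum,,photosynthetic_protists
Euglenida,order,,photosynthetic_protists
Cyanobacteria,phylum,,cyanobacteria
Bacteria,kingdom,copiotroph,copiotrophic_bacteria
Bacteria,kingdom,oligotroph,oligotrophic_bacteria
Bacteroidetes,phylum,,copiotrophic_bacteria
Betaproteobacteria,class,,copiotrophic_bacteria
Firmicutes,phylum,,copiotrophic_bacteria
Acidobacteria,phylum,,oligotrophic_bacteria
Verrucomicrobia,phylum,,oligotrophic_bacteria
Chloroflexi,phylum,,oligotrophic_bacteria
Fungi,kingdom,saprotroph,saprotrophic_fungi
Fungi,kingdom,wood_saprotroph,wood_saprotroph_fungi
Fungi,kingdom,saprotroph_plant_pathogen,saprotroph_plant_pathogen_fungi
Fungi,kingdom,ectomycorrhizal,ectomycorrhizal_fungi
Fungi,kingdom,arbuscular_mycorrhizal,arbuscular_mycorrhizal_fungi
Fungi,kingdom,ericoid_mycorrhizal,ericoid_mycorrhizal_fungi
Fungi,kingdom,animal_pathogen,animal_parasite_fungi
Glomeromycota,phylum,,arbuscular_mycorrhizal_fungi
Mortierellaceae,family,,saprotrophic_fungi
Labyrinthulea,class,,saprotrophic_protists
Amoebozoa,phylum,,bacterivore_protists
Ciliophora,phylum,,bacterivore_protists
Cercozoa,phylum,bacterivore,bacterivore_protists
Cercomonadida,order,,bacterivore_protists
Phytomyxea,class,,plant_pathogen_protists
Oomycota,phylum,plant_pathogen,plant_pathogen_protists
Nematoda,phylum,bacterivore,bacterivore_nematodes
Nematoda,phylum,fungivore,fungivore_nematodes
Nematoda,phylum,omnivore,omnivore_nematodes
Nematoda,phylum,predator,predatory_nematodes
Nematoda,phylum,protist_feeder,protist_feeding_nematodes
Nematoda,phylum,plant_parasite,plant_parasitic_nematodes
Nematoda,phylum,animal_parasite,animal_parasite_nematodes
Rhabditidae,family,,bacterivore_nematodes
Cephalobidae,family,,bacterivore_nematodes
Aphelenchidae,family,,fungivore_nematodes
Tylenchidae,family,,plant_parasitic_nematodes
Dorylaimidae,family,,omnivore_nematodes
Mononchidae,family,,predatory_nematodes
Acari,subclass,bacterivore,bacterivore_mites
Acari,subclass,fungivore,fungivore_mites
Acari,subclass,herbivore,herbivore_mites
Acari,subclass,omnivore,omnivore_mites
Acari,subclass,predator,predatory_mites
Oribatida,order,,fungivore_mites
Mesostigmata,order,,predatory_mites
Rotifera,phylum,,bacterivore_rotifers
Tardigrada,phylum,,tardigrades
Collembola,class,,collembola
Diplura,order,,diplurans
Chilopoda,class,,centipedes
Gastropoda,class,,slugs_snails
Enchytraeidae,family,,enchytraeids
Lumbricidae,family,,earthworms
Insecta,class,herbivore,phytophagous_insects
Insecta,class,fungivore,fungivore_insects
Insecta,class,predator,predatory_insects
Curculionidae,family,,phytophagous_insects
Sciaridae,family,,fungivore_insects
Carabidae,family,,predatory_insects
Staphylinidae,family,,predatory_insects
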