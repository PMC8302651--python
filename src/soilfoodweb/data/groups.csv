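group,class_id,size_rank,organism_scale,endoparasite,cross_scale_feeder,size_exception,resource_links,prey,avoid,marker,provenance
photosynthetic_protists,primary_producers,2,micro,0,0,0,sunlight,,,Euka02,main_text
cyanobacteria,primary_producers,1,micro,0,0,0,sunlight,,,Bact01,reconstructed
copiotrophic_bacteria,decomposers,1,micro,0,0,0,organic_matter,,,Bact01,main_text
oligotrophic_bacteria,decomposers,1,micro,0,0,0,organic_matter,,,Bact01,main_text
saprotrophic_fungi,decomposers,1,micro,0,0,0,organic_matter,,,Fung02,reconstructed
wood_saprotroph_fungi,decomposers,1,micro,0,0,0,organic_matter,,,Fung02,main_text
saprotroph_plant_pathogen_fungi,decomposers,1,micro,0,0,0,organic_matter;plants,,,Fung02,main_text
saprotrophic_protists,decomposers,2,micro,0,0,0,organic_matter,,,Euka02,reconstructed
enchytraeids,decomposers,5,macro,0,1,0,organic_matter,copiotrophic_bacteria;oligotrophic_bacteria;saprotrophic_fungi,,Euka02,main_text
earthworms,decomposers,6,macro,0,1,0,organic_matter,copiotrophic_bacteria;oligotrophic_bacteria;saprotrophic_fungi;saprotrophic_protists,,Euka02,reconstructed
plant_pathogen_protists,phytophagous_plant_parasites,2,micro,1,0,0,plants,,,Euka02,main_text
plant_parasitic_nematodes,phytophagous_plant_parasites,3,micro,0,0,0,plants,,,Euka02,reconstructed
herbivore_mites,phytophagous_plant_parasites,4,macro,0,0,0,plants,,,Euka02,main_text
slugs_snails,phytophagous_plant_parasites,6,macro,0,0,0,plants,,,Euka02,main_text
phytophagous_insects,phytophagous_plant_parasites,5,macro,0,0,0,plants,,,Euka02,reconstructed
ectomycorrhizal_fungi,mycorrhizal_fungi,1,micro,0,0,0,plants,,,Fung02,main_text
arbuscular_mycorrhizal_fungi,mycorrhizal_fungi,1,micro,0,0,0,plants,,,Fung02,main_text
ericoid_mycorrhizal_fungi,mycorrhizal_fungi,1,micro,0,0,0,plants,,,Fung02,main_text
bacterivore_protists,bacterivores,2,micro,0,0,0,,copiotrophic_bacteria;oligotrophic_bacteria;cyanobacteria,,Euka02,main_text
bacterivore_nematodes,bacterivores,3,micro,0,0,0,,copiotrophic_bacteria;oligotrophic_bacteria;cyanobacteria,,Euka02,main_text
bacterivore_mites,bacterivores,4,macro,0,1,0,,copiotrophic_bacteria;oligotrophic_bacteria,,Euka02,main_text
bacterivore_rotifers,bacterivores,3,micro,0,0,0,,copiotrophic_bacteria;oligotrophic_bacteria,,Euka02,reconstructed
fungivore_nematodes,fungivores,3,micro,0,0,0,,saprotrophic_fungi;wood_saprotroph_fungi;saprotroph_plant_pathogen_fungi;ectomycorrhizal_fungi,arbuscular_mycorrhizal_fungi,Euka02,reconstructed
fungivore_mites,fungivores,4,macro,0,1,0,,saprotrophic_fungi;wood_saprotroph_fungi;saprotroph_plant_pathogen_fungi;ectomycorrhizal_fungi,arbuscular_mycorrhizal_fungi,Euka02,reconstructed
collembola,fungivores,4,macro,0,1,0,,saprotrophic_fungi;wood_saprotroph_fungi;saprotroph_plant_pathogen_fungi;ectomycorrhizal_fungi,arbuscular_mycorrhizal_fungi,Euka02,main_text
fungivore_insects,fungivores,5,macro,0,1,0,,saprotrophic_fungi;wood_saprotroph_fungi;saprotroph_plant_pathogen_fungi;ectomycorrhizal_fungi,arbuscular_mycorrhizal_fungi,Euka02,reconstructed
omnivore_nematodes,omnivores,3,micro,0,1,1,,copiotrophic_bacteria;oligotrophic_bacteria;saprotrophic_fungi;bacterivore_protists;photosynthetic_protists;saprotrophic_protists;bacterivore_nematodes;fungivore_nematodes;plant_parasitic_nematodes;enchytraeids,,Euka02,main_text
omnivore_mites,omnivores,4,macro,0,1,0,,saprotrophic_fungi;ectomycorrhizal_fungi;bacterivore_nematodes;fungivore_nematodes;collembola,,Euka02,reconstructed
tardigrades,omnivores,3,micro,0,0,0,,copiotrophic_bacteria;oligotrophic_bacteria;photosynthetic_protists;bacterivore_protists;bacterivore_rotifers,,Euka02,reconstructed
diplurans,omnivores,4,macro,0,1,0,,saprotrophic_fungi;collembola,,Euka02,reconstructed
predatory_nematodes,predators,3,micro,0,0,0,,bacterivore_nematodes;fungivore_nematodes;plant_parasitic_nematodes;bacterivore_protists;saprotrophic_protists;bacterivore_rotifers;tardigrades,,Euka02,reconstructed
protist_feeding_nematodes,predators,3,micro,0,0,0,,bacterivore_protists;photosynthetic_protists;saprotrophic_protists,plant_pathogen_protists,Euka02,main_text
predatory_mites,predators,4,macro,0,1,0,,bacterivore_nematodes;fungivore_nematodes;collembola;fungivore_mites;bacterivore_mites;herbivore_mites,,Euka02,reconstructed
centipedes,predators,6,macro,0,0,0,,collembola;fungivore_mites;predatory_mites;omnivore_mites;diplurans;enchytraeids;phytophagous_insects;fungivore_insects,,Euka02,reconstructed
predatory_insects,predators,5,macro,0,0,0,,collembola;fungivore_mites;bacterivore_mites;herbivore_mites;diplurans;enchytraeids,,Euka02,reconstructed
animal_parasite_nematodes,animal_parasites,3,micro,0,1,1,,slugs_snails;phytophagous_insects;fungivore_insects;earthworms;enchytraeids,,Euka02,reconstructed
animal_parasite_fungi,animal_parasites,1,micro,0,1,1,,bacterivore_nematodes;fungivore_nematodes;plant_parasitic_nematodes;collembola;phytophagous_insects;tardigrades,,Fung02,reconstructed
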