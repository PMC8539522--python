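# Synthetic category -> element (biogeochemical cycle) catalog.
# Stand-in for the full 90-category function catalog of the complete rule
# database, which is not bundled; category names are representative and the
# element distribution mirrors the full database's summary:
# 49 carbon, 16 nitrogen, 11 sulfur categories (plus iron, hydrogen, other).
methanotrophy	C
methanol_oxidation	C
methylotrophy	C
methanogenesis	C
hydrogenotrophic_methanogenesis	C
acetoclastic_methanogenesis	C
methanogenesis_using_formate	C
methanogenesis_by_reduction_of_methyl_compounds	C
methanogenesis_by_disproportionation_of_methyl_groups	C
methanogenesis_by_CO2_reduction	C
aerobic_chemoheterotrophy	C
chemoheterotrophy	C
fermentation	C
cellulolysis	C
xylanolysis	C
ligninolysis	C
chitinolysis	C
aromatic_compound_degradation	C
aromatic_hydrocarbon_degradation	C
aliphatic_non_methane_hydrocarbon_degradation	C
hydrocarbon_degradation	C
oil_bioremediation	C
plastic_degradation	C
starch_degradation	C
pectin_degradation	C
agar_degradation	C
alginate_degradation	C
cellobiose_degradation	C
glycerol_degradation	C
chlorophenol_degradation	C
naphthalene_degradation	C
toluene_degradation	C
phenol_degradation	C
photoautotrophy	C
oxygenic_photoautotrophy	C
anoxygenic_photoautotrophy	C
anoxygenic_photoautotrophy_H2_oxidizing	C
aerobic_anoxygenic_phototrophy	C
photoheterotrophy	C
phototrophy	C
cyanobacteria	C
acetogenesis	C
syntrophic_acetate_oxidation	C
chemolithoautotrophy	C
mixotrophy	C
carbon_monoxide_oxidation	C
formaldehyde_oxidation	C
formate_oxidation	C
humic_matter_degradation	C
nitrification	N
aerobic_ammonia_oxidation	N
aerobic_nitrite_oxidation	N
nitrate_reduction	N
nitrate_respiration	N
nitrite_respiration	N
nitrate_denitrification	N
nitrite_denitrification	N
nitrous_oxide_denitrification	N
denitrification	N
nitrogen_fixation	N
nitrogen_respiration	N
ureolysis	N
anammox	N
nitrate_ammonification	N
nitrite_ammonification	N
sulfate_respiration	S
sulfite_respiration	S
sulfur_respiration	S
thiosulfate_respiration	S
respiration_of_sulfur_compounds	S
dark_sulfide_oxidation	S
dark_sulfur_oxidation	S
dark_thiosulfate_oxidation	S
dark_oxidation_of_sulfur_compounds	S
sulfur_disproportionation	S
anoxygenic_photoautotrophy_S_oxidizing	S
iron_respiration	Fe
dark_iron_oxidation	Fe
dark_hydrogen_oxidation	H
knallgas_bacteria	H
chloroplasts	other
predatory_or_exoparasitic	other
intracellular_parasites	other
animal_parasites_or_symbionts	other
human_pathogens	other
plant_pathogens	other
fish_parasites	other
arsenate_respiration	other
manganese_oxidation	other
manganese_respiration	other
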