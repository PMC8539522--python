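# Miniature taxonomy-to-function rule database (FAPROTAX flat-text dialect).
# Group headers start at column 0; indented lines are taxon wildcard patterns
# or add_group directives pulling in another group's members.
# The group set covers the carbon, nitrogen, sulfur, iron and hydrogen cycle
# categories the pipeline works with; taxa are representative lake
# bacterioplankton lineages.

aerobic_chemoheterotrophy	elements:C
	*Sphingomonadaceae*
	*Burkholderiaceae*
	*Pseudomonadaceae*

aromatic_hydrocarbon_degradation	elements:C
	*Gordonia*

cellulolysis	elements:C
	*Lewinella*
	*Dyadobacter*
	*Acidothermus*

methanol_oxidation	elements:C
	*Paracoccus*

methanotrophy	elements:C
	*Methylomonaceae*

methylotrophy	elements:C
	add_group:methanol_oxidation
	add_group:methanotrophy
	*Methylophilaceae*

chemoheterotrophy	elements:C
	add_group:aerobic_chemoheterotrophy
	add_group:aromatic_hydrocarbon_degradation
	add_group:cellulolysis
	add_group:methylotrophy
	*Acinetobacter*

fermentation	elements:C
	*Carnobacteriaceae*

photoautotrophy	elements:C
	*Tychonema*
	*Cyanobium*

photoheterotrophy	elements:C
	*Rhodoferax*

denitrification	elements:N
	*Stenotrophomonas*

nitrate_respiration	elements:N
	add_group:denitrification
	*Marinobacter*

nitrate_reduction	elements:N
	add_group:nitrate_respiration
	*Ensifer*

nitrogen_fixation	elements:N
	*Bradyrhizobium*

nitrification	elements:N
	*Nitrosomonadaceae*
	*Nitrososphaeraceae*

ureolysis	elements:N
	*Singulisphaera*

sulfate_respiration	elements:S
	*Desulfobacteraceae*

thiosulfate_respiration	elements:S
	*Alishewanella*

sulfur_respiration	elements:S
	*Desulfuromonas*

respiration_of_sulfur_compounds	elements:S
	add_group:sulfate_respiration
	add_group:thiosulfate_respiration
	add_group:sulfur_respiration

dark_sulfide_oxidation	elements:S
	*Thiobacillus*
	*Thiothrix*

iron_respiration	elements:Fe
	*Geobacter*

dark_hydrogen_oxidation	elements:H
	*Hydrogenophaga*
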