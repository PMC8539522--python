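# Regrouping of the raw rule-database groups into canonical, non-nested
# categories, plus the element (biogeochemical cycle) of each canonical
# category.
#
# merge_map:    raw group -> canonical category (several raw groups may merge)
# subtract_map: canonical category -> categories whose ZOTUs are removed from
#               it (the de-nesting step; e.g. Chemo-1 is aerobic
#               chemoheterotrophy minus biopolymer, one-carbon and aromatic
#               degraders, Chemo-3 is the residual chemoheterotrophy)
# drop:         raw umbrella groups fully covered by their members

merge_map:
  aerobic_chemoheterotrophy: Chemo-1
  aromatic_hydrocarbon_degradation: Chemo-2
  chemoheterotrophy: Chemo-3
  cellulolysis: cellulolysis
  methanol_oxidation: methanol_oxidation
  methanotrophy: methanotrophy
  methylotrophy: methylotrophy
  fermentation: fermentation
  photoautotrophy: photoautotrophy
  photoheterotrophy: photoheterotrophy
  denitrification: dissimilatory nitrate reduction
  nitrate_respiration: dissimilatory nitrate reduction
  nitrate_reduction: dissimilatory nitrate reduction
  nitrogen_fixation: nitrogen_fixation
  nitrification: nitrification
  ureolysis: ureolysis
  sulfate_respiration: sulfate_respiration
  thiosulfate_respiration: thiosulfate_respiration
  sulfur_respiration: sulfur_respiration
  dark_sulfide_oxidation: dark_sulfide_oxidation
  iron_respiration: iron_respiration
  dark_hydrogen_oxidation: dark_hydrogen_oxidation

subtract_map:
  Chemo-1: [Chemo-2, cellulolysis, methanol_oxidation, methanotrophy, methylotrophy]
  Chemo-3: [Chemo-1, Chemo-2, cellulolysis, methanol_oxidation, methanotrophy, methylotrophy]
  methylotrophy: [methanol_oxidation, methanotrophy]

drop:
  - respiration_of_sulfur_compounds

elements:
  Chemo-1: C
  Chemo-2: C
  Chemo-3: C
  cellulolysis: C
  methanol_oxidation: C
  methanotrophy: C
  methylotrophy: C
  fermentation: C
  photoautotrophy: C
  photoheterotrophy: C
  dissimilatory nitrate reduction: N
  nitrogen_fixation: N
  nitrification: N
  ureolysis: N
  sulfate_respiration: S
  thiosulfate_respiration: S
  sulfur_respiration: S
  dark_sulfide_oxidation: S
  iron_respiration: Fe
  dark_hydrogen_oxidation: H
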