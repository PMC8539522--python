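# 96-well CLPP plate layout: 31 sole-carbon-source substrates in triplicate
# plus 3 water controls, on an 8-row x 12-column grid.  The plate repeats the
# same 32-well block three times (columns 1-4, 5-8, 9-12); within a block
# wells are filled column-major, with the water control at the top-left of
# each block.  `position` is the 1-based index of the substrate within the
# block (position 0 is the water control).
#
# Substrate groups: amino acids (AA), carbohydrates (C), carboxylic acids
# (CA), polymers (P), amines (A).

n_rows: 8
n_cols: 12
block_cols: 4
control_position: 0

substrates:
  - {code: C3,  name: beta-methyl-D-glucoside,        group: carbohydrates,    position: 1}
  - {code: CA1, name: pyruvic-acid-methyl-ester,      group: carboxylic acids, position: 2}
  - {code: P1,  name: Tween-40,                       group: polymers,         position: 3}
  - {code: P2,  name: Tween-80,                       group: polymers,         position: 4}
  - {code: P3,  name: alpha-cyclodextrin,             group: polymers,         position: 5}
  - {code: P4,  name: glycogen,                       group: polymers,         position: 6}
  - {code: C1,  name: D-cellobiose,                   group: carbohydrates,    position: 7}
  - {code: C2,  name: alpha-D-lactose,                group: carbohydrates,    position: 8}
  - {code: C4,  name: D-xylose,                       group: carbohydrates,    position: 9}
  - {code: C5,  name: i-erythritol,                   group: carbohydrates,    position: 10}
  - {code: C6,  name: D-mannitol,                     group: carbohydrates,    position: 11}
  - {code: C7,  name: N-acetyl-D-glucosamine,         group: carbohydrates,    position: 12}
  - {code: C8,  name: glucose-1-phosphate,            group: carbohydrates,    position: 13}
  - {code: C9,  name: DL-alpha-glycerol-phosphate,    group: carbohydrates,    position: 14}
  - {code: C10, name: D-galactonic-acid-gamma-lactone, group: carbohydrates,   position: 15}
  - {code: CA2, name: D-glucosaminic-acid,            group: carboxylic acids, position: 16}
  - {code: CA3, name: D-galacturonic-acid,            group: carboxylic acids, position: 17}
  - {code: CA4, name: 2-hydroxybenzoic-acid,          group: carboxylic acids, position: 18}
  - {code: CA5, name: 4-hydroxybenzoic-acid,          group: carboxylic acids, position: 19}
  - {code: CA6, name: gamma-hydroxybutyric-acid,      group: carboxylic acids, position: 20}
  - {code: CA7, name: itaconic-acid,                  group: carboxylic acids, position: 21}
  - {code: CA8, name: alpha-ketobutyric-acid,         group: carboxylic acids, position: 22}
  - {code: CA9, name: D-malic-acid,                   group: carboxylic acids, position: 23}
  - {code: AA1, name: L-arginine,                     group: amino acids,      position: 24}
  - {code: AA2, name: L-asparagine,                   group: amino acids,      position: 25}
  - {code: AA3, name: L-phenylalanine,                group: amino acids,      position: 26}
  - {code: AA4, name: L-serine,                       group: amino acids,      position: 27}
  - {code: AA5, name: L-threonine,                    group: amino acids,      position: 28}
  - {code: AA6, name: glycyl-L-glutamic-acid,         group: amino acids,      position: 29}
  - {code: A1,  name: phenylethylamine,               group: amines,           position: 30}
  - {code: A2,  name: putrescine,                     group: amines,           position: 31}
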