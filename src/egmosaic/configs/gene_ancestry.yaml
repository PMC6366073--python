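# Planted gene-tree configuration calibrated to the published ancestry
# binning: 4087 classified trees, with the excavate bins (kinetoplastids
# 1420 plus other excavate lineages 396) summing to 1816 and green
# plants + green algae at 572. The brown-algal total (723) is split
# evenly across its three groups and chlorarachniophytes absorb the
# residual so the bins sum to 4087.
focal_taxon: EGRACILIS
taxa_per_group: 4
support_planted: 95
support_background: [20, 74]
groups:
  - Kinetoplastida
  - ExcavataOther
  - Viridiplantae
  - Haptophyta
  - Cryptophyta
  - Ochrophyta
  - Chlorarachniophyta
  - Rhodophyta
  - Glaucophyta
  - Prokaryotes
  - Metazoa
  - Amoebozoa
bins:
  Kinetoplastida: 1420
  ExcavataOther: 396
  Viridiplantae: 572
  Haptophyta: 241
  Cryptophyta: 241
  Ochrophyta: 241
  Chlorarachniophyta: 359
  Rhodophyta: 50
  Glaucophyta: 53
  Prokaryotes: 220
  Metazoa: 149
  Amoebozoa: 145
rollups:
  Excavata: [Kinetoplastida, ExcavataOther]
  GreenPlantsAlgae: [Viridiplantae]
noise:
  low_support: 0
  mixed_clan: 0
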