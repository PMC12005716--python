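# Chiton karyotype-evolution scenario.
#
# Seven chromosome-level genomes (one gastropod, one bivalve, five
# chitons) descended from a 20-linkage-group molluscan ancestor. The
# scripted events encode the reconstructed route: three synapomorphic
# stem fusions shared by all chitons (LG 4+16+18 as one three-way event,
# LG 7+10, LG 8+9), lineage-specific fusions that reproduce each tip's
# haploid chromosome number (Deshayesiella 1n=11 via three fusions, one
# of them four-way; both Acanthochitona congeners 1n=8 via two different
# fusions each from a 1n=10 genus ancestor), and the Liolophura pattern
# of two linkage groups fusing first and then partially duplicating.
# LG 19 and 20 are deliberately untouched by every event: LG20 is the
# conserved-group analogue that must stay unfused in every tip.
#
# Branch lengths are in My. The Acanthochitona split is ~23 My (fossil
# calibrated); crown Polyplacophora sits ~280 Mya, crown Mollusca at
# 540 Mya. Internal ages without a stated calibration are scenario
# choices.
name: chiton_radiation
n_lgs: 20
genes_per_lg: 236
tree: >-
  ((Gibbula_magus:530,Mizuhopecten_yessoensis:530)Conchifera:10,
  (Deshayesiella_sirenkoi:280,(Callochiton_septemvalvis:200,
  (Liolophura_japonica:150,(Acanthochitona_rubrolineata:23,
  Acanthochitona_discrepans:23)Acanthochitona:127)Chitonida_ss:50)
  Chitonida_sl:80)Polyplacophora:260)Mollusca;
rates:
  translocation: 0.05
translocation_k: 1
events:
  # chiton stem: the three polyplacophoran synapomorphies
  - {branch: Polyplacophora, type: fusion, lgs: [4, 16, 18], pi: 0.8}
  - {branch: Polyplacophora, type: fusion, lgs: [7, 10], pi: 0.8}
  - {branch: Polyplacophora, type: fusion, lgs: [8, 9], pi: 0.8}
  # Lepidopleurida: three novel fusions, one four-way (16 -> 11 chromosomes)
  - {branch: Deshayesiella_sirenkoi, type: fusion, lgs: [1, 2, 3, 5], pi: 0.8}
  - {branch: Deshayesiella_sirenkoi, type: fusion, lgs: [6, 11], pi: 0.8}
  - {branch: Deshayesiella_sirenkoi, type: fusion, lgs: [12, 13], pi: 0.8}
  - {branch: Deshayesiella_sirenkoi, type: shuffle, lg: 14}
  # Chitonida s.l. stem: LG1 joins the 4+16+18 chromosome (-> 1+4+16+18)
  - {branch: Chitonida_sl, type: fusion, lgs: [1, 4], pi: 0.8}
  # Callochitonida: two additional fusions (15 -> 13)
  - {branch: Callochiton_septemvalvis, type: fusion, lgs: [2, 12], pi: 0.8}
  - {branch: Callochiton_septemvalvis, type: fusion, lgs: [3, 6], pi: 0.8}
  - {branch: Callochiton_septemvalvis, type: shuffle, lg: 12}
  # Liolophura: two LGs fuse (poorly mixed) and the product partially duplicates
  - {branch: Liolophura_japonica, type: fusion, lgs: [11, 17], pi: 0.05}
  - {branch: Liolophura_japonica, type: duplication, lg: 11, fraction: 0.6}
  # Acanthochitona stem: 15 -> 10 chromosomes
  - {branch: Acanthochitona, type: fusion, lgs: [2, 3, 5], pi: 0.8}
  - {branch: Acanthochitona, type: fusion, lgs: [6, 11, 12], pi: 0.8}
  - {branch: Acanthochitona, type: fusion, lgs: [13, 14], pi: 0.8}
  # the two congeners: two different fusions each (10 -> 8)
  - {branch: Acanthochitona_rubrolineata, type: fusion, lgs: [2, 6], pi: 0.8}
  - {branch: Acanthochitona_rubrolineata, type: fusion, lgs: [15, 17], pi: 0.8}
  - {branch: Acanthochitona_rubrolineata, type: shuffle, lg: 2}
  - {branch: Acanthochitona_discrepans, type: fusion, lgs: [5, 17], pi: 0.8}
  - {branch: Acanthochitona_discrepans, type: fusion, lgs: [13, 15], pi: 0.8}
  - {branch: Acanthochitona_discrepans, type: shuffle, lg: 5}
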