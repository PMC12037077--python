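# The shipped default scenario: a calsequestrin-like two-paralog family in
# which the focal clade ("AVES") has flipped its skeletal-muscle dominant
# paralog to CASQ2, boosted the acidity of its CASQ2 C-terminal tail on the
# focal stem, and lost CASQ1 exons 2 and 3 in a 3-species subclade.
# These values equal the ScenarioConfig defaults; edit a copy to explore.
seed: 0
n_focal: 6
focal_clade: AVES
nonfocal_clades: [MAM, SQU, CRO]
n_per_nonfocal_clade: 4

aln_length: 300
domains_region: [20, 260]
cterm_region: [270, 300]
paralogs: [CASQ1, CASQ2]
inter_paralog_divergence: 0.30
subst_rate: 0.004
tail_boost: 0.30
tail_boost_paralog: CASQ2

tissues: [skeletal, cardiac]
skeletal_dominant: CASQ1
cardiac_dominant: CASQ2
dominant_cpm: 900.0
minor_cpm: 100.0
lognormal_sigma: 0.3
samples_per_tissue: 2
total_mapped: 20000000.0
focal_skeletal_scale: 2.5
flip:
  tissue: skeletal
  to_paralog: CASQ2

ref_exon_count: 11
exon_deletion:
  paralog: CASQ1
  exons: [2, 3]
  n_species: 3
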