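# Default gene model for the house fly (Musca domestica) voltage-sensitive
# sodium channel (Vssc / para-like) and the four canonical kdr mutation sites.
#
# Coordinates quoted in reference_labels are labels only; the package never
# aligns against the full GenBank records. Guide sequences are the anchor
# oligomers used to pinpoint each mutation codon in Sanger consensus reads.
#
# codon_offset is the position of the codon's first base relative to the end
# (exclusive) of the guide match on the coding strand. L1014F uses -1 because
# the published guide's final base IS the codon's variable base (it spells the
# resistant variant): the same 18-bp context is shared with the allele-specific
# PASA primers, whose 3' ends discriminate at that base.
schema_version: 1
gene_name: Vssc
reference_labels:
  - "NW_026712250.1 position 125581 (L1014F, gDNA label)"
  - "NM_001286885.1 (para-like mRNA label)"
sites:
  - name: M918T
    codon_number: 918
    wild_aa: M
    mutant_aa: T
    wild_codon: ATG
    mutant_codon: ACG
    variable_position: 2
    guide_sequence: AATTTACTCATTTCGATTAC
    codon_offset: 0
  - name: T929I
    codon_number: 929
    wild_aa: T
    mutant_aa: I
    wild_codon: ACA
    mutant_codon: ATA
    variable_position: 2
    guide_sequence: GGTGCATTGGGTAATCTGAT
    codon_offset: 0
  - name: L1014F
    codon_number: 1014
    wild_aa: L
    mutant_aa: F
    wild_codon: CTT
    mutant_codon: TTT
    variable_position: 1
    guide_sequence: ACGGTCGTGATCGGCAATT
    codon_offset: -1
  - name: L1014H
    codon_number: 1014
    wild_aa: L
    mutant_aa: H
    wild_codon: CTT
    mutant_codon: CAT
    variable_position: 2
    guide_sequence: CGGTCGTGATCGGCAATCA
    codon_offset: 0
intron:
  # gDNA carries a large (~1700 bp) intron between the M918/T929 region and
  # the codon-1014 region; cDNA is contiguous. The position is a coordinate on
  # the packaged synthetic cDNA reference.
  position: 140
  length: 1700
pasa:
  # Three-reaction allele-specific PCR for L1014F. Expected sizes are the
  # nominal published gel sizes; measured/predicted bands are matched to them
  # within size_tolerance (fraction of the expected size).
  size_tolerance: 0.10
  max_product_length: 1000
  primers:
    - {name: kdr1, sequence: AAGGATCGCTTCAAGG, direction: forward, annealing_temp: 54}
    - {name: kdr2, sequence: GTCGTGATCGGCAATT, direction: reverse, annealing_temp: 54}
    - {name: kdr3, sequence: CGTCAACTTACCACAAG, direction: forward, annealing_temp: 54}
    - {name: kdr4, sequence: TTCACCCAGTTCTTAAAACGAG, direction: reverse, annealing_temp: 54}
  reactions:
    - {name: control, primers: [kdr1, kdr4], expected_size: 480}
    - {name: susceptible, primers: [kdr1, kdr3], expected_size: 200}
    - {name: resistant, primers: [kdr2, kdr4], expected_size: 280}
sequencing_primers:
  - {name: K1, sequence: TCGCTTCAAGGACCATGAAT, direction: forward, annealing_temp: 60}
  - {name: K2, sequence: TTACGTTTCACCCAGTTCTTA, direction: reverse, annealing_temp: 60}
  - {name: 4Mut_kdr_F, sequence: TCCGGAATTGGAGAAGGTGC, direction: forward, annealing_temp: 55}
  - {name: 4Mut_kdr_R, sequence: TCAAGCCATCGCCCATGATT, direction: reverse, annealing_temp: 55}
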