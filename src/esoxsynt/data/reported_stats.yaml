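# Published summary statistics of the northern pike genome/linkage-map study,
# as printed: each entry gives the printed inputs, the arithmetic relating
# them, and the printed derived value at its printed precision.
worked_examples:
  - name: mean_contig_length_bp
    op: divide
    inputs: [823673596, 94267]      # filtered assembly bp / contig count
    printed: 8738
    precision: 0
  - name: assembly_kmer_coverage_pct
    op: percent
    inputs: [877777613, 911413085]  # scaffolded bp / kmer-estimated genome size
    printed: 96.3
    precision: 1
  - name: est_contigs_mapped_pct
    op: percent
    inputs: [11263, 11662]          # EST contigs mapped / considered
    printed: 96.6
    precision: 1
  - name: polymorphic_markers_total
    op: sum
    inputs: [187, 378]              # EST-designed + scaffold-designed polymorphic
    printed: 565
    precision: 0
  - name: primer_pairs_screened_total
    op: sum
    inputs: [776, 835]
    printed: 1611
    precision: 0
  - name: reference_transcripts_total
    op: sum
    inputs: [9553, 14538, 604, 14001]  # full-length + SwissProt + GO + ORF>=300
    printed: 38696
    precision: 0
  - name: est_primer_polymorphic_pct
    op: percent
    inputs: [187, 776]
    printed: 24
    precision: 0
  - name: half_sib_mapping_progeny
    op: sum
    inputs: [48, 44]                # progeny per father in the mapping family
    printed: 92
    precision: 0
  - name: female_male_recombination_ratio
    op: divide
    inputs: [1245.4, 1166.0]        # female / male sex-specific map totals, cM
    printed: 1.07
    precision: 2
  - name: linkage_groups_expected_from_karyotype
    op: divide
    inputs: [50, 2]                 # diploid karyotype 2N=50
    printed: 25
    precision: 0
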