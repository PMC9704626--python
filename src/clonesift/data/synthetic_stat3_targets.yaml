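# SYNTHETIC reference fixture: STAT3 SH2-domain exon 20/21 amplicon targets.
# Codon numbering follows the STAT3 protein; codons named in known_variants_stat3.tsv
# carry the true residues, all other codons are deterministic filler sequence.
targets:
- name: STAT3_ex20
  chrom: chr17
  start: 40474200
  end: 40474302
  ref_seq: TGGACCTCCTTCGAAGCTGACCTTCAGAGCTGGGATCTGAAAAGTGGTGACCTTCTTAGCTGGGATCTGGTCGAAGGTGACTTCTTTGCTTGGGATCTGGTC
  gene_strand: '-'
  codon_offset: 586
  frame_shift: 0
  build_label: GRCh37-like synthetic reference
- name: STAT3_ex21
  chrom: chr17
  start: 40470120
  end: 40470294
  ref_seq: GACCTTCAGCTCTGGGATCTGGTCGAAGGTGACCTTCAGAGCTGGGATCTGGTCGAAGGTGACCTTAACAGCTGGGATCTGAAGGAAGGTGACCTTATCAGCAATTTTGTAGTCGAAGGTGACCTTCAGAGCTGGGATGTTATTGAATTGGACCTTCAGATAAGGGATCTGGTC
  gene_strand: '-'
  codon_offset: 636
  frame_shift: 0
  build_label: GRCh37-like synthetic reference
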