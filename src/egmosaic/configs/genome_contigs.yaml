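# Toy genome calibrated to the published architecture of contigs longer
# than 10 kbp: 1459 contigs totalling 22 Mb, 53 bearing coding sequence,
# 135 gene models, 271 introns totalling 278,354 bp (mean 1027.14) with
# splice classes 218 conventional / 30 intermediate / 23 nonconventional,
# and 73,482 exonic bases. The published exon count (421) is inconsistent
# with 135 models and 271 introns (which imply 406 exons); the intron-side
# numbers are honoured. 25 sub-threshold contigs exercise the size filter.
n_contigs: 1459
total_contig_bases: 22000000
contigs_with_cds: 53
n_cds: 135
n_introns: 271
total_intron_length: 278354
total_exon_length: 73482
splice_counts:
  conventional: 218
  intermediate: 30
  nonconventional: 23
gene_contig_length: 20000
n_small_contigs: 25
small_contig_length: 5000
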