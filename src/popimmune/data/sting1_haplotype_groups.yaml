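# STING1 four-SNP haplotype group rules.
#
# SNP order: R71H (rs11554776), G230A (rs78233829), R232H (rs1131769),
# R293Q (rs7380824).  Alleles are coded by protein residue: "ref" is the
# wild-type residue of the R232 (WT) protein at each position.  Note that
# at R232H the human reference genome carries the variant residue (H232),
# which is why the all-"ref"-except-232H pattern is named REF.
locus: STING1
snps: [rs11554776, rs78233829, rs1131769, rs7380824]
groups:
  WT:  [ref, ref, ref, ref]
  REF: [ref, ref, alt, ref]
  HAQ: [alt, alt, ref, alt]
  AQ:  [ref, alt, ref, alt]
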