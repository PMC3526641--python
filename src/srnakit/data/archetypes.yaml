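# Default library archetype parameters, v1.
#
# These are generator parameters, tuned so that:
#   * ovary_like has a modal read length of 22 nt driven by miRNAs,
#   * testis_like has a bimodal length profile with local maxima at 24 and
#     27 nt and a planted repeat share of 0.36 over source categories,
#   * ip_like has a mild 24-25 nt peak, a depleted miRNA fraction, and a
#     repeat share near 0.1225 with an exon share near 0.1486.
version: 1
adapter: TGGAATTCTCGGGTGCCAAGG
archetypes:
  ovary_like:
    length_mixture:
      18: 0.02
      19: 0.03
      20: 0.06
      21: 0.12
      22: 0.30
      23: 0.12
      24: 0.08
      25: 0.06
      26: 0.05
      27: 0.04
      28: 0.04
      29: 0.03
      30: 0.03
      31: 0.01
      32: 0.01
    category_mixture:
      miRNA_hairpin: 0.45
      rRNA: 0.04
      tRNA: 0.03
      snRNA: 0.01
      snoRNA: 0.02
      LINE: 0.06
      LTR: 0.04
      satellite: 0.02
      other_repeat: 0.02
      exon: 0.08
      intergenic: 0.23
    fivep_u_bias: 0.30
    isomir_shift_probs: {0: 0.60, 1: 0.12, -1: 0.12, 2: 0.08, -2: 0.08}
    adapter_dimer_rate: 0.02
    low_quality_rate: 0.03
  testis_like:
    length_mixture:
      18: 0.01
      19: 0.01
      20: 0.02
      21: 0.02
      22: 0.03
      23: 0.06
      24: 0.18
      25: 0.10
      26: 0.10
      27: 0.17
      28: 0.10
      29: 0.08
      30: 0.06
      31: 0.03
      32: 0.03
    category_mixture:
      miRNA_hairpin: 0.02
      rRNA: 0.02
      tRNA: 0.02
      snRNA: 0.01
      snoRNA: 0.01
      LINE: 0.15
      LTR: 0.12
      satellite: 0.05
      other_repeat: 0.04
      exon: 0.08
      intergenic: 0.48
    fivep_u_bias: 0.60
    isomir_shift_probs: {0: 0.60, 1: 0.12, -1: 0.12, 2: 0.08, -2: 0.08}
    adapter_dimer_rate: 0.02
    low_quality_rate: 0.02
    intergenic_chrom_weights: {chr1: 0.08, chr2: 0.08, chr3: 0.09, chrZ: 0.25, chrW: 0.50}
  ip_like:
    length_mixture:
      18: 0.02
      19: 0.02
      20: 0.03
      21: 0.04
      22: 0.05
      23: 0.08
      24: 0.16
      25: 0.15
      26: 0.11
      27: 0.09
      28: 0.08
      29: 0.07
      30: 0.05
      31: 0.03
      32: 0.02
    category_mixture:
      miRNA_hairpin: 0.005
      rRNA: 0.012
      tRNA: 0.010
      snRNA: 0.004
      snoRNA: 0.004
      LINE: 0.050
      LTR: 0.040
      satellite: 0.020
      other_repeat: 0.0125
      exon: 0.1486
      intergenic: 0.6939
    fivep_u_bias: 0.60
    isomir_shift_probs: {0: 0.60, 1: 0.12, -1: 0.12, 2: 0.08, -2: 0.08}
    adapter_dimer_rate: 0.03
    low_quality_rate: 0.03
    intergenic_chrom_weights: {chr1: 0.10, chr2: 0.10, chr3: 0.10, chrZ: 0.25, chrW: 0.45}
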