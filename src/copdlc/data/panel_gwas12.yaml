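# Default SNP panel: 12 GWAS candidate loci for COPD / lung function / lung
# cancer typed in smoking cohorts sub-phenotyped for COPD.
#
# Per entry:
#   alphabet        ordered genotype triple (major-hom, het, minor-hom as
#                   tabulated)
#   risk_genotypes  the "exposed" genotype class used in the 2x2 collapse
#   direction       +1 susceptible, -1 protective, 0 = typed and tested but
#                   not part of the 9-SNP composite score
#   effect_class    published G0-G3 assignment (UNASSIGNED for non-score SNPs)
#   risk_allele     allele treated as exposure under the allelic model
panel:
  - snp_id: rs2808630
    gene: CRP
    locus: 1q23
    alphabet: [TT, TC, CC]
    risk_genotypes: [CC]
    direction: -1
    effect_class: G3
    risk_allele: C
  - snp_id: rs7671167
    gene: FAM13A
    locus: 4q22
    alphabet: [CC, TC, TT]
    risk_genotypes: [CC]
    direction: -1
    effect_class: G0
    risk_allele: C
  - snp_id: rs10516526
    gene: GSTCD
    locus: 4q24
    alphabet: [AA, AG, GG]
    risk_genotypes: [GG, AG]
    direction: 0
    effect_class: UNASSIGNED
    risk_allele: G
  - snp_id: rs1489759
    gene: HHIP
    locus: 4q31
    alphabet: [AA, AG, GG]
    risk_genotypes: [GG]
    direction: -1
    effect_class: G0
    risk_allele: G
  - snp_id: rs2202507
    gene: GYPA
    locus: 4q31
    alphabet: [AA, AC, CC]
    risk_genotypes: [CC]
    direction: -1
    effect_class: G0
    risk_allele: C
  - snp_id: rs402710
    gene: CRR9
    locus: 5p15
    alphabet: [GG, GA, AA]
    risk_genotypes: [GG]
    direction: +1
    effect_class: G3
    risk_allele: G
  - snp_id: rs11168048
    gene: HTR4
    locus: 5q33
    alphabet: [TT, CT, CC]
    risk_genotypes: [CC]
    direction: 0
    effect_class: UNASSIGNED
    risk_allele: C
  - snp_id: rs1422795
    gene: ADAM19
    locus: 5q33
    alphabet: [TT, CT, CC]
    risk_genotypes: [CC]
    direction: +1
    effect_class: G2
    risk_allele: C
  - snp_id: rs1052486
    gene: BAT3
    locus: 6p21
    alphabet: [AA, AG, GG]
    risk_genotypes: [GG]
    direction: +1
    effect_class: G2
    risk_allele: G
  - snp_id: rs2070600
    gene: AGER
    locus: 6p21
    alphabet: [CC, CT, TT]
    risk_genotypes: [CT, TT]
    direction: -1
    effect_class: G1
    risk_allele: C
  - snp_id: rs11155242
    gene: GPR126
    locus: 6q24
    alphabet: [AA, AC, CC]
    risk_genotypes: [CC]
    direction: 0
    effect_class: UNASSIGNED
    risk_allele: C
  - snp_id: rs16969968
    gene: CHRNA3/5
    locus: 15q25
    alphabet: [GG, GA, AA]
    risk_genotypes: [AA]
    direction: +1
    effect_class: G2
    risk_allele: A
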