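# Default reduced ACMG evidence configuration.
#
# Evidence codes are assigned per variant:
#   PVS1 - loss-of-function variant in a gene where LoF is an accepted
#          disease mechanism (gene_allowlist: null means every panel gene);
#   PM2  - absent from the population frequency sources (effective MAF == 0)
#          and carried by no in-house control;
#   PP3  - supported by at least `min_support` of the seven computational
#          pathogenicity predictors (CADD counts as damaging at or above
#          `cadd_damaging_min`).
#
# Combining rules are evaluated top class first; a rule fires when all its
# codes are present and, if a `models` restriction is given, the finding's
# inheritance model is listed.  Novel missense variants with predictor
# support (PM2 + PP3) reach "likely pathogenic" only under the dominant
# model; under the recessive model the same evidence stays "uncertain
# significance".
cadd_damaging_min: 20.0
evidence:
  PVS1:
    rule: lof
    gene_allowlist: null
  PM2:
    rule: absent
  PP3:
    rule: predictor_support
    min_support: 4
combining:
  P:
    - codes: [PVS1, PM2]
    - codes: [PVS1, PP3]
  LP:
    - codes: [PVS1]
    - codes: [PM2, PP3]
      models: [AD_het]
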