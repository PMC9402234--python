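# ACMG SF v2.0 secondary-findings panel: 59 genes with highly penetrant,
# medically actionable variants, grouped into five disease categories.
# Coding intervals live in the companion BED file (synthetic stand-in
# coordinates; see its header).
intervals_bed: acmg59_coding_intervals.synthetic.bed
genes:
  ACTA2: cardiovascular
  ACTC1: cardiovascular
  APC: cancers
  APOB: familial_hypercholesteremia
  ATP7B: others
  BMPR1A: cancers
  BRCA1: cancers
  BRCA2: cancers
  CACNA1S: malignant_hyperthermia
  COL3A1: cardiovascular
  DSC2: cardiovascular
  DSG2: cardiovascular
  DSP: cardiovascular
  FBN1: cardiovascular
  GLA: others
  KCNH2: cardiovascular
  KCNQ1: cardiovascular
  LDLR: familial_hypercholesteremia
  LMNA: cardiovascular
  MEN1: cancers
  MLH1: cancers
  MSH2: cancers
  MSH6: cancers
  MUTYH: cancers
  MYBPC3: cardiovascular
  MYH11: cardiovascular
  MYH7: cardiovascular
  MYL2: cardiovascular
  MYL3: cardiovascular
  NF2: cancers
  OTC: others
  PCSK9: familial_hypercholesteremia
  PKP2: cardiovascular
  PMS2: cancers
  PRKAG2: cardiovascular
  PTEN: cancers
  RB1: cancers
  RET: cancers
  RYR1: malignant_hyperthermia
  RYR2: cardiovascular
  SCN5A: cardiovascular
  SDHAF2: cancers
  SDHB: cancers
  SDHC: cancers
  SDHD: cancers
  SMAD3: cardiovascular
  SMAD4: cancers
  STK11: cancers
  TGFBR1: cardiovascular
  TGFBR2: cardiovascular
  TMEM43: cardiovascular
  TNNI3: cardiovascular
  TNNT2: cardiovascular
  TP53: cancers
  TPM1: cardiovascular
  TSC1: cancers
  TSC2: cancers
  VHL: cancers
  WT1: cancers
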