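# Gene panel knowledge file: inheritance mode and gene category for every
# gene with a deleterious call in the study cohort.
# Categories: BRCA, TP53, MMR (mismatch repair: MLH1/MLH3/MSH3),
# CDH1, FA (Fanconi anemia pathway), OTHER.
genes:
  BRCA1: {inheritance: dominant, category: BRCA}
  BRCA2: {inheritance: dominant, category: BRCA}
  TP53: {inheritance: dominant, category: TP53}
  MLH1: {inheritance: dominant, category: MMR}
  MLH3: {inheritance: dominant, category: MMR}
  MSH3: {inheritance: dominant, category: MMR}
  CDH1: {inheritance: dominant, category: CDH1}
  RAD50: {inheritance: dominant, category: FA}
  PALB2: {inheritance: dominant, category: FA}
  FANCD2: {inheritance: dominant, category: FA}
  FANCI: {inheritance: dominant, category: FA}
  SLX4: {inheritance: dominant, category: FA}
  RAD51C: {inheritance: dominant, category: FA}
  RGSL1: {inheritance: dominant, category: OTHER}
  CDKN2A: {inheritance: dominant, category: OTHER}
  SPINK1: {inheritance: dominant, category: OTHER}
  TNFRSF13B: {inheritance: dominant, category: OTHER}
  FGFR3: {inheritance: dominant, category: OTHER}
  WRN: {inheritance: recessive, category: OTHER}
  MUTYH: {inheritance: recessive, category: OTHER}
  CYP17A1: {inheritance: recessive, category: OTHER}
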