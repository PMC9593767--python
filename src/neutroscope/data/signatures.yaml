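# Example functional signatures for neutrophil scoring.
# Gene lists are illustrative defaults drawn from the canonical human
# programs; supply your own YAML for other panels. Weighted signatures
# (aging) use +1 / -1 to mark genes rising / falling with the state.
apoptosis:
  genes: [CASP3, CASP8, CASP9, BAX, BAK1, FAS, TP53, PMAIP1, BBC3, CYCS, APAF1, DIABLO]
maturation:
  genes: [FCGR3B, CXCR2, SELL, IFIT1]
azurophil:
  genes: [MPO, ELANE, DEFA3, AZU1]
ifn_response:
  genes: [FTH1, TNFAIP3, SIGLEC10, CD14]
gelatinase:
  genes: [MMP9, HP, RGL4, FCN1]
aging:
  genes: [FCGR3B, CXCR2, SELL, IFIT1, MMP9, HP, RGL4, FCN1]
  weights:
    FCGR3B: 1
    CXCR2: 1
    SELL: 1
    IFIT1: 1
    MMP9: -1
    HP: -1
    RGL4: -1
    FCN1: -1
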