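# Literature-derived model of metabolic genes altered in cancer cells:
# regulators and enzymes of aerobic glycolysis (Warburg effect), de novo
# lipogenesis (incl. lipolysis/esterification), fatty-acid oxidation and
# cellular fatty-acid uptake.
categories:
  warburg:
    [HIF1A, MYC, POU2F1, PDK1, PFKFB4, PFKFB3, AKT1, MTOR, STK11, PRKAA1,
     PKM, TP53, C12ORF5, SCO2]
  lipogenesis:
    [ACLY, ACACA, ACACB, FASN, SREBF1, NR1H3, PPARA, RXRA, MLXIPL, DGAT1,
     DGAT2, LIPE, MGLL, PPARG, NR1H4, NR1I2]
  fa_oxidation:
    [CPT1C, CYP2E1, ACAA1, CYP4A11, CYP4A22, PPARD]
  fa_uptake:
    [CAV1, CD36, SLC27A1, SLC27A2, SLC27A3, SLC27A4, SLC27A5, SLC27A6,
     FABP1, FABP2, FABP3, FABP4, FABP5, FABP6, FABP7, PMP2, FABP9]
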