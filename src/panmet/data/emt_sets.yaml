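# Marker genes defining the EMT score (mesenchymal sum minus epithelial sum
# of log2 expression). The mesenchymal list is deduplicated to 8 genes.
mesenchymal: [CDH2, FN1, SNAI1, SNAI2, VIM, TWIST1, TWIST2, ZEB2]
epithelial: [CDH1, CLDN4, CLDN7, MUC1, TJP3]
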