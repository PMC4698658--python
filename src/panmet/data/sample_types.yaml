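# Normalization of raw sample-type labels (lower-cased before lookup) to the
# fixed vocabulary {normal, primary, metastatic, blood}. Editable.
primary tumor: primary
primary: primary
primary solid tumor: primary
metastatic: metastatic
metastasis: metastatic
solid tissue normal: normal
normal: normal
blood derived normal: blood
blood: blood
primary blood derived cancer - peripheral blood: blood
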