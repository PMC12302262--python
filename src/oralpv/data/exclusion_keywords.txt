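# Keywords flagging terms that match oral-cavity anatomy words but are
# biologically implausible as vaccine adverse events: contraceptive product
# terms, congenital malformations and oncologic diagnoses.
contracept
congenital
cleft
cancer
carcinoma
neoplasm
malignan
tumour
tumor
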