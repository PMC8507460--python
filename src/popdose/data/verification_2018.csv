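modality,billing_frequency_per_1000,ris_frequency_per_1000
Conventional radiography,439,421
CT,135,109
Diagnostic mammography,21.1,19.1
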