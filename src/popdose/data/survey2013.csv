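modality,frequency_per_1000,dose_per_inhabitant_msv
Conventional radiography,473,0.151
Diagnostic mammography,20,0.007
Screening mammography,11,0.004
Dental radiography (without CBCT),572,0.011
CBCT,6,0.001
CT,117,1.000
Conventional radioscopy,7,0.059
Coronary angioplasty (CA),6,0.080
Other diagnostic interventional radiological procedures,2,0.017
Percutaneous transluminal coronary angioplasty (PTCA),3,0.054
Other therapeutic interventional radiological procedures,2,0.034
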