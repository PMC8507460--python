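modality,frequency_per_1000,dose_vector_msv
Conventional radiography,439,0.32
Diagnostic mammography,21.1,0.36
Screening mammography,11.8,0.36
Dental radiography (without CBCT),584,0.02
CBCT,4.7,0.2
CT,135,7.08
Conventional radioscopy,5.5,8
Coronary angioplasty (CA),6.2,14
Other diagnostic interventional radiological procedures,3.7,8
Percutaneous transluminal coronary angioplasty (PTCA),3,20
Other therapeutic interventional radiological procedures,1.9,20
Nuclear medicine,13.3,8.04
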