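region,frequency_per_1000,median_effective_dose_msv
head,19,2.36
face/sinus,5.3,2.36
dental,0.2,0.6
neck,7.7,2.1
chest,15.9,3.8
abdomen,23.9,10.5
chest and abdomen,22.1,12.1
pelvis,10.6,7.9
spine,15.9,10.7
shoulder,1.1,5.8
elbow,0.6,3.2
wrist/hand,1.3,1.9
hip,3.6,11
knee,4.3,2.7
ankle/foot,3.4,0.06
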