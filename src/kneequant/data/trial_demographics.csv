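patient_id,gender,age,height_cm,weight_kg,bmi,injected_knee,kl_grade
01,F,63,160,73,29,L,3
02,M,78,169,72,25,R,3
03,F,67,146,64,30,L,3
04,M,72,171,75,26,R,2
05,F,65,159,59,23,R,2
06,F,77,154,54,23,R,2
07,F,79,162,60,23,R,4
08,M,51,162,68,26,R,2
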