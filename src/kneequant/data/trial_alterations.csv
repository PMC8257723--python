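patient_id,bone,region,metric,before,after
01,femur,posteromedial,area_ratio,-0.08,0.09
02,femur,posteromedial,area_ratio,-0.11,0.08
03,femur,posteromedial,area_ratio,-0.01,0.08
04,femur,posteromedial,area_ratio,0.00,0.06
05,femur,posteromedial,area_ratio,-0.16,0.04
06,femur,posteromedial,area_ratio,-0.13,0.02
07,femur,posteromedial,area_ratio,-0.08,0.00
08,femur,posteromedial,area_ratio,-0.01,-0.16
01,femur,posterolateral,area_ratio,0.02,-0.02
02,femur,posterolateral,area_ratio,0.01,-0.01
03,femur,posterolateral,area_ratio,0.15,-0.02
04,femur,posterolateral,area_ratio,0.06,-0.04
05,femur,posterolateral,area_ratio,0.02,0.01
06,femur,posterolateral,area_ratio,-0.11,0.12
07,femur,posterolateral,area_ratio,-0.04,0.22
08,femur,posterolateral,area_ratio,-0.02,-0.02
01,tibia,medial,area_ratio,-0.06,0.06
02,tibia,medial,area_ratio,-0.16,0.20
03,tibia,medial,area_ratio,-0.12,0.06
04,tibia,medial,area_ratio,-0.02,-0.14
05,tibia,medial,area_ratio,-0.08,-0.06
06,tibia,medial,area_ratio,0.04,-0.05
07,tibia,medial,area_ratio,0.02,-0.03
08,tibia,medial,area_ratio,0.08,-0.08
01,tibia,lateral,area_ratio,-0.01,0.02
02,tibia,lateral,area_ratio,0.01,-0.04
03,tibia,lateral,area_ratio,0.01,0.04
04,tibia,lateral,area_ratio,-0.05,0.00
05,tibia,lateral,area_ratio,-0.03,0.01
06,tibia,lateral,area_ratio,0.08,-0.03
07,tibia,lateral,area_ratio,0.22,-0.08
08,tibia,lateral,area_ratio,-0.02,-0.04
01,femur,posteromedial,mean_thickness_mm,-0.37,0.13
02,femur,posteromedial,mean_thickness_mm,-0.28,0.29
03,femur,posteromedial,mean_thickness_mm,-0.01,0.05
04,femur,posteromedial,mean_thickness_mm,-0.02,-0.06
05,femur,posteromedial,mean_thickness_mm,-0.30,0.13
06,femur,posteromedial,mean_thickness_mm,-0.13,0.03
07,femur,posteromedial,mean_thickness_mm,-0.16,-0.01
08,femur,posteromedial,mean_thickness_mm,-0.02,-0.55
01,femur,posterolateral,mean_thickness_mm,0.06,0.03
02,femur,posterolateral,mean_thickness_mm,-0.02,-0.02
03,femur,posterolateral,mean_thickness_mm,0.13,0.05
04,femur,posterolateral,mean_thickness_mm,0.07,0.03
05,femur,posterolateral,mean_thickness_mm,-0.11,0.08
06,femur,posterolateral,mean_thickness_mm,-0.19,0.25
07,femur,posterolateral,mean_thickness_mm,-0.40,0.57
08,femur,posterolateral,mean_thickness_mm,-0.06,0.01
01,tibia,medial,mean_thickness_mm,-0.10,0.07
02,tibia,medial,mean_thickness_mm,-0.38,0.57
03,tibia,medial,mean_thickness_mm,-0.06,0.03
04,tibia,medial,mean_thickness_mm,0.01,-0.15
05,tibia,medial,mean_thickness_mm,-0.11,-0.04
06,tibia,medial,mean_thickness_mm,0.17,-0.15
07,tibia,medial,mean_thickness_mm,0.06,-0.08
08,tibia,medial,mean_thickness_mm,0.21,-0.18
01,tibia,lateral,mean_thickness_mm,-0.05,0.08
02,tibia,lateral,mean_thickness_mm,0.06,-0.12
03,tibia,lateral,mean_thickness_mm,-0.07,-0.02
04,tibia,lateral,mean_thickness_mm,-0.10,-0.03
05,tibia,lateral,mean_thickness_mm,-0.06,-0.01
06,tibia,lateral,mean_thickness_mm,0.08,0.00
07,tibia,lateral,mean_thickness_mm,0.39,-0.09
08,tibia,lateral,mean_thickness_mm,0.08,-0.12
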