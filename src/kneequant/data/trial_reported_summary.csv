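bone,region,metric,period,stat,value
femur,posteromedial,area_ratio,before,median,-0.08
femur,posteromedial,area_ratio,before,q1,-0.12
femur,posteromedial,area_ratio,before,q3,-0.01
femur,posteromedial,area_ratio,after,median,0.05
femur,posteromedial,area_ratio,after,q1,0.01
femur,posteromedial,area_ratio,after,q3,0.08
femur,posterolateral,area_ratio,before,median,0.02
femur,posterolateral,area_ratio,before,q1,-0.03
femur,posterolateral,area_ratio,before,q3,0.04
femur,posterolateral,area_ratio,after,median,-0.02
femur,posterolateral,area_ratio,after,q1,-0.02
femur,posterolateral,area_ratio,after,q3,0.07
tibia,medial,area_ratio,before,median,-0.04
tibia,medial,area_ratio,before,q1,-0.10
tibia,medial,area_ratio,before,q3,0.03
tibia,medial,area_ratio,after,median,-0.04
tibia,medial,area_ratio,after,q1,-0.07
tibia,medial,area_ratio,after,q3,0.06
tibia,lateral,area_ratio,before,median,0.00
tibia,lateral,area_ratio,before,q1,-0.03
tibia,lateral,area_ratio,before,q3,0.05
tibia,lateral,area_ratio,after,median,-0.02
tibia,lateral,area_ratio,after,q1,-0.04
tibia,lateral,area_ratio,after,q3,0.02
femur,posteromedial,mean_thickness_mm,before,median,-0.15
femur,posteromedial,mean_thickness_mm,before,q1,-0.29
femur,posteromedial,mean_thickness_mm,before,q3,-0.02
femur,posteromedial,mean_thickness_mm,after,median,0.04
femur,posteromedial,mean_thickness_mm,after,q1,-0.04
femur,posteromedial,mean_thickness_mm,after,q3,0.13
femur,posterolateral,mean_thickness_mm,before,median,-0.04
femur,posterolateral,mean_thickness_mm,before,q1,-0.15
femur,posterolateral,mean_thickness_mm,before,q3,0.07
femur,posterolateral,mean_thickness_mm,after,median,0.04
femur,posterolateral,mean_thickness_mm,after,q1,0.02
femur,posterolateral,mean_thickness_mm,after,q3,0.17
tibia,medial,mean_thickness_mm,before,median,-0.03
tibia,medial,mean_thickness_mm,before,q1,-0.11
tibia,medial,mean_thickness_mm,before,q3,0.12
tibia,medial,mean_thickness_mm,after,median,-0.06
tibia,medial,mean_thickness_mm,after,q1,-0.15
tibia,medial,mean_thickness_mm,after,q3,0.05
tibia,lateral,mean_thickness_mm,before,median,0.01
tibia,lateral,mean_thickness_mm,before,q1,-0.07
tibia,lateral,mean_thickness_mm,before,q3,0.08
tibia,lateral,mean_thickness_mm,after,median,-0.03
tibia,lateral,mean_thickness_mm,after,q1,-0.11
tibia,lateral,mean_thickness_mm,after,q3,-0.01
femur,posteromedial,area_ratio,before_vs_after,p_value,0.031
femur,posterolateral,area_ratio,before_vs_after,p_value,0.469
tibia,medial,area_ratio,before_vs_after,p_value,0.387
tibia,lateral,area_ratio,before_vs_after,p_value,0.336
femur,posteromedial,mean_thickness_mm,before_vs_after,p_value,0.098
femur,posterolateral,mean_thickness_mm,before_vs_after,p_value,0.148
tibia,medial,mean_thickness_mm,before_vs_after,p_value,0.422
tibia,lateral,mean_thickness_mm,before_vs_after,p_value,0.184
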