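variable,mean,sd,min,max
age_yr,44.1,10.8,23,77
weight_kg,66.5,11.4,44,93
height_cm,163.7,6.3,149,176
bmi_kg_m2,24.9,4.4,16.6,33.7
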