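compartment,volume_fraction,flow_fraction,in_field
aorta,0.020,0.050,True
bone,0.070,0.050,True
brain,0.012,0.120,True
bronchi,0.003,0.010,True
fat,0.050,0.050,True
large_arteries,0.040,0.050,True
large_veins,0.080,0.050,True
lungs,0.105,0.030,True
lymph_nodes,0.002,0.010,True
skeletal_muscles,0.140,0.170,True
skin,0.030,0.050,True
stomach,0.010,0.010,True
esophagus,0.002,0.005,True
superior_vena_cava,0.010,0.030,True
thyroid,0.0006,0.015,True
residual_body,0.4254,0.300,True
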