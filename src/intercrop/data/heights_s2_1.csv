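year,configuration,crop,trait,mean,sd,units
2023,MM,maize,plant_height,205.7,,cm
2023,MA(3:1),maize,plant_height,199.97,,cm
2023,AM,alfalfa,plant_height,81.5,,cm
2023,MA(2:2),alfalfa,plant_height,80.35,,cm
2024,MM,maize,plant_height,206.4,,cm
2024,MA(3:1),maize,plant_height,200.04,,cm
2024,AM,alfalfa,plant_height,82.4,,cm
2024,MA(2:2),alfalfa,plant_height,80.65,,cm
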