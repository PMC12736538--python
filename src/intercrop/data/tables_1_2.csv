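year,configuration,crop,trait,mean,sd,units
2023,MM,maize,grain_yield,9470.3,813.05,kg ha-1
2023,MA(1:1),maize,grain_yield,6429.1,363.13,kg ha-1
2023,MA(2:1),maize,grain_yield,7691.3,462.36,kg ha-1
2023,MA(2:2),maize,grain_yield,7800.9,575.11,kg ha-1
2023,MA(3:1),maize,grain_yield,8534.0,922.06,kg ha-1
2023,MA(3:2),maize,grain_yield,8245.8,846.66,kg ha-1
2023,MA(3:3),maize,grain_yield,6771.4,317.67,kg ha-1
2024,MM,maize,grain_yield,9947.0,680.19,kg ha-1
2024,MA(1:1),maize,grain_yield,6386.2,320.48,kg ha-1
2024,MA(2:1),maize,grain_yield,8012.5,294.96,kg ha-1
2024,MA(2:2),maize,grain_yield,8211.4,308.56,kg ha-1
2024,MA(3:1),maize,grain_yield,9104.9,343.56,kg ha-1
2024,MA(3:2),maize,grain_yield,8370.8,913.50,kg ha-1
2024,MA(3:3),maize,grain_yield,7317.2,319.21,kg ha-1
2023,MM,maize,biomass_dm,12086.4,1479.7,kg ha-1
2023,MA(1:1),maize,biomass_dm,8564.3,1109.8,kg ha-1
2023,MA(2:1),maize,biomass_dm,9706.1,1257.7,kg ha-1
2023,MA(2:2),maize,biomass_dm,10277.2,1331.7,kg ha-1
2023,MA(3:1),maize,biomass_dm,10848.4,1405.7,kg ha-1
2023,MA(3:2),maize,biomass_dm,9935.1,1287.3,kg ha-1
2023,MA(3:3),maize,biomass_dm,9706.3,1257.7,kg ha-1
2024,MM,maize,biomass_dm,12598.3,1176.8,kg ha-1
2024,MA(1:1),maize,biomass_dm,9545.1,1388.1,kg ha-1
2024,MA(2:1),maize,biomass_dm,10141.4,1000.3,kg ha-1
2024,MA(2:2),maize,biomass_dm,10738.2,1059.1,kg ha-1
2024,MA(3:1),maize,biomass_dm,11335.1,1117.9,kg ha-1
2024,MA(3:2),maize,biomass_dm,10380.3,1023.8,kg ha-1
2024,MA(3:3),maize,biomass_dm,10141.2,1000.3,kg ha-1
2023,MM,maize,thousand_grain_weight,257.43,8.9,g
2023,MA(1:1),maize,thousand_grain_weight,229.14,7.8,g
2023,MA(2:1),maize,thousand_grain_weight,235.96,6.3,g
2023,MA(2:2),maize,thousand_grain_weight,236.78,4.7,g
2023,MA(3:1),maize,thousand_grain_weight,248.18,18.6,g
2023,MA(3:2),maize,thousand_grain_weight,237.39,17.8,g
2023,MA(3:3),maize,thousand_grain_weight,233.27,6.1,g
2024,MM,maize,thousand_grain_weight,256.45,10.9,g
2024,MA(1:1),maize,thousand_grain_weight,221.76,7.5,g
2024,MA(2:1),maize,thousand_grain_weight,235.98,7.9,g
2024,MA(2:2),maize,thousand_grain_weight,242.80,15.2,g
2024,MA(3:1),maize,thousand_grain_weight,248.40,15.6,g
2024,MA(3:2),maize,thousand_grain_weight,237.41,14.9,g
2024,MA(3:3),maize,thousand_grain_weight,233.28,9.4,g
2023,AM,alfalfa,forage_yield,11779.3,558.00,kg ha-1
2023,MA(1:1),alfalfa,forage_yield,8012.0,570.06,kg ha-1
2023,MA(2:1),alfalfa,forage_yield,6917.2,895.83,kg ha-1
2023,MA(2:2),alfalfa,forage_yield,8366.1,618.64,kg ha-1
2023,MA(3:1),alfalfa,forage_yield,5245.1,281.60,kg ha-1
2023,MA(3:2),alfalfa,forage_yield,5655.1,161.97,kg ha-1
2023,MA(3:3),alfalfa,forage_yield,6867.4,488.62,kg ha-1
2024,AM,alfalfa,forage_yield,12300.0,359.26,kg ha-1
2024,MA(1:1),alfalfa,forage_yield,8377.4,653.80,kg ha-1
2024,MA(2:1),alfalfa,forage_yield,6385.5,1312.70,kg ha-1
2024,MA(2:2),alfalfa,forage_yield,8412.2,596.88,kg ha-1
2024,MA(3:1),alfalfa,forage_yield,5120.9,816.24,kg ha-1
2024,MA(3:2),alfalfa,forage_yield,5646.3,228.63,kg ha-1
2024,MA(3:3),alfalfa,forage_yield,7180.2,560.40,kg ha-1
2023,AM,alfalfa,biomass_dm,9416.9,668.31,kg ha-1
2023,MA(1:1),alfalfa,biomass_dm,5835.1,409.64,kg ha-1
2023,MA(2:1),alfalfa,biomass_dm,4184.5,579.91,kg ha-1
2023,MA(2:2),alfalfa,biomass_dm,6868.3,455.07,kg ha-1
2023,MA(3:1),alfalfa,biomass_dm,3687.1,588.45,kg ha-1
2023,MA(3:2),alfalfa,biomass_dm,4393.3,314.96,kg ha-1
2023,MA(3:3),alfalfa,biomass_dm,6111.8,488.39,kg ha-1
2024,AM,alfalfa,biomass_dm,9807.1,660.40,kg ha-1
2024,MA(1:1),alfalfa,biomass_dm,6139.6,314.17,kg ha-1
2024,MA(2:1),alfalfa,biomass_dm,4450.7,454.34,kg ha-1
2024,MA(2:2),alfalfa,biomass_dm,7213.1,378.58,kg ha-1
2024,MA(3:1),alfalfa,biomass_dm,4179.5,285.58,kg ha-1
2024,MA(3:2),alfalfa,biomass_dm,4391.6,539.29,kg ha-1
2024,MA(3:3),alfalfa,biomass_dm,6232.3,340.38,kg ha-1
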