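# Printed per-product copigmentation-effectiveness values at pH 3.5 / 12% ethanol,
# one row per commercial copigment product, mean and SD of three replicates.
# Columns follow the source layout: A520, L*, a*, b*, hab, C*ab.
family,origin,product,A520_cp,A520_sd,L_cp,L_sd,a_cp,a_sd,b_cp,b_sd,hab_cp,hab_sd,Cab_cp,Cab_sd
reference,epicatechin,Epicatechin,0.061,0.008,-1.39,0.06,2.29,0.02,-1.15,0.09,-8.9,0.2,2.51,0.03
PC/PD,grapes,Grape 1,0.141,0.004,-2.09,0.60,2.26,0.50,-1.00,0.04,-7.2,0.3,2.45,0.05
PC/PD,grapes,Grape 2,0.145,0.002,-1.47,0.60,1.56,0.10,-0.86,0.06,-7.2,0.5,1.71,0.10
PC/PD,grapes,Grape 3,0.167,0.002,-1.84,0.00,1.93,0.20,-0.88,0.05,-7.5,0.4,2.01,0.06
PC/PD,seeds,Seed 1,0.128,0.001,-1.04,0.00,1.06,0.60,-0.47,0.05,-5.2,0.5,1.26,0.06
PC/PD,seeds,Seed 2,0.174,0.007,-2.70,0.00,2.43,0.50,-1.02,0.04,-7.9,0.5,2.49,0.04
PC/PD,seeds,Seed 3,0.073,0.002,-0.90,0.00,1.40,0.60,-0.63,0.04,-6.0,0.3,1.62,0.04
PC/PD,seeds,Seed 4,0.054,0.002,-0.63,0.00,1.25,0.70,-0.52,0.08,-5.3,0.8,1.45,0.03
PC/PD,skins,Skin 1,0.195,0.022,-1.96,0.07,1.81,0.04,-0.76,0.02,-6.7,0.9,2.04,0.13
PC/PD,skins,Skin 2,0.163,0.002,-2.49,0.07,2.37,0.08,-1.40,0.09,-11.3,0.8,2.65,0.05
PF/PR,acacia,Acacia 1,0.125,0.018,-1.41,0.06,0.91,0.08,-0.53,0.14,-4.6,0.5,1.07,0.06
PF/PR,acacia,Acacia 2,0.084,0.006,-1.18,0.14,1.18,0.07,-0.18,0.09,-1.4,0.8,1.20,0.08
PF/PR,quebracho,Quebracho 1,0.078,0.079,-0.97,0.07,1.14,0.04,-0.83,0.06,-7.9,0.7,1.33,0.04
PF/PR,quebracho,Quebracho 2,0.088,0.047,-1.23,0.07,1.80,0.04,-2.27,0.05,-8.1,0.6,1.28,0.11
PF/PR,quebracho,Quebracho 3,0.062,0.007,-1.09,0.06,0.97,0.13,-0.93,0.05,-9.2,1.6,1.39,0.08
PF/PR,quebracho,Quebracho 4,0.076,0.004,-1.13,0.06,1.13,0.15,-0.99,0.19,-9.6,0.8,1.32,0.16
PF/PR,quebracho,Quebracho 5,0.118,0.010,-1.49,0.10,1.55,0.11,-1.63,0.11,-14.4,0.5,1.91,0.12
PF/PR,quebracho,Quebracho 6,0.173,0.002,-2.65,0.06,2.72,0.03,-2.14,0.07,-16.0,0.3,3.17,0.03
GT,nut galls,Nut gall 1,0.302,0.014,-2.76,0.00,4.84,0.09,-2.48,0.10,-15.6,0.1,5.33,0.10
GT,nut galls,Nut gall 2,0.517,0.029,-4.86,0.21,7.01,0.05,-3.78,0.11,-20.0,0.1,7.72,0.06
GT,nut galls,Nut gall 3,0.234,0.007,-2.78,0.06,5.11,0.04,-2.41,0.04,-15.2,0.2,5.59,0.15
GT,nut galls,Nut gall 4,0.467,0.025,-4.36,0.07,6.69,0.12,-4.01,0.05,-23.5,0.1,7.55,0.13
GT,tara,Tara 1,0.520,0.047,-4.94,0.07,7.38,0.03,-4.21,0.07,-14.9,0.1,5.61,0.03
GT,tara,Tara 2,0.409,0.009,-5.18,0.06,7.42,0.07,-4.29,0.06,-12.9,0.1,4.61,0.06
GT,tara,Tara 3,0.588,0.008,-5.45,0.06,8.44,0.07,-5.65,0.04,-16.4,0.1,5.82,0.09
GT,tara,Tara 4,0.512,0.004,-4.90,0.06,7.41,0.06,-4.22,0.06,-14.8,0.2,8.59,0.06
ET,chestnut,Chestnut 1,0.400,0.012,-4.03,0.07,4.06,0.09,-3.48,0.06,-22.8,0.1,4.79,0.09
ET,chestnut,Chestnut 2,0.219,0.005,-3.48,0.12,3.96,0.04,-3.46,0.02,-23.5,0.1,4.72,0.13
ET,chestnut,Chestnut 3,0.219,0.009,-3.54,0.10,4.13,0.08,-3.48,0.06,-23.3,0.2,4.88,0.08
ET,oak,Oak 1,0.222,0.007,-3.06,0.07,5.98,0.10,-2.19,0.08,-15.3,0.1,3.83,0.11
ET,oak,Oak 2,0.307,0.089,-3.66,0.07,6.35,0.09,-5.32,0.09,-36.8,0.0,5.28,0.08
ET,oak,Oak 3,0.212,0.014,-2.79,0.00,5.28,0.10,-2.18,0.03,-22.4,0.1,3.03,0.10
ET,oak,Oak 4,0.290,0.036,-3.91,0.21,3.89,0.13,-6.16,0.07,-27.9,0.1,4.27,0.08
ET,oak,Oak 5,0.173,0.018,-2.44,0.12,5.08,0.08,-2.30,0.07,-17.9,0.1,2.73,0.13
ET,oak,Oak 6,0.262,0.008,-2.76,0.00,3.09,0.05,-2.32,0.08,-11.2,0.1,2.57,0.13
ET,oak,Oak 7,0.272,0.006,-2.91,0.07,4.00,0.11,-3.18,0.04,-10.0,0.1,2.78,0.07
ET,oak,Oak 8,0.353,0.090,-2.96,0.07,5.38,0.08,-2.41,0.04,-10.2,0.1,2.86,0.12
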