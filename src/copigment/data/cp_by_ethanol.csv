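# Printed copigmentation-effectiveness (Cp) slopes and r2 for five copigments
# plus the epicatechin reference at 10 / 12 / 14 % ethanol (pH 3.5).
# Cp/SD are mean +/- SD of three replicate slopes.
# Columns follow the source layout: A520, L*, C*ab, hab, a*, b*.
ethanol_pct,copigment,family,A520_cp,A520_sd,A520_r2,L_cp,L_sd,L_r2,Cab_cp,Cab_sd,Cab_r2,hab_cp,hab_sd,hab_r2,a_cp,a_sd,a_r2,b_cp,b_sd,b_r2
10,epicatechin,reference,0.15,0.00,0.9999,-1.75,0.00,0.9993,2.77,0.02,0.9989,-7.02,0.01,0.9717,2.62,0.02,0.9980,-1.19,0.04,0.9828
10,grape-seed,PC/PD,0.12,0.00,0.9991,-1.46,0.00,0.9909,1.83,0.03,0.9983,-6.27,0.01,0.9777,1.71,0.02,0.9984,-0.94,0.04,0.9842
10,grape-skin,PC/PD,0.14,0.00,0.9849,-2.11,0.00,0.9861,1.97,0.01,0.9827,-8.50,0.01,0.9967,2.15,0.01,0.9857,-1.27,0.04,0.9989
10,quebracho,PF/PR,0.12,0.01,0.9775,-2.03,0.00,0.9798,1.09,0.05,0.8761,-14.97,0.02,0.9875,1.53,0.05,0.9521,-1.94,0.13,0.9933
10,gallotannin,GT,0.47,0.00,0.9983,-6.30,0.00,0.9979,8.33,0.02,0.9979,-25.68,0.01,0.9424,9.39,0.02,0.9983,-5.49,0.07,0.9953
10,ellagitannin,ET,0.23,0.00,0.9983,-3.48,0.00,0.9996,4.43,0.02,0.9858,-20.82,0.00,0.9993,3.82,0.01,0.9871,-3.31,0.02,0.9952
12,epicatechin,reference,0.10,0.00,0.9845,-1.42,0.00,0.9935,1.78,0.16,0.9267,-3.55,0.01,0.9705,1.93,0.11,0.9778,-0.73,0.12,1.0000
12,grape-seed,PC/PD,0.07,0.00,0.9902,-0.56,0.00,0.3213,0.49,0.09,0.5663,-5.53,0.02,0.8155,0.30,0.06,0.4808,0.64,0.17,0.8378
12,grape-skin,PC/PD,0.08,0.00,0.8542,-1.59,0.00,0.9498,0.87,0.05,0.7500,-5.26,0.04,0.7940,1.35,0.05,0.9959,-0.63,0.07,0.8009
12,quebracho,PF/PR,0.22,0.00,0.9554,-3.24,0.00,0.9672,0.98,0.27,0.9600,-9.77,0.02,0.7591,1.10,0.19,0.9568,6.46,0.12,0.7987
12,gallotannin,GT,0.38,0.00,0.9999,-5.22,0.00,0.9994,6.88,0.04,0.9945,-19.07,0.02,0.9829,6.39,0.08,0.9990,-4.09,0.09,0.9986
12,ellagitannin,ET,0.16,0.00,0.9893,-2.72,0.00,0.9840,2.80,0.14,0.9932,-16.45,0.07,1.0000,2.05,0.10,0.9590,-2.25,0.46,0.9998
14,epicatechin,reference,0.09,0.00,0.9980,-1.17,0.00,0.9937,1.75,0.02,0.9977,-6.97,0.00,0.9963,1.60,0.02,0.9972,-1.08,0.02,0.9967
14,grape-seed,PC/PD,0.06,0.00,0.9954,-0.83,0.00,0.9868,1.52,0.02,0.9834,-35.41,0.00,0.8453,1.02,0.02,0.9999,-4.28,0.03,0.8536
14,grape-skin,PC/PD,0.09,0.00,0.9133,-1.44,0.00,0.9651,1.32,0.01,0.8271,-5.70,0.02,0.9218,1.20,0.01,0.8127,-0.87,0.06,0.9251
14,quebracho,PF/PR,0.06,0.00,0.7889,-1.35,0.00,0.7311,1.07,0.03,0.9791,-9.21,0.01,0.9875,0.87,0.02,0.9530,-1.14,0.04,0.9588
14,gallotannin,GT,0.34,0.00,0.9982,-4.52,0.00,0.9993,6.91,0.03,0.9981,-20.86,0.02,0.9644,6.11,0.03,0.9974,-4.23,0.08,0.9969
14,ellagitannin,ET,0.14,0.00,0.9328,-2.23,0.00,0.9516,2.89,0.01,0.9764,-16.15,0.03,0.9745,2.44,0.00,0.9680,-2.47,0.10,0.9898
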