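# Printed copigmentation-effectiveness (Cp) slopes and r2 for five copigments
# plus the epicatechin reference at pH 3.1 / 3.5 / 3.9 (12% ethanol).
# Cp/SD are mean +/- SD of three replicate slopes.
# Columns follow the source layout: A520, L*, C*ab, hab, a*, b*.
ph,copigment,family,A520_cp,A520_sd,A520_r2,L_cp,L_sd,L_r2,Cab_cp,Cab_sd,Cab_r2,hab_cp,hab_sd,hab_r2,a_cp,a_sd,a_r2,b_cp,b_sd,b_r2
3.1,epicatechin,reference,0.12,0.00,0.9997,-1.68,0.00,0.9881,2.40,0.02,0.9978,-5.50,0.00,0.9985,2.19,0.02,0.9976,-1.53,0.02,0.9828
3.1,grape-seed,PC/PD,0.11,0.00,0.9908,-1.55,0.01,0.9993,1.95,0.01,0.9925,-6.95,0.00,0.9987,1.70,0.01,0.9925,-1.70,0.04,0.9842
3.1,grape-skin,PC/PD,0.25,0.01,0.9768,-3.07,0.00,0.9856,3.97,0.00,0.9807,-4.96,0.00,0.9750,3.71,0.00,0.9779,-2.07,0.02,0.9989
3.1,quebracho,PF/PR,0.02,0.00,0.8904,-0.92,0.00,0.9758,0.13,0.04,0.7953,-7.87,0.00,0.9946,-0.16,0.03,0.8585,-1.61,0.04,0.9933
3.1,gallotannin,GT,0.22,0.00,0.8446,-3.02,0.00,0.8318,4.49,0.03,0.8377,-5.36,0.00,0.9173,3.98,0.02,0.8384,-3.18,0.04,0.9953
3.1,ellagitannin,ET,0.13,0.00,0.8334,-2.71,0.00,0.8824,2.52,0.01,0.8371,-13.05,0.00,0.9955,2.00,0.01,0.8233,-3.09,0.02,0.9952
3.5,epicatechin,reference,0.06,0.00,0.8940,-0.92,0.00,0.9231,1.20,0.03,0.8937,-4.06,0.00,0.9763,1.12,0.03,0.8744,-0.62,0.03,1.0000
3.5,grape-seed,PC/PD,0.07,0.00,0.9681,-1.00,0.00,1.0000,1.28,0.02,0.9619,-3.01,0.01,0.9776,1.23,0.02,0.9702,-0.52,0.04,0.8378
3.5,grape-skin,PC/PD,0.12,0.00,0.9581,-1.91,0.00,0.9791,2.01,0.06,0.9660,-7.74,0.01,0.9617,1.83,0.05,0.9610,-1.22,0.06,0.8009
3.5,quebracho,PF/PR,0.17,0.00,0.9251,-2.33,0.00,0.9018,2.50,0.06,0.9525,-8.74,0.01,0.9995,2.38,0.06,0.9562,-1.15,0.08,0.7987
3.5,gallotannin,GT,0.31,0.00,0.9885,-4.14,0.00,0.9832,6.23,0.03,0.9897,-16.75,0.01,0.9516,5.62,0.02,0.0885,-3.41,0.05,0.9986
3.5,ellagitannin,ET,0.15,0.00,0.9964,-2.48,0.00,0.9976,2.52,0.02,0.9959,-12.74,0.00,0.9828,2.19,0.01,0.9930,-1.90,0.01,0.9998
3.9,epicatechin,reference,0.08,0.00,1.0000,-1.08,0.00,0.9826,1.26,0.01,0.9922,-3.79,0.00,0.9932,1.20,0.01,0.9908,-0.45,0.02,0.9967
3.9,grape-seed,PC/PD,0.05,0.00,0.9873,-0.79,0.00,0.9973,0.71,0.01,0.9304,-7.63,0.07,1.0000,0.61,0.02,0.9131,-0.62,0.07,0.8536
3.9,grape-skin,PC/PD,0.06,0.01,0.9873,-0.92,0.00,0.8811,0.85,0.02,0.9996,-11.63,0.01,0.9001,0.70,0.01,0.7340,-0.15,0.13,0.9251
3.9,quebracho,PF/PR,0.05,0.00,0.9434,-1.75,0.00,0.9643,0.98,0.03,0.8275,-11.92,0.01,0.9826,0.80,0.03,0.9943,-3.07,0.05,0.9588
3.9,gallotannin,GT,0.15,0.00,0.9920,-2.08,0.00,0.9952,3.04,0.03,0.9954,-16.14,0.02,0.9924,2.74,0.02,0.9922,-1.75,0.05,0.9969
3.9,ellagitannin,ET,0.10,0.00,0.9510,-1.65,0.00,0.9443,1.62,0.01,0.9615,-18.34,0.02,0.9968,1.33,0.01,0.9692,-1.51,0.07,0.9898
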