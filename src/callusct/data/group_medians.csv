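group,variable,median,iqr
C,load,76.63,27.55
C,stiffness,93.52,107.48
C,bv_mm3,55.28,12.24
C,tmd_mgHAcm3,646.01,18.80
C,bmc_mg,35.81,7.90
C,smi,-0.3583,0.90
C,da,1.1524,0.04
C,bs,1381.08,336.06
C,tbth_mm,0.0961,0.006
D,load,66.33,32.72
D,stiffness,59.28,56.53
D,bv_mm3,49.81,13.95
D,tmd_mgHAcm3,626.60,30.91
D,bmc_mg,30.83,9.97
D,smi,0.0291,0.72
D,da,1.1296,0.06
D,bs,1241.11,404.17
D,tbth_mm,0.0942,0.007
P,load,46.28,32.81
P,stiffness,60.74,51.51
P,bv_mm3,76.73,21.69
P,tmd_mgHAcm3,643.25,15.70
P,bmc_mg,49.39,13.55
P,smi,-1.0147,1.42
P,da,1.1712,0.06
P,bs,1720.34,529.21
P,tbth_mm,0.1004,0.007
K,load,66.00,51.77
K,stiffness,107.76,136.57
K,bv_mm3,69.82,27.49
K,tmd_mgHAcm3,634.98,25.91
K,bmc_mg,44.32,15.66
K,smi,-0.146,1.19
K,da,1.1725,0.09
K,bs,1607.77,526.41
K,tbth_mm,0.0989,0.004
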