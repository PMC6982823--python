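experiment,pressure_bar,dp_um,q_co2_kg_h,kfa0_1e3_lito,kfa0_1e3_catchpole,kfa0_1e3_fitted,dab_1e9_lito,dab_1e9_catchpole,dab_1e9_fitted
1,220,650,0.604,1.41,1.46,0.736,8.63,9.06,2.97
2,220,220,0.602,6.56,6.77,1.72,8.63,9.06,1.06
3,80,650,1.202,0.114,0.118,8.70,38.0,40.2,0.73
4,80,650,1.209,0.114,0.119,8.95,38.0,40.2,0.76
5,80,220,0.602,0.355,0.369,3.42,38.0,40.2,1.04
6,80,650,0.603,7.63,7.93,4.03,38.0,40.2,13.3
7,140,650,1.204,2.67,2.77,1.26,10.7,11.3,3.15
8,180,220,0.913,9.19,9.51,0.773,9.4,9.9,6.61
9,180,220,0.904,9.14,9.46,0.929,9.4,9.9,8.79
10,180,650,0.908,1.97,2.04,2.64,9.4,9.9,13.4
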