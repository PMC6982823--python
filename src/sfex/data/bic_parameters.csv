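experiment,pressure_bar,dp_um,q_co2_kg_h,G_lito,G_catchpole,G_fitted,ksa0_1e5_lito,ksa0_1e5_catchpole,ksa0_1e5_fitted
1,220,650,0.604,0.36,0.36,0.37,7.48,7.48,7.35
2,220,220,0.602,0.61,0.61,0.61,7.01,7.01,7.01
3,80,650,1.202,0.39,0.39,0.40,0.182,0.182,0.182
4,80,650,1.209,0.36,0.36,0.37,0.107,0.107,0.107
5,80,220,0.602,0.52,0.52,0.52,9.28,9.28,9.30
6,80,650,0.603,0.44,0.44,0.45,7.58,7.58,7.58
7,140,650,1.204,0.35,0.35,0.37,7.83,7.84,7.71
8,180,220,0.913,0.62,0.62,0.66,2.75,2.75,2.31
9,180,220,0.904,0.54,0.54,0.59,2.32,2.32,1.91
10,180,650,0.908,0.23,0.23,0.23,0.108,0.108,0.108
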