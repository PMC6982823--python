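experiment,pressure_bar,dp_um,q_co2_kg_h,sh_lito,sh_catchpole,sh_fitted,r2_pct_lito,r2_pct_catchpole,r2_pct_fitted
1,220,650,0.604,0.24,0.24,0.96,98.478,98.477,98.472
2,220,220,0.602,0.13,0.13,4.16,99.352,99.352,99.355
3,80,650,1.202,0.45,0.44,0.06,99.716,99.716,99.718
4,80,650,1.209,0.45,0.44,0.05,99.632,99.632,99.626
5,80,220,0.602,0.16,0.16,1.24,99.297,99.297,99.357
6,80,650,0.603,0.30,0.30,0.13,98.302,98.301,98.322
7,140,650,1.204,0.37,0.37,0.40,98.548,98.541,98.663
8,180,220,0.913,0.17,0.16,5.84,98.268,98.268,99.137
9,180,220,0.904,0.17,0.16,5.11,98.421,98.421,99.019
10,180,650,0.908,0.31,0.31,0.29,99.381,99.381,99.381
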