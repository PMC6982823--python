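experiment,pressure_bar,dp_um,q_co2_kg_h,yield_pct
1,220,650,0.604,0.234
2,220,220,0.602,0.285
3,80,650,1.202,0.093
4,80,650,1.209,0.119
5,80,220,0.602,0.123
6,80,650,0.603,0.117
7,140,650,1.204,0.221
8,180,220,0.913,0.220
9,180,220,0.904,0.229
10,180,650,0.908,0.174
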