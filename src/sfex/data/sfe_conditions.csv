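experiment,pressure_bar,dp_um,q_co2_kg_h,rho_co2_kg_m3,mu_co2_1e5_kg_m_s
1,220,650,0.604,857.20,8.18
2,220,220,0.602,857.20,8.18
3,80,650,1.202,277.90,2.23
4,80,650,1.209,277.90,2.23
5,80,220,0.602,277.90,2.23
6,80,650,0.603,277.90,2.23
7,140,650,1.204,763.27,6.51
8,180,220,0.913,819.51,7.45
9,180,220,0.904,819.51,7.45
10,180,650,0.908,819.51,7.45
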