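volume_m3,com_usd_kg_y0.3,com_usd_kg_y0.5,com_usd_kg_y0.7,com_usd_kg_y1.0,com_usd_kg_y1.5
0.1,999.63,599.78,428.41,299.89,199.93
0.2,942.63,565.58,403.99,282.79,188.53
0.4,952.04,571.22,408.02,285.61,190.41
0.6,945.12,567.07,405.05,283.53,189.02
1.0,813.95,488.37,348.83,244.18,162.79
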