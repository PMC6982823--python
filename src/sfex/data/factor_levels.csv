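factor,symbol,low,high
pressure_bar,x1,80,220
dp_um,x2,220,650
flow_kg_h,x3,0.6,1.2
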