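volume_l,height_m,diameter_m,aspect_ratio,fci_usd
100,2.01,0.252,8.0,853975
200,2.54,0.317,8.0,1378550
400,3.19,0.399,8.0,2225400
600,3.66,0.457,8.0,2944900
1000,4.34,0.542,8.0,4191250
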