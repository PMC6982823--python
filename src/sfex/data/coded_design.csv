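experiment,x1,x2,x3,yield_design_pct
1,1.0000,1.0000,-0.9934,0.23
2,1.0000,-1.0000,-1.0000,0.28
3,-1.0000,1.0000,0.9769,0.09
4,-1.0000,1.0000,1.0000,0.12
5,-1.0000,-1.0000,-1.0000,0.12
6,-1.0000,1.0000,-0.9967,0.12
7,-0.1429,1.0000,0.9835,0.22
8,0.4286,-1.0000,0.0247,0.22
9,0.4286,-1.0000,-0.0049,0.23
10,0.4286,1.0000,0.0082,0.17
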