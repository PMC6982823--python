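coefficient,value,t_statistic,significance
a0,0.183,12.43,***
a1,0.084,3.71,*
a2,0.000,0.01,99.1%
a3,-0.002,-0.10,92.2%
a12,-0.013,-0.80,48.5%
a13,0.017,0.71,53.3%
a23,0.019,0.86,45.3%
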