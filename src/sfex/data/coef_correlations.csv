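term,a1,a2,a3,a12,a13,a23
a1,1.0000,-0.3039,-0.3291,0.2608,-0.3623,-0.2981
a2,-0.3039,1.0000,0.3909,-0.0455,-0.2335,-0.2095
a3,-0.3291,0.3909,1.0000,-0.3748,-0.3771,0.4994
a12,0.2608,-0.0455,-0.3748,1.0000,0.2565,-0.2247
a13,-0.3623,-0.2335,-0.3771,0.2565,1.0000,-0.2563
a23,-0.2981,-0.2095,0.4994,-0.2247,-0.2563,1.0000
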