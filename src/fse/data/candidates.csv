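,e1,e2,e3,e4,e5
x1,0.85,0.71,0.38,0.32,0.75
x2,0.56,0.82,0.76,0.64,0.43
x3,0.84,0.51,0.82,0.53,0.47
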