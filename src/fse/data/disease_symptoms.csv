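,e1,e2,e3,e4,e5,e6,e7
d1,0.6,0,0.6,0.9,0,0.7,0.8
d2,0.2,0,0.1,0.9,0.8,0,0
d3,0.3,0.7,0.3,0.8,0.3,0.4,0
d4,0.4,0,0.2,0.7,0.1,0.6,0.5
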