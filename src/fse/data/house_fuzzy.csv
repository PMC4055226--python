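,e1,e2,e3,e4
h1,1,1,0.1,0.1
h2,1,0.1,0.4,0.3
h3,0.2,0.3,1,1
h4,0.3,0.2,1,1
h5,1,0.1,0,0
h6,0.7,0.9,0.1,1
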