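,e1,e2,e3,e4
h1,1,1,0,0
h2,1,0,0,0
h3,0,0,1,1
h4,0,0,0,1
h5,0,0,1,0
h6,1,1,0,1
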