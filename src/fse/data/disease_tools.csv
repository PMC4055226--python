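,s1,s2,s3
d1,0.6,0.8,0.4
d2,0.8,0.3,0.6
d3,0.8,0.4,0.7
d4,0.6,0.8,0.3
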