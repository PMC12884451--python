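from,124A,122A,122D,124D,ReA-
124A,,5,31,0.2,10
122A,14,,11,18,0
122D,25,41,,7,0
124D,0.1,31,8,,
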