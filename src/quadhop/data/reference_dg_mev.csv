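from,124A,122A,122D,124D
124A,0,67,-320,172
122A,-67,0,-296,18
122D,320,296,0,262
124D,-172,-18,-262,0
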