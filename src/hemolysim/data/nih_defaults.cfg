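# loop-experiment constants (L, %, L/min, min, g/L, mg/dL per HI%)
V = 1.0
Ht = 37.0
Q = 5.0
T = 30.0
kappa = 110.0
k = 4.63
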