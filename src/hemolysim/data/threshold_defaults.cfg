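# critical-stress threshold law (Pa, s, days)
coefficient = 88.905
exponent = -0.3372
lifespan_days = 115.0
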