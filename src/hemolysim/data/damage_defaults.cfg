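# power-law damage model constants (stress Pa, time s, HI %)
C = 3.62e-05
alpha = 2.416
beta = 0.785
threshold_stress = 25.0
aging_stress = 0.3886
HI0 = 5.5
correction_factor = 0.0416
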