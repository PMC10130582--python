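# hemolysim

Aging-aware hemolysis estimation for rotary blood pumps.

Ventricular assist devices expose red blood cells to non-physiological
shear stress, and the released plasma-free hemoglobin — hemolysis — is the
central blood-damage figure of merit in pump design. CFD-based design
loops estimate it by tracking particles through the flow field and feeding
each trace's stress history into an empirical damage model. `hemolysim`
implements that post-processing chain for engineers and researchers
working on blood-contacting devices:

* the **power-law kernel** `HI = C·τ^α·t^β` (HI in percent, τ in Pa, t in
  s; defaults C = 3.62×10⁻⁵, α = 2.416, β = 0.785),
* **effective-time (shear-history) accumulation**: before each new stress
  level the damage already accrued is re-expressed as the equivalent
  exposure time at the new level,
  `t_eff = ((τ_{i-1}^α · t_{i-1}^β)/τ_i^α)^{1/β}`, so constant-stress
  results are independent of discretization,
* an **aging-aware model**: intervals at or below the physiological
  threshold (25 Pa) are replaced by the red cell's lifetime-equivalent
  stress — the critical-stress law `τ_crit = 88.905·t^{-0.3372}` evaluated
  at a 115-day lifespan, 0.3886 Pa — and the blood's initial hemolysis
  HI₀ = 5.5 % seeds the damage state and is subtracted from the result,
* **stress-tensor scalarization** (von-Mises-type equivalent shear),
  pathline file IO, per-trace and ensemble estimation with the low-stress
  correction factor 0.0416 on C,
* **NIH / free-hemoglobin conversions** linking model HI to loop-bench
  measurements, red-cell biconcave-shape and Kelvin–Voigt membrane closed
  forms, and synthetic ramp/spike load generators.

## Worked example

Estimate single-history damage with and without the aging treatment:

```python
from hemolysim import StressHistory, accumulate_effective, accumulate_novel

h = StressHistory(times=[0.5, 1.0, 1.5], stresses=[100.0, 10.0, 200.0])
print("HIeff =", accumulate_effective(h).final_hi)
nov = accumulate_novel(h)
print("HInew raw =", nov.final_hi, "increment =", nov.hi_increment)
```

```
HIeff = 8.315363952344324
HInew raw = 11.96998542566541 increment = 6.46998542566541
```

`HIeff` is the plain shear-history estimate: the 10 Pa interval is fed to
the power law as-is. The aging-aware model replaces it with the
0.3886 Pa aging stress, starts from the effective time equivalent to the
blood's 5.5 % initial hemolysis, and reports the device-attributable
increment 6.47 % — lower than 8.32 % because damage is concave in exposure
(β < 1), so pre-damaged blood accrues less marginal damage.

The same comparison over a pump-pass ensemble, from the shell:

```sh
hemolysim estimate --input examples/spike_traces.csv --model effective --output eff.csv
hemolysim estimate --input examples/spike_traces.csv --model novel    --output nov.csv
```

```
10 traces, model=effective: mean HI = 0.00868505 % (sd 0.00355616 %)
10 traces, model=novel: mean HI = 0.00119517 % (sd 0.000612194 %)
```

Each trace in `examples/spike_traces.csv` (generated by
`hemolysim simulate`) is one 50 ms pump transit: a ~10 Pa physiological
background with a sub-threshold-to-150 Pa impeller spike. Because the
traces visit the ≤ 25 Pa regime, C is automatically corrected by 0.0416
for both models; the aging-aware estimate is about sevenfold lower, the
direction in which loop experiments differ from plain power-law
predictions. `hemolysim convert` moves between HI, plasma-free hemoglobin
(mg/dL) and NIH (g/100L); `hemolysim shape` dumps the biconcave cell
contour.

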