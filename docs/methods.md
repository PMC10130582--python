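# Methods

## The damage model

The kernel is the empirical power law

    HI(τ, t) = C · τ^α · t^β      [HI in %, τ in Pa, t in s]

with defaults C = 3.62×10⁻⁵, α = 2.416, β = 0.785 — the regression
constants of the classic bovine-blood shear experiments. All HI values in
this package live on the 0–100 percent scale, never as fractions.

A note on β: the constant circulates in the literature in two variants,
0.785 and a transposed 0.875. The worked anchor value — HI = 14.957 % at
700 Pa for 25 ms — is reproduced only by β = 0.785 (direct evaluation
gives 14.9571; with 0.875 it gives 10.7), so 0.785 is the default and the
other variant is available by override.

### Effective-time accumulation

The power law describes constant loading only. For a piecewise-constant
stress history the damage state is carried across stress levels by the
*effective time*: before interval *i* the accumulated damage is
re-expressed as the exposure at the new stress that would have produced
it,

    t_eff = ((τ_{i-1}^α · T_{i-1}^β) / τ_i^α)^{1/β}
          = (τ_{i-1}/τ_i)^{α/β} · T_{i-1},

where T_{i-1} is the running equivalent duration; then
HI_i = C·τ_i^α·(t_eff + Δt_i)^β. Because the construction preserves the
damage level across substitutions, the cumulative HI is non-decreasing
and a constant-stress history yields the same result under any
discretization (verified to 1e-10 relative in the tests).

Numerical choices at the edges:

* **Zero-stress intervals.** The equivalence is singular at τ = 0: no
  finite exposure at zero stress represents positive damage. Zero-stress
  intervals therefore contribute no damage and freeze the (reference
  stress, equivalent duration) pair; this is the τ→0 limit of the
  increment and keeps damage monotone.
* **First interval.** With no prior interval and no seeding, t_eff = 0.
* The implementation steps the stress-ratio form; the test oracle
  re-derives each step from the damage-based form
  `t_eff = (HI_prev/(C·τ^α))^{1/β}`, an algebraically independent route.

### Aging equivalence and the initial hemolysis

The critical-stress threshold law τ_crit = 88.905·t^(−0.3372) (Pa, s)
gives the stress below which a given exposure causes no hemolysis.
Evaluated at the mean red-cell lifespan (115 days × 86 400 s/day) it
yields 0.3886 Pa: the constant stress a cell can sustain for exactly one
lifetime. The aging-aware model uses it two ways:

1. **Substitution.** Any interval with raw stress ≤ 25 Pa (boundary
   inclusive) is physiological loading — aging, not mechanical damage —
   and its stress is replaced by 0.3886 Pa. The substitution is
   idempotent, and supra-threshold intervals are untouched.
2. **Seeding.** Circulating blood already carries free hemoglobin
   (HI₀ = 5.5 %, i.e. a 25.47 mg/dL baseline at k = 4.63 mg/dL per HI %).
   With seeding on, the starting effective time solves
   HI₀ = C·τ₁^α·t₀^β at the first (substituted) stress level, and HI₀ is
   subtracted from the final index, floored at zero. The reported
   increment is thus the device-attributable damage, and since β < 1
   makes HI concave in exposure, pre-damaged blood accrues *less*
   marginal damage — the mechanism by which this model predicts lower,
   experiment-ward estimates.

The seeding semantics were a genuinely open design point: the defining
relation `HI_new = HI_i − HI₀` does not by itself say how HI₀ enters
HI_i. Seeding-then-subtracting is the only reading under which (a) the
result is non-negative by construction, (b) fully supra-threshold
histories with externally supplied initial values make the aging model
coincide with the plain effective-time model, and (c) mixed-regime pump
estimates drop toward measured values. The alternative — no seeding —
is available behind the `seed_initial` flag; it reduces the model to
effective-time accumulation on the substituted stresses.

### Low-stress correction

The power-law constants were regressed on high-stress data and
overpredict mixed-regime loading. For any trace containing an interval at
or below the 25 Pa threshold, C is multiplied by 0.0416 (giving
1.5×10⁻⁶). The trigger is per-trace — the correction rescales the model
constant, not individual intervals — with a global on/off override.
Whether the original procedure applied it per-trace or globally is not
specified; per-trace is the conservative reading and is documented here
as this package's choice.

## Pathline post-processing

Tensor samples (six components of a symmetric viscous stress tensor) are
reduced to the scalar equivalent shear

    τ_s = sqrt((1/6)·[(τ11−τ22)² + (τ22−τ33)² + (τ11−τ33)²]
               + τ12² + τ13² + τ23²),

which is invariant to hydrostatic shifts and returns exactly the applied
shear for a pure-shear state (the off-diagonal sum runs over the three
distinct pairs — with all six ordered pairs a pure shear of magnitude s
would map to s·√2, breaking the interchangeable use of scalar stress and
applied shear). When building tensors from a velocity gradient,
η·∂v_i/∂x_j is symmetrized first, since the scalarization presumes a
symmetric tensor and a rigid rotation must produce no stress.

Stress *samples* at times t₀…t_n become n piecewise-constant intervals.
The default assigns each interval the stress at its left endpoint —
samples are CFD snapshots, so left-constant is the simplest causal
convention; right-endpoint and midpoint conventions are available for
sensitivity checks, and how the original traces were discretized is not
recorded anywhere, so this is a package choice.

Three estimation models are exposed per trace: `powerlaw` (the naive
baseline — the kernel evaluated once with the time-weighted mean stress
and total transit time), `effective`, and `novel` (aging-aware, the
default). Ensemble estimates are the arithmetic mean of per-trace values
(the damage increment for the seeded aging model), with the sample
standard deviation as dispersion; a failing trace aborts with its
identifier unless `skip_failures` logs it as NaN.

## Conversions

k = 4.63 mg/dL of plasma-free hemoglobin per HI percent is treated as an
empirical constant of the blood preparation ("mg%" is read as mg/dL
throughout, the standard clinical usage). The normalized index of
hemolysis is computed in g/100L,

    NIH = ΔfreeHb · V · (100 − Ht)/100 · 100/(Q·T),

with loop defaults V = 1 L, Ht = 37 %, Q = 5 L/min, T = 30 min, and the
bench hemolysis index is NIH·100/((100 − Ht)·κ) with κ = 110 g/L total
hemoglobin. The κ placement follows from dimensional analysis — HI must
be released-over-total hemoglobin — and reproduces the observed magnitude
of bench HI values (~10⁻⁴ %). ΔfreeHb comes from an ordinary
least-squares slope over the sampled free-hemoglobin time series
(scipy's linregress), scaled by the sampling interval.

## Red-cell geometry and membrane

The resting shape is the Evans–Fung biconcave parametrization with
D₀ = 7.82 μm and thickness coefficients (0.0518, 2.0026, −4.491); the
published rendering of the formula is typeset ambiguously, but the
coefficients are exactly the Evans–Fung constants, which fixes the
reconstruction. "Perimeter" is the arc length of the meridional x–z
cross-section (both branches), computed by dense polyline integration —
the convention of 2D shear-flow morphology studies; whether a 3D
surface-derived measure was meant elsewhere is not inferable, so the 2D
reading is documented as the package's definition. The membrane is a
Kelvin–Voigt solid: G = E/(2(1+ν)) = 172.4 Pa at E = 500 Pa, ν = 0.45;
relaxation time η/G = 1.276×10⁻⁴ s at η = 0.022 Pa·s; creep strain
(σ₀/G)(1 − e^(−t/τ)). The coupled fluid–structure problem of a cell in a
shear box is out of scope — only the closed forms are implemented, and
the plate relation v = τ·δ/μ is exposed as a pure formula because no gap
width is fixed by the source data.

## Synthetic data

The generators produce the two loading shapes the models are exercised
on: monotone ramps (bench shear-loading experiments; default 200→50 Pa
over 60 s in 1 s steps) and single pump-pass spikes (default: 50 ms
transit at a 10 Pa physiological background rising to 150 Pa at 30 % of
the pass — loosely the shape of a particle transit near an axial
impeller, chosen once as representative; no published trace was
digitized). Ensembles jitter peak stresses by unit-median lognormal
factors (relative sd 0.2 by default) — lognormal keeps stresses positive,
and no trace-to-trace variability model exists to match. Generation is a
pure function of (spec, seed).

What the synthetic data do **not** emulate: the true stress distribution
of any real pump (no turbulence, no multi-pass recirculation, no
residence-time distribution), measurement noise of the free-hemoglobin
assay, or temperature effects. Passing tests therefore demonstrate the
correctness of the damage algebra and its invariants, not predictive
accuracy for a physical device.

## Known limitations

* The interval-stepped models have no continuous-time (ODE) counterpart
  here, by design.
* Bench-measured hemolysis of a specific pump cannot be reproduced
  without that pump's trace data; the package validates against closed
  forms, algebraic identities, and independent step-by-step re-evaluation
  instead.
* Default problem sizes (tens to hundreds of synthetic traces, ≤ a few
  thousand intervals) keep the full suite in seconds; all generators
  scale to larger ensembles linearly.
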