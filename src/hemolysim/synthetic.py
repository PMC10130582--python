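"""Synthetic stress histories and pathline ensembles.

Two loading shapes cover the regimes in which hemolysis models are
exercised:

* **ramps** — monotone increase or decrease of shear stress over tens of
  seconds, the shape of bench shear-loading experiments on blood;
* **spikes** — a single pass through a pump: a long low-stress transit
  with a sub-millisecond high-stress excursion near the impeller.

Ensembles of spike traces with lognormally jittered peak stresses emulate
the trace-to-trace variability of Lagrangian particle tracking through a
pump flow field.  Generation is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .accumulation import StressHistory
from .pathlines import PathlineSet

__all__ = ["RampSpec", "SpikeSpec", "ramp_history", "spike_history", "ensemble"]


@dataclass(frozen=True)
class RampSpec:
    """Linear stress ramp: ``start_stress`` to ``end_stress`` (Pa) over
    ``duration`` seconds in ``n_steps`` equal intervals."""

    start_stress: float = 200.0
    end_stress: float = 50.0
    duration: float = 60.0
    n_steps: int = 60

    def __post_init__(self) -> None:
        if self.start_stress < 0 or self.end_stress < 0:
            raise ValueError("ramp stresses must be non-negative")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be at least 1")


@dataclass(frozen=True)
class SpikeSpec:
    """Single pump-pass profile: low base stress, a linear rise to
    ``peak_stress`` peaking at ``rise_fraction`` of the pass, then a linear
    fall back to base.

    Defaults describe one transit through an axial pump: a 50 ms pass at a
    physiological ~10 Pa background with a short excursion to 150 Pa near
    the impeller.
    """

    base_stress: float = 10.0
    peak_stress: float = 150.0
    pass_duration: float = 0.05
    rise_fraction: float = 0.3
    n_samples: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.peak_stress >= self.base_stress >= 0:
            raise ValueError("require peak_stress >= base_stress >= 0")
        if not self.pass_duration > 0:
            raise ValueError("pass_duration must be positive")
        if not 0 < self.rise_fraction < 1:
            raise ValueError("rise_fraction must lie in (0, 1)")
        if self.n_samples < 3:
            raise ValueError("n_samples must be at least 3")


def ramp_history(spec: RampSpec) -> StressHistory:
    """Stress history of ``n_steps`` equal intervals with stresses linearly
    interpolated between start and end (each interval carries its midpoint
    stress, so a one-step ramp uses the mean of start and end)."""
    times = np.linspace(0.0, spec.duration, spec.n_steps + 1)[1:]
    frac = (np.arange(spec.n_steps) + 0.5) / spec.n_steps
    stresses = spec.start_stress + (spec.end_stress - spec.start_stress) * frac
    return StressHistory(times=times, stresses=stresses, start_time=0.0)


def _spike_profile(spec: SpikeSpec, t: np.ndarray) -> np.ndarray:
    t_peak = spec.rise_fraction * spec.pass_duration
    rise = spec.base_stress + (spec.peak_stress - spec.base_stress) * t / t_peak
    fall = spec.peak_stress - (spec.peak_stress - spec.base_stress) * (
        t - t_peak
    ) / (spec.pass_duration - t_peak)
    return np.where(t <= t_peak, rise, fall)


def spike_history(spec: SpikeSpec) -> StressHistory:
    """Piecewise-constant sampling of the triangular spike profile.

    Sample times are ``n_samples`` uniform points over the pass plus the
    exact peak time, so the generated maximum equals ``peak_stress``.
    Deterministic for a fixed spec.
    """
    t_peak = spec.rise_fraction * spec.pass_duration
    times = np.union1d(np.linspace(0.0, spec.pass_duration, spec.n_samples), [t_peak])
    stresses = _spike_profile(spec, times)
    return StressHistory.from_samples(times, stresses, convention="left")


def ensemble(
    spec: SpikeSpec,
    n_traces: int = 100,
    jitter: float = 0.2,
    seed: int | None = None,
) -> PathlineSet:
    """Ensemble of spike traces with lognormally jittered peak stresses.

    Peak stresses are multiplied by independent lognormal factors with
    unit median and relative standard deviation ``jitter`` (lognormal
    keeps stresses positive; the median is peak-preserving).  ``seed``
    overrides ``spec.seed``; identical (spec, seed) reproduce the ensemble
    exactly.
    """
    if n_traces < 1:
        raise ValueError("n_traces must be at least 1")
    if jitter < 0:
        raise ValueError("jitter must be non-negative")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if jitter == 0:
        factors = np.ones(n_traces)
    else:
        # sigma chosen so the factor's sd/mean equals `jitter`; median stays 1.
        sigma = np.sqrt(np.log1p(jitter**2))
        factors = np.exp(sigma * rng.standard_normal(n_traces))
    width = len(str(n_traces - 1))
    traces = {}
    for i, f in enumerate(factors):
        peak = max(spec.peak_stress * f, spec.base_stress)
        traces[f"trace{i:0{width}d}"] = spike_history(replace(spec, peak_stress=peak))
    return PathlineSet(traces)
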