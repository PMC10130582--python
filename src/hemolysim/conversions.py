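"""Conversions between model hemolysis indices and bench measurements.

The hemolysis index HI (percent) is the increment of plasma-free
hemoglobin divided by total blood hemoglobin.  Loop experiments instead
report plasma-free hemoglobin concentrations (mg/dL, clinically written
"mg%") and the normalized index of hemolysis NIH (g of hemoglobin released
per 100 L pumped).  This module holds the linear algebra connecting them:

* ``delta_PfHb = k * HI`` with the empirical coefficient k (default
  4.63 mg/dL per HI %), and its inverse for the initial hemolysis HI0;
* ``NIH [g/100L] = dfreeHb * V * (100 - Ht)/100 * 100/(Q*T)``;
* ``HI_exp [%] = NIH * 100 / ((100 - Ht) * kappa)``, i.e. NIH re-expressed
  as a released-to-total hemoglobin ratio.

All HI values are on the 0-100 percent scale, never fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._config import read_flat_config, write_flat_config

__all__ = [
    "NIHContext",
    "hi_to_delta_pfhb",
    "initial_hi",
    "nih",
    "nih_to_hi",
    "freehb_slope",
]


@dataclass(frozen=True)
class NIHContext:
    """Loop-experiment constants for NIH and HI conversions.

    V: circulating blood volume (L); Ht: hematocrit (%); Q: flow rate
    (L/min); T: sampling interval (min); kappa: total hemoglobin (g/L);
    k: mg/dL of plasma-free hemoglobin per percent of HI.
    """

    V: float = 1.0
    Ht: float = 37.0
    Q: float = 5.0
    T: float = 30.0
    kappa: float = 110.0
    k: float = 4.63

    def __post_init__(self) -> None:
        for name in ("V", "Q", "T", "kappa", "k"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0 < self.Ht < 100:
            raise ValueError(f"hematocrit must lie in (0, 100) %, got {self.Ht}")

    def to_file(self, path) -> None:
        write_flat_config(
            path,
            {f: getattr(self, f) for f in self.__dataclass_fields__},
            header="loop-experiment constants (L, %, L/min, min, g/L, mg/dL per HI%)",
        )

    @classmethod
    def from_file(cls, path) -> "NIHContext":
        return cls(**read_flat_config(path, set(cls.__dataclass_fields__)))


def hi_to_delta_pfhb(hi: float, k: float = 4.63) -> float:
    """Plasma-free hemoglobin increment (mg/dL) for a hemolysis index (%)."""
    if hi < 0:
        raise ValueError(f"HI must be non-negative, got {hi}")
    return hi * k


def initial_hi(pfhb0: float, k: float = 4.63) -> float:
    """Initial hemolysis index (%) from a baseline free-hemoglobin level.

    Inverse of :func:`hi_to_delta_pfhb`: ``HI0 = PfHb0 / k`` with PfHb0 in
    mg/dL.  The published baseline 25.47 mg/dL gives HI0 = 5.5 %.
    """
    if pfhb0 < 0:
        raise ValueError(f"PfHb0 must be non-negative, got {pfhb0}")
    if k == 0:
        raise ValueError("conversion coefficient k must be nonzero")
    return pfhb0 / k


def nih(delta_freehb: float, ctx: NIHContext | None = None) -> float:
    """Normalized index of hemolysis (g/100L).

    ``delta_freehb`` is the free-hemoglobin increment (g/L) over one
    sampling interval.  The index normalizes the released mass by plasma
    fraction and pumped volume: ``dfreeHb * V * (100-Ht)/100 * 100/(Q*T)``.
    """
    if ctx is None:
        ctx = NIHContext()
    if delta_freehb < 0:
        raise ValueError(f"delta_freehb must be non-negative, got {delta_freehb}")
    return delta_freehb * ctx.V * (100.0 - ctx.Ht) / 100.0 * 100.0 / (ctx.Q * ctx.T)


def nih_to_hi(nih_value: float, ctx: NIHContext | None = None) -> float:
    """Experimental hemolysis index (%) from an NIH value (g/100L).

    ``HI = NIH * 100 / ((100 - Ht) * kappa)`` — the released hemoglobin
    renormalized by the total hemoglobin ``kappa``, which makes HI the
    dimensionless released-to-total ratio on the percent scale.
    """
    if ctx is None:
        ctx = NIHContext()
    if nih_value < 0:
        raise ValueError(f"NIH must be non-negative, got {nih_value}")
    return nih_value * 100.0 / ((100.0 - ctx.Ht) * ctx.kappa)


def freehb_slope(times_min, freehb_gl, interval_T: float = 30.0) -> float:
    """Free-hemoglobin increment per sampling interval by OLS regression.

    Fits a least-squares line to (time in min, freeHb in g/L) samples; the
    slope times ``interval_T`` is the per-interval increment consumed by
    :func:`nih`.  Needs at least two samples at distinct times.
    """
    times = np.asarray(times_min, dtype=float)
    values = np.asarray(freehb_gl, dtype=float)
    if times.shape != values.shape or times.ndim != 1:
        raise ValueError("times and freeHb values must be equal-length 1-D arrays")
    if len(times) < 2:
        raise ValueError("need at least two samples to estimate a slope")
    if np.ptp(times) == 0:
        raise ValueError("sample times are all identical; slope is undefined")
    if not interval_T > 0:
        raise ValueError(f"interval_T must be positive, got {interval_T}")
    result = stats.linregress(times, values)
    return float(result.slope) * interval_T
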