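"""Pathline post-processing: from CFD particle traces to hemolysis numbers.

A Lagrangian trace carries either a scalar shear stress or the six
independent components of a symmetric stress tensor at each time sample.
Tensor samples are reduced to a scalar equivalent shear stress with the
von-Mises-type combination

    tau_s = sqrt( (1/6) * [(t11-t22)^2 + (t22-t33)^2 + (t11-t33)^2]
                  + t12^2 + t13^2 + t23^2 ),

which is insensitive to the hydrostatic part of the tensor and returns
exactly the applied shear magnitude for a pure-shear state.  Samples are
then converted to a piecewise-constant :class:`~hemolysim.accumulation.StressHistory`
(left-endpoint convention by default) and fed through one of three models:

``powerlaw``
    the naive baseline: the power law evaluated once with the
    time-weighted mean stress and the total transit time;
``effective``
    history-aware effective-time accumulation;
``novel``
    the aging-aware model with threshold substitution and
    initial-hemolysis seeding.

For traces that visit the physiological regime (any interval at or below
the threshold stress) the power-law coefficient C is multiplied by the
low-stress correction factor, reflecting that the high-stress regression
constant overpredicts damage in mixed-regime loading.  Ensemble estimates
average the per-trace results arithmetically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
import pandas as pd

from .accumulation import (
    HemolysisTrace,
    StressHistory,
    accumulate_effective,
    accumulate_novel,
)
from .damage import DamageParams, hemolysis_index

__all__ = [
    "TensorSeries",
    "PathlineSet",
    "EnsembleSummary",
    "scalar_stress",
    "tensor_from_velocity_gradient",
    "read_pathlines",
    "write_pathlines",
    "trace_hemolysis",
    "ensemble_hemolysis",
]

TENSOR_COLUMNS = ["t11_Pa", "t22_Pa", "t33_Pa", "t12_Pa", "t13_Pa", "t23_Pa"]
POSITION_COLUMNS = ["x_m", "y_m", "z_m"]

Model = Literal["powerlaw", "effective", "novel"]


@dataclass(frozen=True)
class TensorSeries:
    """Time series of symmetric stress tensors along one trace.

    ``tensors`` has shape (n, 6) with columns (t11, t22, t33, t12, t13,
    t23) in Pa; only the upper triangle is stored because the tensor is
    symmetric.  ``positions`` (n, 3), in metres, are optional metadata.
    """

    times: np.ndarray
    tensors: np.ndarray
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        tensors = np.asarray(self.tensors, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "tensors", tensors)
        if tensors.ndim != 2 or tensors.shape[1] != 6:
            raise ValueError("tensors must have shape (n_samples, 6)")
        if len(times) != len(tensors):
            raise ValueError("times and tensors must have equal length")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.positions is not None:
            positions = np.asarray(self.positions, dtype=float)
            object.__setattr__(self, "positions", positions)
            if positions.shape != (len(times), 3):
                raise ValueError("positions must have shape (n_samples, 3)")

    def __len__(self) -> int:
        return len(self.times)

    def scalarize(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (times, scalar stresses) via :func:`scalar_stress`."""
        return self.times, scalar_stress(self.tensors)


def scalar_stress(tensor) -> float | np.ndarray:
    """Scalar equivalent shear stress from symmetric-tensor components.

    ``tensor`` is one sample of six components (t11, t22, t33, t12, t13,
    t23) or an (n, 6) array of them.  The normal-stress differences enter
    with weight 1/6 and the three distinct shear components with weight 1,
    so a pure shear state (only t12 = s) maps to exactly ``s`` and any
    hydrostatic contribution cancels.
    """
    arr = np.asarray(tensor, dtype=float)
    scalar_input = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[-1] != 6:
        raise ValueError("expected 6 tensor components (t11, t22, t33, t12, t13, t23)")
    if not np.all(np.isfinite(arr)):
        raise ValueError("tensor components must be finite")
    t11, t22, t33, t12, t13, t23 = arr.T
    normal = ((t11 - t22) ** 2 + (t22 - t33) ** 2 + (t11 - t33) ** 2) / 6.0
    shear = t12**2 + t13**2 + t23**2
    out = np.sqrt(normal + shear)
    return float(out[0]) if scalar_input else out


def tensor_from_velocity_gradient(gradient, viscosity: float) -> np.ndarray:
    """Viscous stress components from a 3x3 velocity-gradient tensor.

    Computes ``eta * dv_i/dx_j`` and takes the symmetric part, so a rigid
    rotation (antisymmetric gradient) produces zero stress.  Returns the
    six components (t11, t22, t33, t12, t13, t23) in Pa.
    """
    grad = np.asarray(gradient, dtype=float)
    if grad.shape != (3, 3):
        raise ValueError("velocity gradient must be a 3x3 array")
    if not np.all(np.isfinite(grad)):
        raise ValueError("velocity gradient entries must be finite")
    if not viscosity > 0:
        raise ValueError(f"viscosity must be positive, got {viscosity}")
    sym = 0.5 * viscosity * (grad + grad.T)
    return np.array([sym[0, 0], sym[1, 1], sym[2, 2], sym[0, 1], sym[0, 2], sym[1, 2]])


@dataclass
class PathlineSet:
    """An ordered collection of traces keyed by unique identifiers."""

    traces: dict[str, StressHistory | TensorSeries]

    def __post_init__(self) -> None:
        if not isinstance(self.traces, dict):
            self.traces = dict(self.traces)

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self) -> Iterator[tuple[str, StressHistory | TensorSeries]]:
        return iter(self.traces.items())

    def __getitem__(self, trace_id: str) -> StressHistory | TensorSeries:
        return self.traces[trace_id]

    @property
    def ids(self) -> list[str]:
        return list(self.traces)


def _read_table(path) -> pd.DataFrame:
    # sep=None sniffs comma, tab or whitespace delimiters.
    return pd.read_csv(path, sep=None, engine="python", comment="#")


def read_pathlines(path, schema: str | None = None) -> PathlineSet:
    """Read a delimiter-separated pathline table into a :class:`PathlineSet`.

    Two schemas are recognised (auto-detected from the header unless
    ``schema`` forces one): *scalar* with columns (trace_id, time_s,
    stress_Pa) and *tensor* with (trace_id, time_s, t11_Pa ... t23_Pa) plus
    optional positions (x_m, y_m, z_m).  Rows are grouped by trace_id and
    sorted by time; non-monotone duplicate times within a trace raise with
    the offending trace named.

    Scalar rows are *samples*: each trace needs at least two of them to
    define an exposure interval, but single-sample traces are accepted here
    and only rejected at estimation time.
    """
    frame = _read_table(path)
    cols = set(frame.columns)
    if "trace_id" not in cols or "time_s" not in cols:
        raise ValueError(f"{path}: pathline tables need 'trace_id' and 'time_s' columns")
    has_scalar = "stress_Pa" in cols
    has_tensor = set(TENSOR_COLUMNS) <= cols
    if schema is None:
        if has_scalar and has_tensor:
            raise ValueError(f"{path}: mixed schemas (both scalar and tensor columns)")
        if has_scalar:
            schema = "scalar"
        elif has_tensor:
            schema = "tensor"
        else:
            missing = sorted({"stress_Pa"} - cols) if not has_tensor else []
            raise ValueError(
                f"{path}: columns match neither the scalar schema "
                f"(trace_id, time_s, stress_Pa) nor the tensor schema "
                f"(trace_id, time_s, {', '.join(TENSOR_COLUMNS)})"
            )
    elif schema == "scalar" and not has_scalar:
        raise ValueError(f"{path}: scalar schema requested but 'stress_Pa' is missing")
    elif schema == "tensor" and not has_tensor:
        missing = sorted(set(TENSOR_COLUMNS) - cols)
        raise ValueError(f"{path}: tensor schema requested but missing {missing}")

    traces: dict[str, StressHistory | TensorSeries] = {}
    for trace_id, group in frame.groupby("trace_id", sort=False):
        group = group.sort_values("time_s", kind="stable")
        times = group["time_s"].to_numpy(dtype=float)
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            row = int(group.index[np.flatnonzero(np.diff(times) <= 0)[0] + 1])
            raise ValueError(
                f"{path}: trace {trace_id!r} has non-increasing time at row {row}"
            )
        if schema == "scalar":
            stresses = group["stress_Pa"].to_numpy(dtype=float)
            if np.any(stresses < 0):
                raise ValueError(f"{path}: trace {trace_id!r} has negative stress")
            if len(times) < 2:
                traces[str(trace_id)] = ScalarSamples(times=times, stresses=stresses)
            else:
                traces[str(trace_id)] = StressHistory.from_samples(times, stresses)
        else:
            tensors = group[TENSOR_COLUMNS].to_numpy(dtype=float)
            positions = None
            if set(POSITION_COLUMNS) <= cols:
                positions = group[POSITION_COLUMNS].to_numpy(dtype=float)
            traces[str(trace_id)] = TensorSeries(
                times=times, tensors=tensors, positions=positions
            )
    return PathlineSet(traces)


@dataclass(frozen=True)
class ScalarSamples:
    """Raw scalar stress samples that are too short to form an interval.

    A lone sample defines no exposure interval; the reader preserves it so
    the set round-trips, and estimation rejects it with a clear message.
    """

    times: np.ndarray
    stresses: np.ndarray


def write_pathlines(pathlines: PathlineSet, path, sep: str = ",") -> None:
    """Write a scalar-schema pathline table (trace_id, time_s, stress_Pa)."""
    frames = []
    for trace_id, trace in pathlines:
        if isinstance(trace, TensorSeries):
            times, stresses = trace.scalarize()
            frame = pd.DataFrame({"time_s": times, "stress_Pa": stresses})
        elif isinstance(trace, ScalarSamples):
            frame = pd.DataFrame({"time_s": trace.times, "stress_Pa": trace.stresses})
        else:
            frame = trace.to_frame()
        frame.insert(0, "trace_id", trace_id)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def _as_history(trace, convention: str) -> StressHistory:
    if isinstance(trace, StressHistory):
        return trace
    if isinstance(trace, (TensorSeries, ScalarSamples)):
        if len(trace.times) < 2:
            raise ValueError(
                "trace has a single time sample; at least two are needed to "
                "define an exposure interval"
            )
        if isinstance(trace, TensorSeries):
            _, samples = trace.scalarize()
        else:
            samples = trace.stresses
        return StressHistory.from_samples(trace.times, samples, convention)
    raise TypeError(f"unsupported trace type {type(trace).__name__}")


def trace_hemolysis(
    trace,
    model: Model = "novel",
    params: DamageParams | None = None,
    *,
    seed_initial: bool = True,
    correction: Literal["auto", "on", "off"] = "auto",
    convention: str = "left",
) -> HemolysisTrace:
    """Hemolysis estimate for a single trace.

    Tensor traces are scalarized first; samples become intervals under the
    chosen endpoint ``convention``.  ``correction`` controls the low-stress
    C correction: ``"auto"`` applies it when any interval sits at or below
    the threshold stress (per-trace trigger), ``"on"``/``"off"`` force it.
    """
    if params is None:
        params = DamageParams()
    history = _as_history(trace, convention)
    if len(history) == 0:
        raise ValueError("trace defines no exposure interval")
    if correction == "on" or (
        correction == "auto" and np.any(history.stresses <= params.threshold_stress)
    ):
        params = params.corrected()
    elif correction not in ("auto", "off", "on"):
        raise ValueError(f"unknown correction mode {correction!r}")

    if model == "powerlaw":
        durations = history.durations
        mean_stress = float(np.average(history.stresses, weights=durations))
        hi = hemolysis_index(mean_stress, history.total_duration, params)
        return HemolysisTrace(
            raw_stress=history.stresses.copy(),
            substituted_stress=np.full(len(history), mean_stress),
            effective_time_start=np.zeros(len(history)),
            cumulative_hi=np.full(len(history), hi),
            final_hi=hi,
            hi_subtracted=0.0,
            model="powerlaw",
        )
    if model == "effective":
        return accumulate_effective(history, params)
    if model == "novel":
        return accumulate_novel(history, params, seed_initial=seed_initial)
    raise ValueError(f"unknown model {model!r}; expected powerlaw, effective or novel")


@dataclass(frozen=True)
class EnsembleSummary:
    """Ensemble hemolysis estimate: mean, dispersion and per-trace detail.

    ``mean_hi`` averages :attr:`HemolysisTrace.hi_increment` (which equals
    the raw final HI except for the seeded aging-aware model); ``std_hi``
    is the sample standard deviation (0 for a single trace).
    """

    mean_hi: float
    std_hi: float
    per_trace: pd.DataFrame
    model: str

    @property
    def n_traces(self) -> int:
        return len(self.per_trace)


def ensemble_hemolysis(
    pathlines: PathlineSet,
    model: Model = "novel",
    params: DamageParams | None = None,
    *,
    seed_initial: bool = True,
    correction: Literal["auto", "on", "off"] = "auto",
    convention: str = "left",
    skip_failures: bool = False,
) -> EnsembleSummary:
    """Average per-trace hemolysis over a pathline ensemble.

    A failing trace aborts the run with its identifier in the message
    unless ``skip_failures`` is set, in which case it is recorded as NaN
    and excluded from the statistics.
    """
    if len(pathlines) == 0:
        raise ValueError("ensemble estimation needs a non-empty pathline set")
    records = []
    for trace_id, trace in pathlines:
        try:
            result = trace_hemolysis(
                trace,
                model,
                params,
                seed_initial=seed_initial,
                correction=correction,
                convention=convention,
            )
            records.append(
                {
                    "trace_id": trace_id,
                    "final_hi_pct": result.final_hi,
                    "hi_increment_pct": result.hi_increment,
                    "n_intervals": len(result.raw_stress),
                }
            )
        except (ValueError, TypeError) as err:
            if not skip_failures:
                raise ValueError(f"trace {trace_id!r} failed: {err}") from err
            records.append(
                {
                    "trace_id": trace_id,
                    "final_hi_pct": np.nan,
                    "hi_increment_pct": np.nan,
                    "n_intervals": 0,
                }
            )
    table = pd.DataFrame.from_records(records)
    values = table["hi_increment_pct"].dropna().to_numpy()
    if len(values) == 0:
        raise ValueError("all traces failed; no hemolysis values to average")
    mean = float(np.mean(values))
    std = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return EnsembleSummary(mean_hi=mean, std_hi=std, per_trace=table, model=model)
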