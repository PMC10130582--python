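"""Stress-tensor scalarization, pathline IO, and ensemble estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemolysim import (
    DamageParams,
    PathlineSet,
    SpikeSpec,
    StressHistory,
    TensorSeries,
    accumulate_novel,
    ensemble,
    ensemble_hemolysis,
    hemolysis_index,
    read_pathlines,
    scalar_stress,
    spike_history,
    tensor_from_velocity_gradient,
    trace_hemolysis,
    write_pathlines,
)


class TestScalarStress:
    def test_pure_shear_returns_shear_magnitude(self):
        assert scalar_stress([0, 0, 0, 5.0, 0, 0]) == pytest.approx(5.0)
        assert scalar_stress([0, 0, 0, 0, 0, -3.0]) == pytest.approx(3.0)

    def test_hydrostatic_state_is_stress_free(self):
        assert scalar_stress([7.0, 7.0, 7.0, 0, 0, 0]) == 0.0

    def test_uniaxial_tension(self):
        sigma = 9.0
        assert scalar_stress([sigma, 0, 0, 0, 0, 0]) == pytest.approx(sigma / np.sqrt(3))

    @given(
        comps=st.lists(st.floats(-100, 100), min_size=6, max_size=6),
        p=st.floats(-50, 50),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_pressure_invariance(self, comps, p):
        """Adding a hydrostatic component c*I changes nothing."""
        shifted = list(comps)
        for i in range(3):
            shifted[i] += p
        assert scalar_stress(shifted) == pytest.approx(scalar_stress(comps), abs=1e-9)

    def test_vectorized(self):
        arr = np.array([[0, 0, 0, 5.0, 0, 0], [7, 7, 7, 0, 0, 0]])
        np.testing.assert_allclose(scalar_stress(arr), [5.0, 0.0])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            scalar_stress([np.nan, 0, 0, 0, 0, 0])


class TestTensorFromVelocityGradient:
    def test_simple_shear(self):
        grad = np.zeros((3, 3))
        grad[0, 1] = 10.0  # dv1/dx2
        comps = tensor_from_velocity_gradient(grad, viscosity=0.0035)
        # symmetric part: t12 = eta * gamma / 2
        assert comps[3] == pytest.approx(0.0035 * 10.0 / 2)
        assert np.allclose(np.delete(comps, 3), 0.0)

    def test_zero_gradient(self):
        assert np.allclose(tensor_from_velocity_gradient(np.zeros((3, 3)), 0.0035), 0.0)

    def test_rigid_rotation_produces_no_stress(self):
        omega = np.array([[0, 1.0, 0], [-1.0, 0, 0], [0, 0, 0]])
        assert np.allclose(tensor_from_velocity_gradient(omega, 0.0035), 0.0)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            tensor_from_velocity_gradient(np.zeros((2, 2)), 0.0035)
        with pytest.raises(ValueError):
            tensor_from_velocity_gradient(np.full((3, 3), np.nan), 0.0035)
        with pytest.raises(ValueError):
            tensor_from_velocity_gradient(np.zeros((3, 3)), 0.0)


class TestReadPathlines:
    def _write(self, path, text):
        path.write_text(text)
        return path

    def test_scalar_schema(self, tmp_path):
        path = self._write(
            tmp_path / "scalar.csv",
            "trace_id,time_s,stress_Pa\nA,0.0,10\nA,0.5,20\nA,1.0,30\n",
        )
        pathlines = read_pathlines(path)
        assert len(pathlines) == 1
        history = pathlines["A"]
        assert isinstance(history, StressHistory)
        assert len(history) == 2  # 3 samples -> 2 intervals

    def test_interleaved_traces_are_grouped_and_sorted(self, tmp_path):
        path = self._write(
            tmp_path / "mixed.csv",
            "trace_id,time_s,stress_Pa\n"
            "A,0.5,20\nB,0.0,5\nA,0.0,10\nB,1.0,15\nA,1.0,30\nB,0.5,10\n",
        )
        pathlines = read_pathlines(path)
        assert sorted(pathlines.ids) == ["A", "B"]
        np.testing.assert_allclose(pathlines["A"].stresses, [10, 20])

    def test_tensor_schema(self, tmp_path):
        path = self._write(
            tmp_path / "tensor.csv",
            "trace_id,time_s,t11_Pa,t22_Pa,t33_Pa,t12_Pa,t13_Pa,t23_Pa\n"
            "A,0.0,0,0,0,5,0,0\nA,1.0,0,0,0,10,0,0\n",
        )
        trace = read_pathlines(path)["A"]
        assert isinstance(trace, TensorSeries)
        _, stresses = trace.scalarize()
        np.testing.assert_allclose(stresses, [5.0, 10.0])

    def test_single_sample_trace_accepted_but_not_estimable(self, tmp_path):
        path = self._write(
            tmp_path / "short.csv", "trace_id,time_s,stress_Pa\nA,0.0,10\n"
        )
        pathlines = read_pathlines(path)
        assert len(pathlines) == 1
        with pytest.raises(ValueError, match="single time sample"):
            trace_hemolysis(pathlines["A"], "effective")

    def test_missing_columns(self, tmp_path):
        path = self._write(tmp_path / "bad.csv", "trace_id,time_s\nA,0.0\n")
        with pytest.raises(ValueError, match="schema"):
            read_pathlines(path)

    def test_duplicate_time_named_in_error(self, tmp_path):
        path = self._write(
            tmp_path / "dup.csv",
            "trace_id,time_s,stress_Pa\nA,0.0,10\nA,0.0,20\n",
        )
        with pytest.raises(ValueError, match="'A'"):
            read_pathlines(path)

    def test_whitespace_delimited(self, tmp_path):
        path = self._write(
            tmp_path / "ws.tsv",
            "trace_id\ttime_s\tstress_Pa\nA\t0.0\t10\nA\t1.0\t20\n",
        )
        assert len(read_pathlines(path)) == 1

    def test_round_trip_matches_in_memory(self, tmp_path):
        pathlines = ensemble(SpikeSpec(n_samples=12), n_traces=5, jitter=0.3, seed=7)
        path = tmp_path / "rt.csv"
        write_pathlines(pathlines, path)
        back = read_pathlines(path)
        direct = ensemble_hemolysis(pathlines, "novel")
        from_file = ensemble_hemolysis(back, "novel")
        assert from_file.mean_hi == pytest.approx(direct.mean_hi, rel=1e-9)


class TestTraceHemolysis:
    def test_powerlaw_on_constant_trace_equals_closed_form(self, params):
        history = StressHistory(times=np.linspace(0.1, 1.0, 10), stresses=np.full(10, 80.0))
        result = trace_hemolysis(history, "powerlaw", params, correction="off")
        assert result.final_hi == pytest.approx(hemolysis_index(80.0, 1.0, params), rel=1e-12)

    def test_effective_equals_novel_above_threshold_unseeded(self, params):
        history = StressHistory(times=[0.1, 0.2, 0.3], stresses=[100.0, 300.0, 50.0])
        eff = trace_hemolysis(history, "effective", params)
        nov = trace_hemolysis(history, "novel", params, seed_initial=False)
        assert eff.final_hi == nov.final_hi

    def test_matches_direct_accumulation_composition(self, params):
        """Pathline layer on a spike trace == accumulation called directly."""
        history = spike_history(SpikeSpec(base_stress=30.0, peak_stress=200.0))
        via_pathlines = trace_hemolysis(history, "novel", params, correction="off")
        direct = accumulate_novel(history, params)
        assert via_pathlines.final_hi == pytest.approx(direct.final_hi, rel=1e-12)

    def test_correction_triggers_on_low_stress_interval(self, params):
        low = StressHistory(times=[0.1, 0.2], stresses=[10.0, 100.0])
        high = StressHistory(times=[0.1, 0.2], stresses=[60.0, 100.0])
        corrected = trace_hemolysis(low, "effective", params)
        manual = trace_hemolysis(low, "effective", params.corrected(), correction="off")
        assert corrected.final_hi == pytest.approx(manual.final_hi, rel=1e-12)
        uncorrected = trace_hemolysis(high, "effective", params)
        plain = trace_hemolysis(high, "effective", params, correction="off")
        assert uncorrected.final_hi == plain.final_hi

    def test_tensor_trace_is_scalarized(self, params):
        times = np.array([0.0, 0.5, 1.0])
        tensors = np.zeros((3, 6))
        tensors[:, 3] = [50.0, 80.0, 60.0]  # pure shear t12
        series = TensorSeries(times=times, tensors=tensors)
        from_tensor = trace_hemolysis(series, "effective", params)
        scalar = StressHistory.from_samples(times, [50.0, 80.0, 60.0])
        from_scalar = trace_hemolysis(scalar, "effective", params)
        assert from_tensor.final_hi == pytest.approx(from_scalar.final_hi, rel=1e-12)

    def test_unknown_model_rejected(self, params):
        history = StressHistory(times=[0.1], stresses=[100.0])
        with pytest.raises(ValueError, match="unknown model"):
            trace_hemolysis(history, "bogus", params)


class TestEnsembleHemolysis:
    def test_copies_of_one_trace(self, params):
        history = StressHistory(times=[0.1, 0.2], stresses=[100.0, 200.0])
        single = trace_hemolysis(history, "effective", params)
        pathlines = PathlineSet({f"t{i}": history for i in range(5)})
        summary = ensemble_hemolysis(pathlines, "effective", params)
        assert summary.mean_hi == pytest.approx(single.final_hi, rel=1e-12)
        assert summary.std_hi == 0.0

    def test_mean_of_two_known_traces(self, params):
        h1 = StressHistory(times=[0.1], stresses=[100.0])
        h2 = StressHistory(times=[0.1], stresses=[200.0])
        a = trace_hemolysis(h1, "effective", params).final_hi
        b = trace_hemolysis(h2, "effective", params).final_hi
        summary = ensemble_hemolysis(PathlineSet({"a": h1, "b": h2}), "effective", params)
        assert summary.mean_hi == pytest.approx((a + b) / 2, rel=1e-12)

    def test_matches_brute_force_loop(self, params):
        pathlines = ensemble(SpikeSpec(n_samples=15), n_traces=100, jitter=0.2, seed=3)
        summary = ensemble_hemolysis(pathlines, "novel", params)
        brute = np.mean(
            [trace_hemolysis(t, "novel", params).hi_increment for _, t in pathlines]
        )
        assert summary.mean_hi == pytest.approx(brute, rel=1e-12)

    def test_order_invariance(self, params):
        pathlines = ensemble(SpikeSpec(n_samples=10), n_traces=20, jitter=0.2, seed=5)
        reversed_set = PathlineSet(dict(reversed(list(pathlines))))
        s1 = ensemble_hemolysis(pathlines, "effective", params)
        s2 = ensemble_hemolysis(reversed_set, "effective", params)
        assert s1.mean_hi == pytest.approx(s2.mean_hi, rel=1e-12)
        assert s1.std_hi == pytest.approx(s2.std_hi, rel=1e-12)

    def test_failing_trace_names_identifier(self, params):
        good = StressHistory(times=[0.1], stresses=[100.0])
        bad = StressHistory(times=[], stresses=[])
        pathlines = PathlineSet({"good": good, "broken": bad})
        with pytest.raises(ValueError, match="broken"):
            ensemble_hemolysis(pathlines, "effective", params)
        summary = ensemble_hemolysis(pathlines, "effective", params, skip_failures=True)
        assert summary.n_traces == 2
        assert summary.per_trace["hi_increment_pct"].isna().sum() == 1

    def test_empty_set_rejected(self, params):
        with pytest.raises(ValueError):
            ensemble_hemolysis(PathlineSet({}), "effective", params)
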