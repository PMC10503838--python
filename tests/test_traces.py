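"""Rolling-sum response, trace validation and group aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from photogam.traces import (
    TraceError,
    WellTrace,
    aggregate_group_mean,
    frame_to_group_series,
    group_series_frame,
    read_well_traces,
    rolling_sum,
    write_well_traces,
)


def brute_force_rolling_sum(d, w):
    """O(n*w) double-loop oracle for the trailing-window sum."""
    out = np.full(len(d), np.nan)
    for t in range(w - 1, len(d)):
        acc = 0.0
        for i in range(t - w + 1, t + 1):
            acc += d[i]
        out[t] = acc
    return out


class TestRollingSum:
    def test_constant_input(self):
        r = rolling_sum(np.ones(200), 60)
        assert np.isnan(r[:59]).all()
        assert np.allclose(r[59:], 60.0)

    def test_all_zero(self):
        r = rolling_sum(np.zeros(100), 60)
        assert np.all(r[59:] == 0.0)

    def test_single_impulse(self):
        d = np.zeros(400)
        d[100] = 5.0
        r = rolling_sum(d, 60)
        covered = np.arange(100, 160)
        assert np.allclose(r[covered], 5.0)
        rest = np.setdiff1d(np.arange(59, 400), covered)
        assert np.all(r[rest] == 0.0)

    def test_too_short_series(self):
        with pytest.raises(TraceError):
            rolling_sum(np.zeros(10), 60)
        with pytest.raises(TraceError):
            rolling_sum(np.zeros(10), 0)

    @given(
        d=hnp.arrays(
            np.float64,
            st.integers(20, 300),
            elements=st.floats(0, 50, allow_nan=False),
        ),
        w=st.integers(1, 20),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_matches_brute_force(self, d, w):
        """Cumulative-sum implementation equals the double loop to 1e-12."""
        if len(d) < w:
            d = np.concatenate([d, np.zeros(w - len(d))])
        got = rolling_sum(d, w)
        exp = brute_force_rolling_sum(d, w)
        scale = max(1.0, np.nanmax(np.abs(exp)))
        assert np.allclose(got[w - 1:], exp[w - 1:], rtol=0, atol=1e-12 * scale)

    def test_integer_exactness(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 30, size=500).astype(float)
        assert np.array_equal(
            rolling_sum(d, 60)[59:], brute_force_rolling_sum(d, 60)[59:]
        )


def _mk_trace(aid, wid, d, geno="WT"):
    return WellTrace(aid, wid, {"geno": geno}, np.asarray(d, dtype=float))


class TestWellTrace:
    def test_negative_distance_rejected(self):
        with pytest.raises(TraceError):
            _mk_trace("a1", "w1", [-1.0, 0.0])

    def test_unknown_factor_level_rejected(self):
        with pytest.raises(TraceError):
            _mk_trace("a1", "w1", [0.0, 1.0], geno="XX")

    def test_undeclared_factor_passes(self):
        tr = WellTrace("a1", "w1", {"treatment": "drugA"}, np.zeros(5))
        assert tr.group_labels["treatment"] == "drugA"


class TestAggregation:
    def test_identical_traces_mean_is_identity(self):
        d = np.abs(np.sin(np.arange(300) / 7.0))
        traces = [_mk_trace("a1", f"w{i}", d) for i in range(2)]
        gs = aggregate_group_mean(traces, ["geno"], stride_s=1)
        assert len(gs) == 1
        expect = rolling_sum(d, 60)[59:]
        assert np.allclose(gs[0].rsums, expect)

    def test_elementwise_mean_of_two(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(200), rng.random(200)
        traces = [_mk_trace("a1", "w1", a), _mk_trace("a1", "w2", b)]
        gs = aggregate_group_mean(traces, ["geno"], stride_s=1)
        expect = (rolling_sum(a, 60)[59:] + rolling_sum(b, 60)[59:]) / 2
        assert np.allclose(gs[0].rsums, expect)

    def test_cell_count(self):
        rng = np.random.default_rng(1)
        traces = [
            _mk_trace("a1", f"w{i}", rng.random(150), geno=g)
            for g in ("WT", "HM")
            for i in range(48)
        ]
        gs = aggregate_group_mean(traces, ["geno"], stride_s=1)
        assert len(gs) == 2
        assert {g.group["geno"] for g in gs} == {"WT", "HM"}
        assert all(g.n_fish == 48 for g in gs)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        traces = [
            _mk_trace(f"a{j}", f"w{i}", rng.random(150), geno=g)
            for j in (1, 2)
            for g in ("WT", "HM")
            for i in range(3)
        ]
        gs1 = aggregate_group_mean(traces, ["geno"], stride_s=3)
        perm = [traces[i] for i in rng.permutation(len(traces))]
        gs2 = aggregate_group_mean(perm, ["geno"], stride_s=3)
        for s1, s2 in zip(gs1, gs2):
            assert s1.assay_id == s2.assay_id and s1.group == s2.group
            assert np.array_equal(s1.rsums, s2.rsums)

    def test_window_start_and_stride(self):
        d = np.ones(400)
        gs = aggregate_group_mean([_mk_trace("a1", "w1", d)], ["geno"],
                                  stride_s=30, start_s=100)
        assert gs[0].time_s[0] == 100
        assert np.all(np.diff(gs[0].time_s) == 30)


class TestTraceIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        traces = [
            WellTrace(f"a{j}", f"w{i}", {"geno": g},
                      np.round(rng.random(90), 6))
            for j in (1, 2)
            for i, g in enumerate(["WT", "HM", "HT"])
        ]
        write_well_traces(traces, tmp_path / "t.csv", tmp_path / "m.csv")
        back = read_well_traces(tmp_path / "t.csv", tmp_path / "m.csv")
        assert len(back) == len(traces)
        orig = {(t.assay_id, t.well_id): t for t in traces}
        for t in back:
            o = orig[(t.assay_id, t.well_id)]
            assert t.group_labels == o.group_labels
            assert np.allclose(t.distance_per_s, o.distance_per_s, atol=1e-6)

    def test_missing_second_is_gap_error(self, tmp_path):
        df = pd.DataFrame(
            {"assay_id": "a1", "well_id": "w1",
             "time_s": [0, 1, 3], "distance_mm": [0.0, 1.0, 2.0]}
        )
        df.to_csv(tmp_path / "t.csv", index=False)
        pd.DataFrame([{"assay_id": "a1", "well_id": "w1", "geno": "WT"}]).to_csv(
            tmp_path / "m.csv", index=False
        )
        with pytest.raises(TraceError, match="w1"):
            read_well_traces(tmp_path / "t.csv", tmp_path / "m.csv")

    def test_unknown_genotype_rejected(self, tmp_path):
        df = pd.DataFrame(
            {"assay_id": "a1", "well_id": "w1",
             "time_s": [0, 1], "distance_mm": [0.0, 1.0]}
        )
        df.to_csv(tmp_path / "t.csv", index=False)
        pd.DataFrame([{"assay_id": "a1", "well_id": "w1", "geno": "XX"}]).to_csv(
            tmp_path / "m.csv", index=False
        )
        with pytest.raises(TraceError):
            read_well_traces(tmp_path / "t.csv", tmp_path / "m.csv")


def test_group_series_frame_round_trip(small_series):
    back = frame_to_group_series(small_series)
    again = group_series_frame(back)
    pd.testing.assert_frame_equal(
        small_series.sort_values(["assay_id", "geno", "time_s"]).reset_index(drop=True),
        again.sort_values(["assay_id", "geno", "time_s"]).reset_index(drop=True),
        check_like=True,
    )
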