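"""Window enumeration against an independent brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxipredict import (
    VitalTrace,
    WindowSpec,
    build_dataset,
    build_rows,
    dataset_grid,
    load_dataset,
    row_count,
    save_dataset,
)
from oxipredict.windowing import DEFAULT_GRID, SupervisedDataset

from conftest import make_segment


def brute_force_rows(spo2, w, s, f, hr=None):
    """Literal sliding enumeration: inputs x[i+s*(j-1)], target x[i+s*w+f],
    for 1-based i while the target index stays inside the run."""
    n = len(spo2)
    rows = []
    i = 1
    while i + s * w + f <= n:
        inputs = [spo2[i + s * (j - 1) - 1] for j in range(1, w + 1)]
        if hr is not None:
            inputs += [hr[i + s * (j - 1) - 1] for j in range(1, w + 1)]
        rows.append(inputs + [spo2[i + s * w + f - 1]])
        i += 1
    width = w * (2 if hr is not None else 1) + 1
    if not rows:
        return np.empty((0, width))
    return np.asarray(rows, dtype=float)


class TestRowCount:
    @pytest.mark.parametrize(
        "n,w,s,f,expected",
        [
            (130, 20, 5, 20, 10),
            (120, 20, 5, 20, 0),
            (200, 20, 5, 20, 80),
            (200, 10, 10, 20, 80),
            (0, 2, 1, 1, 0),
        ],
    )
    def test_examples(self, n, w, s, f, expected):
        assert row_count(n, WindowSpec(w, s, f)) == expected

    @given(
        st.integers(0, 400),
        st.integers(1, 25),
        st.integers(1, 12),
        st.integers(1, 45),
    )
    @settings(max_examples=150, deadline=None)
    def test_count_matches_enumeration(self, n, w, s, f):
        spo2 = np.linspace(60, 100, max(n, 1))[:n]
        assert row_count(n, WindowSpec(w, s, f)) == len(
            brute_force_rows(spo2, w, s, f)
        )

    @given(st.integers(0, 2000))
    @settings(max_examples=80, deadline=None)
    def test_count_depends_only_on_span(self, n):
        """(w20,s5,f20) and (w10,s10,f20) share s*w+f=120, hence counts."""
        assert row_count(n, WindowSpec(20, 5, 20)) == row_count(
            n, WindowSpec(10, 10, 20)
        )


class TestBuildRows:
    def test_ramp_example(self):
        seg = make_segment(np.arange(1.0, 131.0))
        rows = build_rows(seg, WindowSpec(2, 3, 4))
        assert rows.shape == (120, 3)
        assert rows[0].tolist() == [1.0, 4.0, 11.0]
        assert rows[-1].tolist() == [120.0, 123.0, 130.0]  # target on last point

    def test_constant_segment(self):
        seg = make_segment(np.full(50, 95.0))
        rows = build_rows(seg, WindowSpec(4, 2, 3))
        assert rows.shape[0] == row_count(50, WindowSpec(4, 2, 3))
        assert np.all(rows == 95.0)

    def test_segment_shorter_than_window(self):
        seg = make_segment(np.full(5, 95.0))
        assert build_rows(seg, WindowSpec(20, 1, 1)).shape[0] == 0

    def test_hr_channel_layout(self):
        spo2 = np.arange(61, 91, dtype=float)
        hr = spo2 + 20  # distinct values in hr range
        seg = make_segment(spo2, hr=hr)
        spec = WindowSpec(3, 2, 4, channels="spo2_hr")
        rows = build_rows(seg, spec)
        oracle = brute_force_rows(seg.spo2, 3, 2, 4, hr=seg.hr)
        assert np.array_equal(rows, oracle)

    def test_hr_channel_requires_hr(self):
        seg = make_segment(np.full(30, 95.0))
        with pytest.raises(ValueError, match="heart-rate"):
            build_rows(seg, WindowSpec(3, 2, 4, channels="spo2_hr"))

    @given(
        st.integers(1, 300),
        st.integers(1, 15),
        st.integers(1, 8),
        st.integers(1, 30),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_oracle_equivalence(self, n, w, s, f, rnd):
        values = np.asarray([rnd.uniform(60, 100) for _ in range(n)])
        rows = build_rows(make_segment(values), WindowSpec(w, s, f))
        oracle = brute_force_rows(values, w, s, f)
        assert rows.shape == oracle.shape
        assert np.array_equal(rows, oracle)


class TestBuildDataset:
    def _two_segment_trace(self):
        ts = np.concatenate([np.arange(130.0), 200.0 + np.arange(5.0)])
        spo2 = np.concatenate([np.linspace(60, 90, 130), np.full(5, 95.0)])
        return VitalTrace(ts, spo2)

    def test_per_segment_concatenation(self):
        ds = build_dataset(self._two_segment_trace(), WindowSpec(2, 3, 4))
        assert ds.n_rows == 120  # 120 + 0

    def test_gap_reduces_rows(self):
        ts = np.arange(100.0)
        spo2 = np.full(100, 95.0)
        whole = build_dataset(VitalTrace(ts, spo2), WindowSpec(5, 2, 5))
        ts_gap = ts.copy()
        ts_gap[50:] += 10.0  # insert one gap mid-trace
        split = build_dataset(VitalTrace(ts_gap, spo2), WindowSpec(5, 2, 5))
        assert split.n_rows < whole.n_rows

    def test_empty_trace(self):
        ds = build_dataset(VitalTrace(np.empty(0), np.empty(0)), WindowSpec(2, 1, 1))
        assert ds.n_rows == 0

    def test_no_row_straddles_gap(self):
        """Values differ across the gap; every row must be single-valued."""
        ts = np.concatenate([np.arange(40.0), 100.0 + np.arange(40.0)])
        spo2 = np.concatenate([np.full(40, 90.0), np.full(40, 80.0)])
        ds = build_dataset(VitalTrace(ts, spo2), WindowSpec(4, 2, 3))
        for row in ds.rows:
            assert len(np.unique(row)) == 1

    def test_determinism(self, sim_trace):
        spec = WindowSpec(10, 2, 5)
        a = build_dataset(sim_trace, spec)
        b = build_dataset(sim_trace, spec)
        assert np.array_equal(a.rows, b.rows)


class TestGridAndPersistence:
    def test_default_grid_counts(self, sim_trace):
        datasets = dataset_grid(sim_trace, DEFAULT_GRID)
        assert len(datasets) == 5
        from oxipredict import segment_continuous

        for ds, spec in zip(datasets, DEFAULT_GRID):
            expected = sum(
                row_count(len(seg), spec) for seg in segment_continuous(sim_trace)
            )
            assert ds.n_rows == expected

    def test_duplicate_spec_duplicates_dataset(self, sim_trace):
        spec = WindowSpec(5, 2, 5)
        a, b = dataset_grid(sim_trace, [spec, spec])
        assert np.array_equal(a.rows, b.rows)

    def test_empty_spec_list_rejected(self, sim_trace):
        with pytest.raises(ValueError):
            dataset_grid(sim_trace, [])

    def test_save_load_round_trip(self, tmp_path, sim_trace):
        ds = build_dataset(sim_trace, WindowSpec(5, 2, 5))
        p = tmp_path / "ds.csv"
        save_dataset(ds, p)
        back = load_dataset(p)
        assert back.spec == ds.spec
        assert np.allclose(back.rows, ds.rows)
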