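"""Scaling, splitting, and the repeat-training protocol."""

import numpy as np
import pytest

from oxipredict import (
    ModelArchitecture,
    SupervisedDataset,
    TrainingProtocol,
    VitalTrace,
    WindowSpec,
    build_dataset,
    evaluate_repeats,
    fit_scaler,
    persistence_metrics,
    split_dataset,
    train_model,
)
from oxipredict.modeling import _reshape_inputs

SMALL_FCNN = ModelArchitecture("fcnn", (16, 8))
SMALL_GRU = ModelArchitecture("gru", (8,))


def ramp_dataset(n=400, w=5, s=2, f=5):
    """Noiseless rising-then-falling saturation ramp (predictable)."""
    t = np.arange(n, dtype=float)
    spo2 = 85 + 10 * np.abs(np.sin(2 * np.pi * t / 600))
    return build_dataset(VitalTrace(t, spo2), WindowSpec(w, s, f))


class TestScaler:
    def test_constant_inputs_degenerate_std(self):
        rows = np.full((20, 4), 95.0)
        ds = SupervisedDataset(rows, WindowSpec(3, 1, 1))
        with pytest.warns(UserWarning, match="zero-variance"):
            sc = fit_scaler(ds)
        assert np.allclose(sc.mean, 95.0)
        assert np.allclose(sc.std, 1.0)

    def test_column_statistics(self):
        rows = np.array([[0.0, 10.0, 95.0], [2.0, 14.0, 96.0]])
        ds = SupervisedDataset(rows, WindowSpec(2, 1, 1))
        sc = fit_scaler(ds)
        assert np.allclose(sc.mean, [1.0, 12.0])  # population std convention
        assert np.allclose(sc.std, [1.0, 2.0])

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        rows = np.column_stack([rng.uniform(80, 100, (50, 6))])
        ds = SupervisedDataset(rows, WindowSpec(5, 1, 1))
        sc = fit_scaler(ds)
        X = rng.uniform(80, 100, (10, 5))
        assert np.allclose(sc.inverse_transform(sc.transform(X)), X, atol=1e-10)

    def test_too_few_rows(self):
        ds = SupervisedDataset(np.full((1, 3), 95.0), WindowSpec(2, 1, 1))
        with pytest.raises(ValueError):
            fit_scaler(ds)


class TestSplit:
    def _dataset(self, n):
        rows = np.random.default_rng(0).uniform(80, 100, (n, 4))
        return SupervisedDataset(rows, WindowSpec(3, 1, 1))

    def test_fraction_sizes(self):
        tr, va, te = split_dataset(self._dataset(100), seed=1)
        assert (tr.n_rows, va.n_rows, te.n_rows) == (70, 15, 15)

    def test_disjoint_and_exhaustive(self):
        ds = self._dataset(97)
        tr, va, te = split_dataset(ds, seed=2)
        stacked = np.vstack([tr.rows, va.rows, te.rows])
        assert stacked.shape == ds.rows.shape
        assert np.array_equal(
            np.sort(stacked, axis=0), np.sort(ds.rows, axis=0)
        )

    def test_same_seed_identical(self):
        ds = self._dataset(200)
        a = split_dataset(ds, seed=5)
        b = split_dataset(ds, seed=5)
        for x, y in zip(a, b):
            assert np.array_equal(x.rows, y.rows)

    def test_different_seeds_differ(self):
        ds = self._dataset(1000)
        a = split_dataset(ds, seed=1)[0]
        b = split_dataset(ds, seed=2)[0]
        assert not np.array_equal(a.rows, b.rows)

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            split_dataset(self._dataset(9))

    def test_invalid_fractions(self):
        with pytest.raises(ValueError):
            TrainingProtocol(fractions=(0.5, 0.3, 0.3))


class TestTrainModel:
    def test_constant_signal_learned_exactly(self, constant_model):
        model, _ = constant_model
        assert model.metrics.mae < 0.01

    def test_beats_persistence_on_smooth_signal(self):
        ds = ramp_dataset()
        proto = TrainingProtocol(repeats=1, seed=4, max_epochs=60)
        model = train_model(SMALL_FCNN, ds, proto)
        assert model.metrics.mae < persistence_metrics(ds).mae

    def test_seeded_determinism(self):
        ds = ramp_dataset(n=200)
        proto = TrainingProtocol(repeats=1, seed=8, max_epochs=10)
        a = train_model(SMALL_FCNN, ds, proto)
        b = train_model(SMALL_FCNN, ds, proto)
        assert a.metrics == b.metrics

    def test_incompatible_rows_rejected(self):
        rows = np.full((50, 4), 95.0)
        ds = SupervisedDataset(rows, WindowSpec(3, 1, 1))
        ds.spec = WindowSpec(5, 1, 1)  # corrupt the pairing
        with pytest.raises(ValueError, match="incompatible"):
            train_model(SMALL_FCNN, ds, TrainingProtocol(repeats=1))

    def test_predictions_in_saturation_units(self, constant_model):
        model, ds = constant_model
        preds = model.predict(ds.X[:5])
        assert np.all((preds > 90) & (preds < 100))

    def test_gru_trains_on_same_rows(self):
        ds = ramp_dataset(n=250)
        proto = TrainingProtocol(repeats=1, seed=4, max_epochs=15)
        model = train_model(SMALL_GRU, ds, proto)
        assert model.metrics.mae < 5.0  # sane scale, not divergent


class TestReshape:
    def test_gru_reshape_round_trip(self):
        """Flat rows -> (n, w, channels) loses no information."""
        spec = WindowSpec(4, 2, 3, channels="spo2_hr")
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(6, spec.input_length))
        arch = ModelArchitecture("gru", (4,))
        cube = _reshape_inputs(arch, spec, X)
        assert cube.shape == (6, 4, 2)
        # channel 0 is the SpO2 block, channel 1 the HR block, same order
        assert np.array_equal(cube[:, :, 0], X[:, :4])
        assert np.array_equal(cube[:, :, 1], X[:, 4:])
        back = cube.transpose(0, 2, 1).reshape(6, -1)
        assert np.array_equal(back, X)


class TestEvaluateRepeats:
    def _run(self, repeats):
        ds = ramp_dataset(n=250)
        proto = TrainingProtocol(repeats=repeats, seed=3, max_epochs=8)
        return evaluate_repeats(SMALL_FCNN, ds, proto)

    def test_repeats_one_gives_zero_std(self):
        model = self._run(1)
        assert all(v == 0.0 for v in model.metrics_std.values())

    def test_std_reported_and_mean_bounded(self):
        ds = ramp_dataset(n=250)
        proto = TrainingProtocol(repeats=3, seed=3, max_epochs=8)
        seeds = np.random.SeedSequence(3).generate_state(3)
        singles = [
            train_model(
                SMALL_FCNN,
                ds,
                TrainingProtocol(
                    repeats=1, seed=int(s) % (2**31), max_epochs=8
                ),
            ).metrics.mae
            for s in seeds
        ]
        model = evaluate_repeats(SMALL_FCNN, ds, proto)
        assert np.isfinite(model.metrics_std["mae"])
        assert min(singles) <= model.metrics.mae <= max(singles)
        assert model.metrics.mae == pytest.approx(np.mean(singles))
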