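"""Gate-equation fidelity, gradients, and trainability of the forecaster."""

import math

import numpy as np
import pytest

from actinovelty.lstm import (
    CellState,
    ForecasterError,
    ForecasterParams,
    LSTMLayerParams,
    TrainConfig,
    _loss_and_grads,
    evaluate_mse,
    forward,
    load_params,
    lstm_cell_step,
    save_params,
    train,
    windows_to_arrays,
)
from actinovelty.preprocessing import SynchronizedRecording
from actinovelty.scoring import pearson
from actinovelty.segmentation import segment_windows
from actinovelty.synthetic import generate_motif_dictionary, tile_motif

from conftest import brute_force_forward, motif_recording


def _scalar_layer(value=1.0):
    one = np.full((1, 1), value)
    return LSTMLayerParams(
        Wf=one.copy(), Wi=one.copy(), Wo=one.copy(), Wc=one.copy(),
        Uf=one.copy(), Ui=one.copy(), Uo=one.copy(), Uc=one.copy(),
        bf=np.zeros(1), bi=np.zeros(1), bo=np.zeros(1), bc=np.zeros(1),
    )


class TestCellStep:
    def test_all_zero_parameters(self):
        layer = LSTMLayerParams(
            **{f"W{g}": np.zeros((3, 2)) for g in "fioc"},
            **{f"U{g}": np.zeros((2, 2)) for g in "fioc"},
            **{f"b{g}": np.zeros(2) for g in "fioc"},
        )
        state = lstm_cell_step(np.ones(3), CellState.zero(2), layer)
        assert np.allclose(state.c, 0.0)
        assert np.allclose(state.h, 0.0)

    def test_scalar_hand_computation(self):
        """All weights 1, biases 0, x=1, zero state: the five equations give
        c = s(1)*tanh(1), h = s(1)*tanh(c), with s the logistic sigmoid."""
        sig1 = 1.0 / (1.0 + math.exp(-1.0))
        state = lstm_cell_step(np.ones(1), CellState.zero(1), _scalar_layer())
        c_expected = sig1 * math.tanh(1.0)
        assert state.c[0] == pytest.approx(c_expected, abs=1e-15)
        assert state.h[0] == pytest.approx(sig1 * math.tanh(c_expected), abs=1e-15)

    def test_forget_gate_saturation(self):
        """bf -> +inf drives f -> 1 so the old memory passes through."""
        layer = _scalar_layer()
        layer.bf = np.array([100.0])
        prev = CellState(h=np.zeros(1), c=np.array([0.7]))
        state = lstm_cell_step(np.zeros(1), prev, layer)
        sig0 = 0.5
        expected_c = 1.0 * 0.7 + sig0 * math.tanh(0.0)
        assert state.c[0] == pytest.approx(expected_c, abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ForecasterError):
            lstm_cell_step(np.ones(2), CellState.zero(1), _scalar_layer())


class TestForward:
    def test_zero_parameters_predict_bias(self):
        params = ForecasterParams.init(hidden_sizes=(5, 3), seed=0)
        for a in params.arrays():
            a[...] = 0.0
        params.bd[...] = np.arange(80, dtype=float)
        pred = forward(params, np.zeros((60, 4)))
        assert np.array_equal(pred, np.arange(80.0).reshape(20, 4))

    def test_matches_brute_force_oracle(self):
        """Batched forward equals the naive per-step evaluation of the five
        gate equations on 50 random small parameter sets, to 1e-10."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            h1, h2 = rng.integers(1, 6, size=2)
            params = ForecasterParams.init(
                hidden_sizes=(int(h1), int(h2)), seed=int(rng.integers(1 << 31))
            )
            x = rng.normal(scale=0.5, size=(60, 4))
            assert np.abs(forward(params, x) - brute_force_forward(params, x)).max() < 1e-10

    def test_deterministic_and_batch_consistent(self):
        params = ForecasterParams.init(hidden_sizes=(6, 4), seed=3)
        x = np.random.default_rng(0).normal(size=(3, 60, 4))
        batch = forward(params, x)
        assert np.array_equal(batch, forward(params, x))
        for j in range(3):
            assert np.allclose(batch[j], forward(params, x[j]), atol=1e-12)

    def test_rejects_non_finite_input(self):
        params = ForecasterParams.init(hidden_sizes=(3, 2), seed=0)
        x = np.zeros((60, 4))
        x[10, 2] = np.nan
        with pytest.raises(ForecasterError):
            forward(params, x)

    def test_hidden_states_are_tanh_bounded(self):
        from actinovelty.lstm import _forward_cached

        params = ForecasterParams.init(hidden_sizes=(8, 5), seed=1)
        x = np.random.default_rng(2).normal(scale=2.0, size=(4, 60, 4))
        _, caches = _forward_cached(params, x)
        for cache in caches:
            assert np.abs(cache["h"]).max() < 1.0


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """BPTT gradients agree with central finite differences on a tiny
        two-layer network."""
        rng = np.random.default_rng(7)
        params = ForecasterParams.init(hidden_sizes=(3, 2), seed=11)
        X = rng.normal(scale=0.5, size=(2, 60, 4))
        Y = rng.normal(scale=0.5, size=(2, 80))
        _, grads = _loss_and_grads(params, X, Y)
        arrays = params.arrays()
        eps = 1e-6
        checked = 0
        for a, g in zip(arrays, grads):
            flat = a.reshape(-1)
            for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = evaluate_mse(params, X, Y)
                flat[idx] = orig - eps
                down = evaluate_mse(params, X, Y)
                flat[idx] = orig
                fd = (up - down) / (2 * eps)
                assert g.reshape(-1)[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)
                checked += 1
        assert checked > 50


class TestTraining:
    def test_zero_epochs_returns_seeded_init(self):
        rec = motif_recording(generate_motif_dictionary(1, seed=9), 0, 800)
        windows = segment_windows(rec)
        cfg = TrainConfig(max_epochs=0, seed=4)
        params = train(windows, cfg)
        ref = ForecasterParams.init(hidden_sizes=(50, 20), seed=4)
        assert all(np.array_equal(a, b) for a, b in zip(params.arrays(), ref.arrays()))

    def test_seeded_training_is_reproducible(self):
        rec = motif_recording(generate_motif_dictionary(1, seed=9), 0, 1600)
        windows = segment_windows(rec)
        cfg = TrainConfig(max_epochs=3, seed=5)
        p1 = train(windows, cfg)
        p2 = train(windows, cfg)
        assert all(np.array_equal(a, b) for a, b in zip(p1.arrays(), p2.arrays()))

    def test_loss_descends_and_history_recorded(self):
        rec = motif_recording(generate_motif_dictionary(2, seed=3), 0, 2400)
        windows = segment_windows(rec)
        params = train(windows, TrainConfig(max_epochs=10, seed=0))
        X, Y = windows_to_arrays(windows)
        init = ForecasterParams.init(hidden_sizes=(50, 20), seed=0)
        assert evaluate_mse(params, X, Y) <= evaluate_mse(init, X, Y)
        epochs, train_mse, val_mse = zip(*params.history)
        assert epochs[0] == 0 and val_mse[-1] <= val_mse[0]

    def test_single_motif_is_learnable(self):
        """Held-out windows of a periodic motif are forecast with r > 0.95
        once the network has memorised it."""
        d = generate_motif_dictionary(1, seed=5)
        rec = motif_recording(d, 0, 4800, sd=0.5)
        windows = segment_windows(rec)
        cfg = TrainConfig(max_epochs=300, batch_size=16, patience=50, seed=0)
        params = train(windows[:48], cfg)
        rs = [pearson(forward(params, w.x), w.y) for w in windows[48:]]
        assert min(rs) > 0.95

    def test_in_dictionary_beats_out_of_dictionary(self):
        """The novelty mechanism: a control-trained model forecasts motifs
        from its own dictionary better than motifs from a disjoint one."""
        dA = generate_motif_dictionary(4, seed=1)
        dB = generate_motif_dictionary(4, seed=2)

        def windows_from(d):
            out = []
            for i in range(len(d)):
                out.extend(segment_windows(motif_recording(d, i, 1600)))
            return out

        wA, wB = windows_from(dA), windows_from(dB)
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(wA))
        trn = [wA[i] for i in idx[:60]]
        held = [wA[i] for i in idx[60:]]
        params = train(trn, TrainConfig(max_epochs=300, batch_size=16, patience=50, seed=0))
        r_in = np.mean([pearson(forward(params, w.x), w.y) for w in held])
        r_out = np.mean([pearson(forward(params, w.x), w.y) for w in wB])
        assert r_in > r_out + 0.1

    def test_bin_filtering_and_empty_error(self):
        d = generate_motif_dictionary(1, seed=6)
        from actinovelty.segmentation import IntensityBins

        windows = segment_windows(motif_recording(d, 0, 800, sd=0.5))
        bins = IntensityBins()
        with pytest.raises(ForecasterError, match="empty"):
            train(windows, TrainConfig(max_epochs=1), bin=5, bins=bins)
        params = train(windows, TrainConfig(max_epochs=1, seed=0), bin=2, bins=bins)
        assert params.metadata["bin"] == 2

    def test_three_layer_variant_runs(self):
        d = generate_motif_dictionary(1, seed=8)
        windows = segment_windows(motif_recording(d, 0, 800))
        params = train(windows, TrainConfig(max_epochs=1, seed=0),
                       hidden_sizes=(50, 50, 50))
        assert len(params.layers) == 3
        assert forward(params, windows[0].x).shape == (20, 4)


class TestSerialization:
    def test_roundtrip(self, tmp_path):
        d = generate_motif_dictionary(1, seed=2)
        windows = segment_windows(motif_recording(d, 0, 800))
        params = train(windows, TrainConfig(max_epochs=2, seed=1))
        path = tmp_path / "model.npz"
        save_params(params, path)
        loaded = load_params(path)
        assert all(np.array_equal(a, b) for a, b in zip(params.arrays(), loaded.arrays()))
        assert loaded.metadata["bin"] == "all"
        x = np.random.default_rng(0).normal(size=(60, 4))
        assert np.array_equal(forward(params, x), forward(loaded, x))
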