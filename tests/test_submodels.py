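from fractions import Fraction

import numpy as np
import pytest

from ensplice.data_io import OneHotBatch, encode_one_hot
from ensplice.errors import ArchitectureError, DegenerateDataError, InputShapeError
from ensplice.submodels import (
    CNN_SCHEDULE,
    DNN_SCHEDULE,
    LRSchedule,
    SUBMODEL_NAMES,
    TrainConfig,
    build_submodel,
    default_schedule,
    inverse_time_decay,
    load_model,
    predict_binary,
    preset_spec,
    save_model,
    train_submodel,
)
from ensplice.synthetic import SyntheticConfig, default_motif, generate_dataset


def _layer_summary(spec):
    out = []
    for ls in spec.layers:
        p = ls.params
        if ls.kind == "conv1d":
            out.append(("conv1d", p["filters"], p["kernel_size"]))
        elif ls.kind == "maxpool1d":
            out.append(("maxpool1d", p["pool_size"]))
        elif ls.kind == "dropout":
            out.append(("dropout", p["rate"]))
        elif ls.kind == "dense":
            out.append(("dense", p["units"], p["activation"]))
        else:
            out.append((ls.kind,))
    return out


class TestPresets:
    def test_cnn1(self):
        assert _layer_summary(preset_spec("CNN1")) == [
            ("conv1d", 72, 5), ("conv1d", 144, 7), ("conv1d", 168, 7),
            ("flatten",), ("dropout", 0.20), ("dense", 2, "sigmoid"),
        ]

    def test_cnn2(self):
        assert _layer_summary(preset_spec("CNN2")) == [
            ("conv1d", 136, 3), ("conv1d", 72, 4), ("maxpool1d", 7),
            ("conv1d", 272, 7), ("maxpool1d", 3), ("flatten",),
            ("dropout", 0.35), ("dense", 2, "sigmoid"),
        ]

    def test_cnn3(self):
        assert _layer_summary(preset_spec("CNN3")) == [
            ("conv1d", 208, 9), ("maxpool1d", 6), ("conv1d", 120, 5),
            ("maxpool1d", 3), ("flatten",), ("dropout", 0.20),
            ("dense", 2, "sigmoid"),
        ]

    def test_cnn4(self):
        assert _layer_summary(preset_spec("CNN4")) == [
            ("conv1d", 250, 5), ("conv1d", 250, 5), ("conv1d", 250, 5),
            ("maxpool1d", 3), ("flatten",), ("dropout", 0.20),
            ("dense", 2, "sigmoid"),
        ]

    def test_dnn1(self):
        assert _layer_summary(preset_spec("DNN1")) == [
            ("flatten",), ("dense", 704, "relu"), ("dense", 224, "relu"),
            ("dropout", 0.1), ("dense", 512, "relu"), ("dropout", 0.15),
            ("dense", 2, "sigmoid"),
        ]

    def test_dnn2(self):
        assert _layer_summary(preset_spec("DNN2")) == [
            ("flatten",), ("dense", 704, "relu"), ("dense", 224, "relu"),
            ("dense", 128, "relu"), ("dropout", 0.15), ("dense", 2, "sigmoid"),
        ]

    def test_dnn3(self):
        assert _layer_summary(preset_spec("DNN3")) == [
            ("flatten",), ("dense", 256, "relu"), ("dense", 352, "relu"),
            ("dense", 32, "relu"), ("dense", 352, "relu"), ("dropout", 0.15),
            ("dense", 2, "sigmoid"),
        ]

    def test_dnn4_random_normal(self):
        spec = preset_spec("DNN4")
        assert _layer_summary(spec) == [
            ("flatten",), ("dense", 250, "relu"), ("dense", 250, "relu"),
            ("dense", 250, "relu"), ("dropout", 0.25), ("dense", 2, "sigmoid"),
        ]
        for ls in spec.layers:
            if ls.kind == "dense":
                assert ls.params["initializer"] == "random_normal"

    @pytest.mark.parametrize("name", SUBMODEL_NAMES)
    def test_final_layer_invariant(self, name):
        last = preset_spec(name).layers[-1]
        assert last.kind == "dense"
        assert last.params["units"] == 2
        assert last.params["activation"] == "sigmoid"

    def test_unknown_name_lists_valid(self):
        with pytest.raises(KeyError, match="CNN1"):
            preset_spec("CNN9")

    def test_json_export(self):
        doc = preset_spec("CNN1").to_json()
        assert '"conv1d"' in doc and '"CNN1"' in doc


class TestInverseTimeDecay:
    def test_step_zero(self):
        assert inverse_time_decay(CNN_SCHEDULE, 0) == 0.001

    def test_cnn_step_1400(self):
        # 0.001 / (1 + 0.1 * 1400 / 140) = 0.001 / 11... no: 0.1*10 = 1 -> 0.0005
        assert inverse_time_decay(CNN_SCHEDULE, 1400) == pytest.approx(0.0005, abs=1e-15)

    def test_dnn_step_80(self):
        assert inverse_time_decay(DNN_SCHEDULE, 80) == pytest.approx(0.002 / 2.4, abs=1e-15)

    def test_closed_form_across_steps(self):
        for sched in (CNN_SCHEDULE, DNN_SCHEDULE):
            steps = np.arange(0, 100001, 997)
            got = np.array([inverse_time_decay(sched, int(s)) for s in steps])
            # exact rational evaluation of the closed form
            oracle = np.array(
                [
                    float(
                        Fraction(sched.initial_rate)
                        / (1 + Fraction(sched.decay_rate) * int(s) / sched.decay_steps)
                    )
                    for s in steps
                ]
            )
            assert np.abs(got - oracle).max() < 1e-12

    def test_strictly_decreasing(self):
        vals = [inverse_time_decay(DNN_SCHEDULE, s) for s in range(0, 500, 7)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_negative_step(self):
        with pytest.raises(ValueError):
            inverse_time_decay(CNN_SCHEDULE, -1)

    def test_invalid_schedule(self):
        with pytest.raises(ArchitectureError):
            LRSchedule(initial_rate=0.0, decay_steps=10, decay_rate=0.1)


class TestBuildSubmodel:
    def test_output_shape(self):
        model = build_submodel(preset_spec("CNN1"), 140, seed=0)
        x = np.zeros((3, 140, 4), dtype=np.float32)
        assert model.predict_proba(x).shape == (3, 2)

    def test_outputs_are_probabilities(self):
        model = build_submodel(preset_spec("CNN3"), 60, seed=1)
        out = model.predict_proba(np.random.default_rng(0).random((5, 60, 4)).astype(np.float32))
        assert ((out >= 0) & (out <= 1)).all()

    def test_pool_collapse_raises(self):
        with pytest.raises(ArchitectureError, match="CNN2"):
            build_submodel(preset_spec("CNN2"), 4, seed=0)

    def test_seed_reproducible(self):
        a = build_submodel(preset_spec("DNN1"), 30, seed=9)
        b = build_submodel(preset_spec("DNN1"), 30, seed=9)
        for wa, wb in zip(a.get_weights(), b.get_weights()):
            np.testing.assert_array_equal(wa, wb)

    def test_seed_changes_weights(self):
        a = build_submodel(preset_spec("DNN1"), 30, seed=1)
        b = build_submodel(preset_spec("DNN1"), 30, seed=2)
        assert any(
            not np.array_equal(wa, wb)
            for wa, wb in zip(a.get_weights(), b.get_weights())
        )


def _tiny_dataset(signal=1.0, n=100, length=30, seed=2):
    motif = default_motif("donor", length, (length // 2, length // 2 + 1), 1.0)
    cfg = SyntheticConfig(n_per_class=n, window_length=length, site_type="donor",
                          signal_strength=signal, seed=seed)
    ds = generate_dataset(cfg, motif)
    return encode_one_hot(ds), ds.labels


class TestTrainSubmodel:
    def test_zero_epochs_untouched(self):
        batch, y = _tiny_dataset(n=20)
        model = build_submodel(preset_spec("DNN2"), 30, seed=0)
        before = model.get_weights()
        _, history = train_submodel(model, batch, y, TrainConfig(max_epochs=0))
        assert history == {"loss": [], "val_loss": []}
        for wa, wb in zip(before, model.get_weights()):
            np.testing.assert_array_equal(wa, wb)

    def test_single_class_raises(self):
        batch, y = _tiny_dataset(n=20)
        model = build_submodel(preset_spec("DNN2"), 30, seed=0)
        with pytest.raises(DegenerateDataError):
            train_submodel(model, batch, np.ones_like(y), TrainConfig(max_epochs=1))

    def test_label_length_mismatch(self):
        batch, y = _tiny_dataset(n=20)
        model = build_submodel(preset_spec("DNN2"), 30, seed=0)
        with pytest.raises(InputShapeError):
            train_submodel(model, batch, y[:-1], TrainConfig(max_epochs=1))

    def test_history_records_epochs(self):
        batch, y = _tiny_dataset(n=40)
        model = build_submodel(preset_spec("DNN2"), 30, seed=0)
        _, history = train_submodel(
            model, batch, y,
            TrainConfig(max_epochs=3, schedule=DNN_SCHEDULE, early_stop_patience=10, seed=1),
        )
        assert len(history["loss"]) == 3 and len(history["val_loss"]) == 3

    def test_training_reproducible(self):
        batch, y = _tiny_dataset(n=60)
        preds = []
        for _ in range(2):
            model = build_submodel(preset_spec("DNN3"), 30, seed=4)
            train_submodel(model, batch, y,
                           TrainConfig(max_epochs=2, schedule=DNN_SCHEDULE, seed=4))
            preds.append(predict_binary(model, batch))
        np.testing.assert_array_equal(preds[0], preds[1])

    @pytest.mark.slow
    @pytest.mark.parametrize("name", SUBMODEL_NAMES)
    def test_capacity_on_separable_data(self, name):
        """Every preset fits 200 strongly separable records."""
        batch, y = _tiny_dataset(signal=1.0, n=100, length=30)
        model = build_submodel(preset_spec(name), 30, seed=1)
        train_submodel(
            model, batch, y,
            TrainConfig(max_epochs=12, schedule=default_schedule(name),
                        early_stop_patience=30, seed=1),
        )
        train_acc = (predict_binary(model, batch) == y).mean()
        assert train_acc >= 0.95


class TestPredictBinary:
    def test_argmax_and_tie_rule(self, fixed_model_factory, dummy_batch):
        class Stub:
            input_shape = (8, 4)

            def predict_proba(self, x, batch_size=512):
                return np.array([[0.2, 0.9], [0.5, 0.5], [0.7, 0.3]])

        out = predict_binary(Stub(), dummy_batch(3))
        np.testing.assert_array_equal(out, [1, 0, 0])

    def test_shape_mismatch(self):
        model = build_submodel(preset_spec("DNN2"), 30, seed=0)
        bad = OneHotBatch(tensor=np.zeros((2, 29, 4), dtype=np.float32))
        with pytest.raises(InputShapeError):
            predict_binary(model, bad)

    def test_length_contract(self):
        batch, y = _tiny_dataset(n=17)
        model = build_submodel(preset_spec("DNN2"), 30, seed=0)
        assert len(predict_binary(model, batch)) == len(y)


def test_save_load_round_trip(tmp_path):
    batch, y = _tiny_dataset(n=30)
    spec = preset_spec("DNN2")
    model = build_submodel(spec, 30, seed=3)
    train_submodel(model, batch, y, TrainConfig(max_epochs=1, schedule=DNN_SCHEDULE, seed=3))
    save_model(model, spec, tmp_path / "m")
    loaded, loaded_spec = load_model(tmp_path / "m")
    assert loaded_spec == spec
    np.testing.assert_array_equal(
        predict_binary(loaded, batch), predict_binary(model, batch)
    )
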