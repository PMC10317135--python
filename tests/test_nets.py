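"""Architecture audits, parameter accounting, training contracts."""

import numpy as np
import pytest

from artscore.nets import (
    ArchSpec,
    ChopClassifier,
    TrainConfig,
    build_architecture,
    count_parameters,
    count_weight_layers,
    load_classifier,
    predict_chop,
    predict_proba,
    save_classifier,
    train_classifier,
)

EXPECTED_LAYERS = {"alexnet": 8, "vgg16": 16, "resnet50": 50, "squeezenet": 18}


@pytest.mark.parametrize("arch", sorted(EXPECTED_LAYERS))
@pytest.mark.parametrize("num_classes", [5, 13])
@pytest.mark.parametrize("width", [1.0, 0.3])
def test_weight_layer_audit_is_width_and_class_invariant(arch, num_classes, width):
    model = build_architecture(ArchSpec(arch, num_classes, 256, width))
    assert count_weight_layers(model) == EXPECTED_LAYERS[arch]


def fire_params(in_c, sq, e1, e3):
    return (sq * in_c + sq) + (e1 * sq + e1) + (e3 * sq * 9 + e3)


def squeezenet_param_oracle(num_classes):
    """Brute-force per-layer shape-product sum for the canonical config."""
    total = 96 * 3 * 49 + 96  # conv1 7x7
    cfg = [  # (in, squeeze, expand1, expand3)
        (96, 16, 64, 64), (128, 16, 64, 64), (128, 32, 128, 128),
        (256, 32, 128, 128), (256, 48, 192, 192), (384, 48, 192, 192),
        (384, 64, 256, 256), (512, 64, 256, 256),
    ]
    for in_c, sq, e1, e3 in cfg:
        total += fire_params(in_c, sq, e1, e3)
    total += num_classes * 512 + num_classes  # conv10 1x1
    return total


def test_squeezenet_parameter_count_matches_brute_force_oracle():
    for k in (13, 1000):
        model = build_architecture(ArchSpec("squeezenet", k))
        assert count_parameters(model) == squeezenet_param_oracle(k)


def test_canonical_squeezenet_is_1_2_million_parameters():
    model = build_architecture(ArchSpec("squeezenet", 1000))
    millions = count_parameters(model) / 1e6
    # two significant figures, as the size is usually quoted
    assert float(f"{millions:.2g}") == 1.2


def test_canonical_alexnet_is_about_60_million_parameters():
    model = build_architecture(ArchSpec("alexnet", 1000))
    n = count_parameters(model)
    assert n == 61_100_840  # exact single-stream count


def test_width_multiplier_strictly_shrinks_models():
    for arch in EXPECTED_LAYERS:
        full = count_parameters(build_architecture(ArchSpec(arch, 13)))
        half = count_parameters(
            build_architecture(ArchSpec(arch, 13, 256, 0.5))
        )
        assert half < full


def test_lone_linear_layer_closed_form():
    from artscore.nn.layers import Linear

    layer = Linear(17, 9)
    assert sum(p.data.size for p in layer.parameters()) == 17 * 9 + 9


def test_softmax_probabilities_sum_to_one():
    model = build_architecture(ArchSpec("squeezenet", 5, 64, 0.25))
    rng = np.random.default_rng(0)
    probs = predict_proba(model, rng.random((3, 64, 64)))
    assert probs.shape == (3, 5)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)


def test_resnet_identity_shortcuts_carry_signal_with_zeroed_branches():
    model = build_architecture(ArchSpec("resnet50", 13, 64, 0.25))
    from artscore.nets import Bottleneck

    for m in model.modules():
        if isinstance(m, Bottleneck):
            for name in ("conv1", "conv2", "conv3"):
                getattr(m, name).weight.data[:] = 0.0
                getattr(m, name).bias.data[:] = 0.0
    probs = predict_proba(model, np.random.default_rng(1).random((1, 64, 64)))
    assert np.isfinite(probs).all() and probs.shape == (1, 13)


def test_prediction_is_deterministic():
    model = build_architecture(ArchSpec("squeezenet", 5, 64, 0.25))
    chop = np.random.default_rng(2).random((64, 64))
    assert np.array_equal(predict_chop(model, chop), predict_chop(model, chop))


def test_unknown_architecture_rejected():
    with pytest.raises(ValueError):
        ArchSpec("lenet", 5)


class TestTraining:
    @pytest.fixture(scope="class")
    def tiny_run(self, merged5):
        from artscore.synthgen import generate_chop_dataset

        ds = generate_chop_dataset(24, merged5, 64, seed=1)
        x, y = ds.chops, ds.labels
        model = build_architecture(ArchSpec("squeezenet", 5, 64, 0.25), seed=0)
        cfg = TrainConfig(epochs=4, seed=0)
        model, report = train_classifier(model, x[:96], y[:96], x[96:], y[96:], cfg)
        return model, report, (x, y, cfg)

    def test_lr_trace_is_non_increasing_piecewise_constant(self, tiny_run):
        _, report, _ = tiny_run
        lrs = report.lr
        assert all(b <= a for a, b in zip(lrs, lrs[1:]))
        assert set(lrs) <= {1e-2, 1e-3, 1e-4, 1e-5}

    def test_top5_at_least_top1_every_epoch(self, tiny_run):
        _, report, _ = tiny_run
        for t1, t5 in zip(report.val_acc, report.val_top5):
            assert t5 >= t1
        for t1, t5 in zip(report.train_acc, report.train_top5):
            assert t5 >= t1
        assert all(0 <= v <= 100 for v in report.val_acc + report.train_acc)

    def test_same_seed_reproduces_loss_history(self, tiny_run, merged5):
        _, report, (x, y, cfg) = tiny_run
        model2 = build_architecture(ArchSpec("squeezenet", 5, 64, 0.25), seed=0)
        _, report2 = train_classifier(model2, x[:96], y[:96], x[96:], y[96:], cfg)
        assert report.train_loss == report2.train_loss
        assert report.val_loss == report2.val_loss

    def test_checkpoint_round_trip_is_bitwise(self, tiny_run, tmp_path):
        model, _, (x, _, _) = tiny_run
        path = tmp_path / "clf.h5"
        save_classifier(path, model)
        loaded = load_classifier(path)
        a = predict_proba(model, x[:4])
        b = predict_proba(loaded, x[:4])
        assert np.array_equal(a, b)

    def test_labels_out_of_range_rejected(self):
        model = build_architecture(ArchSpec("squeezenet", 5, 64, 0.25))
        x = np.zeros((4, 64, 64))
        with pytest.raises(ValueError, match="labels"):
            train_classifier(
                model, x, np.array([0, 1, 2, 7]), x, np.zeros(4, int),
                TrainConfig(epochs=1),
            )


def test_estimator_clones_and_fits_through_sklearn_api(merged5):
    from sklearn.base import clone

    from artscore.synthgen import generate_chop_dataset

    est = ChopClassifier(
        arch="squeezenet", width_multiplier=0.25, input_size=64,
        epochs=2, seed=0,
    )
    est2 = clone(est)
    assert est2.get_params() == est.get_params()
    ds = generate_chop_dataset(12, merged5, 64, seed=2)
    est2.fit(ds.chops, ds.labels)
    preds = est2.predict(ds.chops[:5])
    assert preds.shape == (5,)
    assert set(preds) <= set(est2.classes_)
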