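import numpy as np
import pytest

from prm3d.cnn import (
    TrainConfig,
    build_model,
    cross_validate,
    predict,
    softmax,
    train,
)
from prm3d.cnn.train import fold_partition
from prm3d.preprocess import NetworkInput


def _constant_input(level, subject_id, label):
    return NetworkInput(np.full((1, 32, 32, 32), level, dtype=np.float32),
                        "prm", subject_id, label)


def _separable_dataset(n=20):
    # all-emphysema PRM (intensity 1.0) vs all-normal PRM (0.125)
    return [
        _constant_input(1.0 if i % 2 else 0.125, f"s{i}", i % 2)
        for i in range(n)
    ]


def test_parameter_count_matches_layer_arithmetic():
    # conv: f*(27c+1); BN: 2f; dense: in*out+out
    expected = (
        32 * (27 * 1 + 1) + 64 * (27 * 32 + 1) + 128 * (27 * 64 + 1)
        + 2 * (32 + 64 + 128)
        + (4 ** 3 * 128) * 128 + 128 + 128 * 128 + 128 + 128 * 2 + 2
    )
    assert expected == 1_343_490
    assert build_model(1).n_parameters() == expected


def test_two_channel_model_parameter_count():
    m = build_model(2)
    assert m.n_parameters() == 1_343_490 + 32 * 27  # extra input-channel taps


def test_rejects_unsupported_channel_count():
    with pytest.raises(ValueError):
        build_model(3)


def test_forward_zero_input_is_finite_softmax():
    m = build_model(1, seed=0)
    probs = softmax(m.forward(np.zeros((2, 32, 32, 32, 1), np.float32)))
    assert np.isfinite(probs).all()
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_same_seed_identical_weights():
    a, b = build_model(1, seed=7), build_model(1, seed=7)
    for pa, pb in zip(a.params(), b.params()):
        np.testing.assert_array_equal(pa, pb)
    c = build_model(1, seed=8)
    assert any(not np.array_equal(pa, pc)
               for pa, pc in zip(a.params(), c.params()))


def test_predict_is_deterministic_and_batch_consistent(rng):
    m = build_model(1, seed=3)
    x = NetworkInput(rng.random((1, 32, 32, 32)).astype(np.float32), "prm", "a")
    p1, p2 = predict(m, x), predict(m, x)
    np.testing.assert_array_equal(p1, p2)
    batch = predict(m, [x, x, x])
    assert batch.shape == (3, 2)
    np.testing.assert_allclose(batch, np.tile(batch[0], (3, 1)), atol=1e-6)
    np.testing.assert_allclose(batch.sum(axis=1), 1.0, atol=1e-6)


def test_training_separates_trivial_classes():
    data = _separable_dataset(20)
    model = build_model(1, seed=0)
    cfg = TrainConfig(iterations=45, batch_size=10, seed=0)
    res = train(model, data, cfg)
    assert res.acc_history[-1] == 1.0
    # converging optimization: early-phase loss far above late-phase loss
    assert np.mean(res.loss_history[-10:]) < np.mean(res.loss_history[:10])


def test_training_rejects_single_class():
    data = [_constant_input(1.0, f"s{i}", 1) for i in range(8)]
    with pytest.raises(ValueError):
        train(build_model(1), data, TrainConfig(iterations=2, batch_size=4))


def test_train_reproducible_given_seed():
    data = _separable_dataset(12)
    cfg = TrainConfig(iterations=5, batch_size=6, seed=5)
    r1 = train(build_model(1, seed=1), data, cfg)
    r2 = train(build_model(1, seed=1), data, cfg)
    np.testing.assert_array_equal(r1.loss_history, r2.loss_history)
    for pa, pb in zip(r1.model.params(), r2.model.params()):
        np.testing.assert_array_equal(pa, pb)


def test_fold_partition_properties():
    labels = np.r_[np.ones(204, int), np.zeros(392, int)]
    folds = fold_partition(labels, k=5, seed=0)
    test_sizes = sorted(len(te) for _, te in folds)
    assert set(test_sizes) <= {119, 120}
    seen = np.concatenate([te for _, te in folds])
    assert sorted(seen) == list(range(596))  # disjoint cover
    ratio = labels.mean()
    for tr, te in folds:
        assert not set(tr) & set(te)
        # stratification: class count within one subject of proportionality
        assert abs(labels[te].sum() - ratio * len(te)) <= 1


def test_fold_partition_deterministic():
    labels = np.r_[np.ones(20, int), np.zeros(30, int)]
    a = fold_partition(labels, 5, seed=3)
    b = fold_partition(labels, 5, seed=3)
    for (tra, tea), (trb, teb) in zip(a, b):
        np.testing.assert_array_equal(tea, teb)


def test_cross_validate_contract_on_separable_data():
    data = _separable_dataset(20)
    cfg = TrainConfig(iterations=30, batch_size=8, seed=0)
    results, report = cross_validate(data, k=2, cfg=cfg)
    tested = sorted(sid for r in results for sid in r.test_ids)
    assert tested == sorted(d.subject_id for d in data)
    assert report.accuracy == 1.0
    for r in results:
        assert np.all((r.test_probs >= 0) & (r.test_probs <= 1))


def test_cross_validate_argument_errors():
    data = _separable_dataset(8)
    with pytest.raises(ValueError):
        cross_validate(data, k=1, cfg=TrainConfig(iterations=1))
    with pytest.raises(ValueError):
        cross_validate(data, k=5, cfg=TrainConfig(iterations=1))
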