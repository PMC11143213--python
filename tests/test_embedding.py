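"""Loss identities, gradient correctness, sampling, and training contracts."""

import numpy as np
import pytest

from lrbin.embedding import (
    EmbedderConfig,
    VariationalEmbedder,
    WeightedSampler,
    embed,
    loss_components,
    make_weighted_sampler,
    train_embedder,
)
from lrbin.features import FeatureRecord


def _random_simplex(rng, n):
    x = rng.random(n)
    return x / x.sum()


def _records(n, dim_a=400, dim_t=136, seed=0, flag_first=False):
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        x_a = _random_simplex(rng, dim_a)
        x_t = _random_simplex(rng, dim_t)
        recs.append(
            FeatureRecord(
                barcode=f"b{i}", x_a=x_a, x_t=x_t,
                sampling_weight=float(x_a.max() ** 2),
                flagged=flag_first and i == 0,
            )
        )
    return recs


def test_kl_vanishes_at_prior():
    lb = loss_components(
        _random_simplex(np.random.default_rng(0), 400),
        _random_simplex(np.random.default_rng(1), 136),
        np.full(400, 1 / 400), np.full(136, 1 / 136),
        mu=np.zeros(32), sigma=np.ones(32),
    )
    assert lb.l_kl == pytest.approx(0.0, abs=1e-12)


def test_loss_weights_recomputed_from_dims():
    config = EmbedderConfig()
    w_a, w_t, w_kl = config.loss_weights(400, 136)
    assert w_a == pytest.approx(0.1 / np.log(400))
    assert w_a == pytest.approx(0.0166914, abs=1e-6)
    assert w_t == pytest.approx(0.9 / np.log(136))
    assert w_kl == pytest.approx(0.015 / 32)
    # different dims -> different weights (nothing hard-coded)
    assert config.loss_weights(100, 50)[0] == pytest.approx(0.1 / np.log(100))


def test_weighted_sum_identity():
    rng = np.random.default_rng(2)
    config = EmbedderConfig()
    lb = loss_components(
        _random_simplex(rng, 400), _random_simplex(rng, 136),
        _random_simplex(rng, 400), _random_simplex(rng, 136),
        mu=rng.normal(size=32), sigma=np.abs(rng.normal(size=32)) + 0.1,
        config=config,
    )
    w_a, w_t, w_kl = config.loss_weights(400, 136)
    assert lb.total == pytest.approx(w_a * lb.l_a + w_t * lb.l_t + w_kl * lb.l_kl, abs=1e-6)
    assert lb.l_kl >= 0


def test_perfect_reconstruction_of_one_hot():
    x_a = np.eye(400)[7]
    lb = loss_components(
        x_a, np.full(136, 1 / 136), x_a, np.full(136, 1 / 136),
        mu=np.zeros(32), sigma=np.ones(32),
    )
    assert lb.l_a == pytest.approx(-np.log(1 + 1e-9), abs=1e-12)


def test_as_printed_flips_reconstruction_sign():
    rng = np.random.default_rng(3)
    args = (
        _random_simplex(rng, 400), _random_simplex(rng, 136),
        _random_simplex(rng, 400), _random_simplex(rng, 136),
        rng.normal(size=32), np.abs(rng.normal(size=32)) + 0.1,
    )
    default = loss_components(*args)
    printed = loss_components(*args, config=EmbedderConfig(as_printed=True))
    assert printed.l_a == pytest.approx(-default.l_a)
    assert printed.l_kl == pytest.approx(default.l_kl)


def test_loss_shape_mismatch_raises():
    with pytest.raises(ValueError, match="shape"):
        loss_components(np.ones(400), np.ones(136), np.ones(399), np.ones(136),
                        np.zeros(32), np.ones(32))


def test_weighted_sampler_ratio():
    sampler = WeightedSampler([1.0, 3.0], seed=0)
    draws = sampler.draw(100_000)
    share = np.mean(draws == 1)
    assert share == pytest.approx(0.75, abs=0.02)


def test_weighted_sampler_degenerate_and_deterministic():
    assert set(WeightedSampler([5.0], seed=1).draw(50)) == {0}
    a = WeightedSampler([1, 2, 3], seed=2).draw(100)
    b = WeightedSampler([1, 2, 3], seed=2).draw(100)
    assert (a == b).all()


def test_weighted_sampler_all_zero():
    with pytest.raises(ValueError, match="uniform_fallback"):
        WeightedSampler([0.0, 0.0], seed=0)
    s = WeightedSampler([0.0, 0.0], seed=0, uniform_fallback=True)
    assert set(s.draw(200)) == {0, 1}


def test_make_weighted_sampler_uses_record_weights():
    recs = _records(3, seed=4)
    recs[0].sampling_weight = 0.0
    recs[1].sampling_weight = 1.0
    recs[2].sampling_weight = 1.0
    draws = make_weighted_sampler(recs, seed=5).draw(500)
    assert 0 not in draws


def test_backprop_matches_finite_differences():
    """Analytic gradients agree with numerical differentiation of the loss."""
    config = EmbedderConfig(hidden_sizes=(8, 8), latent_dim=4, dropout_p=0.0, seed=6)
    model = VariationalEmbedder(10, 6, config)
    rng = np.random.default_rng(7)
    x = np.hstack([
        np.stack([_random_simplex(rng, 10) for _ in range(5)]),
        np.stack([_random_simplex(rng, 6) for _ in range(5)]),
    ])
    eps = rng.standard_normal((5, 4))
    model.loss_and_grads(x, eps=eps)
    checked = 0
    for _, owner, name, grad in list(model._grad_pairs()):
        param = getattr(owner, name)
        flat_idx = (0,) if param.ndim == 1 else (0, 0)
        h = 1e-6
        orig = param[flat_idx]
        param[flat_idx] = orig + h
        up = loss_components_total(model, x, eps)
        param[flat_idx] = orig - h
        down = loss_components_total(model, x, eps)
        param[flat_idx] = orig
        numeric = (up - down) / (2 * h)
        assert grad[flat_idx] == pytest.approx(numeric, rel=1e-3, abs=1e-7), name
        checked += 1
    assert checked >= 10


def loss_components_total(model, x, eps):
    mu, sigma, _ = model._encode(x, train=True)
    z = mu + sigma * eps
    xhat_a, xhat_t = model._decode(z, train=True)
    lb = loss_components(
        x[:, : model.dim_a], x[:, model.dim_a :], xhat_a, xhat_t, mu, sigma, model.config
    )
    return lb.total


def _small_config(**kw):
    defaults = dict(hidden_sizes=(32, 32), latent_dim=8, batch_size=16,
                    max_epochs=8, patience=5, seed=11)
    defaults.update(kw)
    return EmbedderConfig(**defaults)


def test_training_reduces_loss_and_is_deterministic():
    recs = _records(80, seed=8)
    model1, log1 = train_embedder(recs, _small_config())
    model2, log2 = train_embedder(recs, _small_config())
    assert log1[4]["total"] <= log1[0]["total"]
    assert log1[-1]["val_total"] == log2[-1]["val_total"]
    for key, arr in model1.state_arrays().items():
        np.testing.assert_array_equal(arr, model2.state_arrays()[key])


def test_logged_totals_satisfy_weighted_sum_identity():
    recs = _records(64, seed=9)
    config = _small_config(max_epochs=3)
    _, log = train_embedder(recs, config)
    w_a, w_t, w_kl = config.loss_weights(400, 136)
    for entry in log:
        expected = w_a * entry["l_a"] + w_t * entry["l_t"] + w_kl * entry["l_kl"]
        assert entry["total"] == pytest.approx(expected, abs=1e-6)


def test_train_requires_enough_records():
    with pytest.raises(ValueError, match="batch_size"):
        train_embedder(_records(10, seed=10), _small_config(batch_size=16))


def test_embed_is_deterministic_and_excludes_flagged():
    recs = _records(80, seed=12, flag_first=True)
    recs[0].x_a = np.zeros(400)
    model, _ = train_embedder(recs, _small_config())
    r1 = embed(model, recs)
    r2 = embed(model, recs)
    assert r1.mu.shape == (79, 8)
    assert r1.excluded == ["b0"]
    np.testing.assert_array_equal(r1.mu, r2.mu)
    # duplicating a record duplicates its row exactly
    dup = embed(model, [recs[1], recs[1]])
    np.testing.assert_array_equal(dup.mu[0], dup.mu[1])


def test_checkpoint_round_trip(tmp_path):
    recs = _records(64, seed=13)
    model, _ = train_embedder(recs, _small_config(max_epochs=2))
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = VariationalEmbedder.load(path)
    np.testing.assert_array_equal(embed(model, recs).mu, embed(loaded, recs).mu)


def test_config_validation():
    with pytest.raises(ValueError, match="alpha"):
        EmbedderConfig(alpha=1.5)


def test_weighted_sampling_raises_rare_genome_share(small_community):
    """Weighted draws contain more rare-genome barcodes than uniform draws."""
    from lrbin.features import build_global_kmer_table, extract_features
    from lrbin.simulate import barcode_truth_labels

    groups = small_community["groups"]
    table = build_global_kmer_table(groups)
    records = extract_features(groups, table)
    labels = barcode_truth_labels(small_community["truth"])
    rare = np.array([labels[r.barcode] == "g2" for r in records])
    weighted = make_weighted_sampler(records, seed=31).draw(20_000)
    uniform = WeightedSampler(np.ones(len(records)), seed=31).draw(20_000)
    assert rare[weighted].mean() > rare[uniform].mean()
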