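"""Featurizer determinism, transformer aggregation and component reduction."""

import numpy as np
import pytest

from lactopath import synthio
from lactopath.containers import PatchBag, Tile
from lactopath.mil import (
    AggregatorConfig,
    HandcraftedFeaturizer,
    aggregate_slide,
    featurize_patches,
    init_aggregator,
    reduce_components,
    train_aggregator,
)
from lactopath.mil import transformer as tr


def _tiles(rng, n, edge=32):
    return [
        Tile(
            slide_id="s",
            x=i * edge,
            y=0,
            pixels=rng.integers(0, 255, size=(edge, edge, 3)).astype(np.uint8),
        )
        for i in range(n)
    ]


@pytest.fixture(scope="module")
def small_cfg():
    return AggregatorConfig(
        input_dim=12, model_dim=16, n_layers=2, n_heads=2, head_dim=8,
        ffn_dim=32, seed=0,
    )


class TestFeaturizer:
    def test_same_tile_same_embedding(self, rng):
        tiles = _tiles(rng, 1)
        bag1 = featurize_patches(tiles * 2, seed=3)
        np.testing.assert_array_equal(bag1.embeddings[0], bag1.embeddings[1])

    def test_batch_size_does_not_change_results(self, rng):
        tiles = _tiles(rng, 30)
        a = featurize_patches(tiles, batch_size=1, seed=0)
        b = featurize_patches(tiles, batch_size=256, seed=0)
        np.testing.assert_array_equal(a.embeddings, b.embeddings)

    def test_brightness_shift_changes_embedding(self, rng):
        tiles = _tiles(rng, 1)
        shifted = Tile(
            slide_id="s", x=0, y=0,
            pixels=np.clip(tiles[0].pixels.astype(int) + 40, 0, 255).astype(np.uint8),
        )
        f = HandcraftedFeaturizer(seed=0)
        e1 = f([tiles[0].pixels])
        e2 = f([shifted.pixels])
        assert np.abs(e1 - e2).max() > 1e-6

    def test_empty_tile_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            featurize_patches([], seed=0)

    def test_output_shape_and_coords(self, rng):
        tiles = _tiles(rng, 5)
        bag = featurize_patches(tiles, seed=0)
        assert bag.embeddings.shape == (5, 768)
        assert bag.coords.tolist() == [[i * 32, 0] for i in range(5)]


class TestTransformer:
    def test_gradients_match_finite_differences(self, small_cfg, rng):
        w = init_aggregator(small_cfg)
        x = rng.normal(size=(4, 12))
        dcls = rng.normal(size=16)
        _, caches = tr._forward(w.params, small_cfg, x)
        grads = tr._backward(w.params, small_cfg, caches, dcls)
        for key in ("W_in", "cls", "l0_Wq", "l0_Wo", "l1_W1", "l1_ln2_g", "lnf_g"):
            flat = w.params[key].ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                eps, orig = 1e-6, flat[i]
                flat[i] = orig + eps
                up = float(tr._forward(w.params, small_cfg, x)[0] @ dcls)
                flat[i] = orig - eps
                dn = float(tr._forward(w.params, small_cfg, x)[0] @ dcls)
                flat[i] = orig
                num = (up - dn) / (2 * eps)
                assert grads[key].ravel()[i] == pytest.approx(num, rel=1e-4, abs=1e-7)

    def test_permutation_invariance_full_size(self, rng):
        weights = init_aggregator(AggregatorConfig(seed=0))
        bag = PatchBag(slide_id="a", embeddings=rng.normal(size=(60, 768)))
        perm = PatchBag(
            slide_id="a", embeddings=bag.embeddings[rng.permutation(60)]
        )
        e1 = aggregate_slide(bag, weights).vector
        e2 = aggregate_slide(perm, weights).vector
        np.testing.assert_allclose(e1, e2, atol=1e-6)
        assert e1.shape == (512,)

    def test_single_patch_bag_valid(self, rng):
        weights = init_aggregator(AggregatorConfig(seed=0))
        bag = PatchBag(slide_id="one", embeddings=rng.normal(size=(1, 768)))
        assert aggregate_slide(bag, weights).vector.shape == (512,)

    def test_weights_roundtrip_through_checkpoint(self, tmp_path, small_cfg):
        w = init_aggregator(small_cfg)
        w.loss_history = [1.0, 0.5]
        path = tmp_path / "agg.npz"
        tr.save_weights(w, path)
        back = tr.load_weights(path)
        assert back.config == small_cfg
        assert back.loss_history == [1.0, 0.5]
        for k in w.params:
            np.testing.assert_array_equal(w.params[k], back.params[k])


def _toy_bags(rng, n_bags, n_patch, dim, effect):
    bags = []
    direction = rng.standard_normal(dim)
    direction /= np.linalg.norm(direction)
    for i in range(n_bags):
        label = i % 2
        shift = (effect / 2 if label else -effect / 2) * direction
        emb = rng.normal(size=(n_patch, dim)) + shift
        bags.append(PatchBag(slide_id=f"b{i}", embeddings=emb, label=label))
    return bags


class TestTraining:
    def test_loss_decreases_on_training_bags(self, rng):
        cfg = AggregatorConfig(
            input_dim=768, model_dim=32, n_layers=2, n_heads=2, head_dim=16,
            ffn_dim=64, seed=0,
        )
        bags = _toy_bags(rng, 12, 20, 768, effect=2.0)
        w = train_aggregator(bags, cfg, epochs=10, lr=1e-3, seed=0)
        assert w.loss_history[-1] < w.loss_history[0]

    def test_training_deterministic_given_seed(self, rng):
        cfg = AggregatorConfig(
            input_dim=768, model_dim=16, n_layers=1, n_heads=2, head_dim=8,
            ffn_dim=32, seed=0,
        )
        bags = _toy_bags(rng, 8, 10, 768, effect=1.0)
        w1 = train_aggregator(bags, cfg, epochs=2, lr=1e-3, seed=5)
        w2 = train_aggregator(bags, cfg, epochs=2, lr=1e-3, seed=5)
        assert w1.loss_history == w2.loss_history
        for k in w1.params:
            np.testing.assert_array_equal(w1.params[k], w2.params[k])

    def test_single_class_rejected(self, rng):
        bags = [
            PatchBag(slide_id=f"b{i}", embeddings=rng.normal(size=(5, 768)), label=1)
            for i in range(4)
        ]
        with pytest.raises(ValueError, match="class"):
            train_aggregator(bags, AggregatorConfig(seed=0), epochs=1)

    def test_strong_signal_cls_embeddings_linearly_separable(self, rng):
        from sklearn.linear_model import LogisticRegression

        cfg = AggregatorConfig(
            input_dim=768, model_dim=64, n_layers=2, n_heads=2, head_dim=32,
            ffn_dim=128, seed=0,
        )
        bags = _toy_bags(rng, 24, 30, 768, effect=3.0)
        train, test = bags[:16], bags[16:]
        w = train_aggregator(train, cfg, epochs=15, lr=1e-3, seed=0)
        xtr = np.stack([aggregate_slide(b, w).vector for b in train])
        xte = np.stack([aggregate_slide(b, w).vector for b in test])
        probe = LogisticRegression(max_iter=2000).fit(
            xtr, [b.label for b in train]
        )
        assert probe.score(xte, [b.label for b in test]) > 0.9


class TestReduce:
    def test_rank3_data_has_no_variance_beyond_3(self, rng):
        basis = rng.normal(size=(3, 50))
        x = rng.normal(size=(40, 3)) @ basis
        reduced, reducer = reduce_components(x, k=10)
        assert reducer.explained_variance_ratio[3:].sum() == pytest.approx(0.0, abs=1e-9)

    def test_reconstruction_matches_eckart_young(self, rng):
        x = rng.normal(size=(30, 20))
        k = 5
        reduced, reducer = reduce_components(x, k=k)
        recon = reduced @ reducer.components + reducer.mean
        err = np.linalg.norm(x - recon) ** 2
        # optimal rank-k error from the full SVD of the centered matrix
        xc = x - x.mean(axis=0)
        s = np.linalg.svd(xc, compute_uv=False)
        optimal = (s[k:] ** 2).sum()
        assert err == pytest.approx(optimal, rel=1e-9)

    def test_width_capped_with_warning(self, rng):
        x = rng.normal(size=(10, 512))
        with pytest.warns(UserWarning, match="capping"):
            reduced, _ = reduce_components(x, k=128)
        assert reduced.shape == (10, 9)

    def test_components_orthonormal_variance_nonincreasing(self, rng):
        x = rng.normal(size=(25, 15))
        _, reducer = reduce_components(x, k=8)
        gram = reducer.components @ reducer.components.T
        np.testing.assert_allclose(gram, np.eye(8), atol=1e-9)
        assert (np.diff(reducer.explained_variance) <= 1e-12).all()

    def test_single_slide_rejected(self, rng):
        with pytest.raises(ValueError):
            reduce_components(rng.normal(size=(1, 10)))


class TestEndToEndRecovery:
    """Planted-signal recovery through featurize -> aggregate -> classify."""

    def test_image_bags_flow_through_featurizer(self, rng):
        bags = synthio.simulate_bags(
            synthio.BagSimConfig(
                n_slides=4, patches_per_slide=(4, 6), tile_edge=48, seed=0
            ),
            mode="images",
        )
        emb = featurize_patches(bags[0].tiles, seed=0)
        assert emb.embeddings.shape[1] == 768
        weights = init_aggregator(AggregatorConfig(seed=0))
        vec = aggregate_slide(emb, weights).vector
        assert vec.shape == (512,)

    def test_null_effect_probe_near_chance(self, rng):
        from sklearn.linear_model import LogisticRegression

        cfg = AggregatorConfig(
            input_dim=768, model_dim=32, n_layers=2, n_heads=2, head_dim=16,
            ffn_dim=64, seed=0,
        )
        bags = _toy_bags(rng, 30, 15, 768, effect=0.0)
        w = train_aggregator(bags[:20], cfg, epochs=3, lr=1e-3, seed=0)
        xte = np.stack([aggregate_slide(b, w).vector for b in bags[20:]])
        probe = LogisticRegression(max_iter=2000).fit(
            np.stack([aggregate_slide(b, w).vector for b in bags[:20]]),
            [b.label for b in bags[:20]],
        )
        acc = probe.score(xte, [b.label for b in bags[20:]])
        assert 0.0 <= acc <= 0.9  # no perfect recovery without signal
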