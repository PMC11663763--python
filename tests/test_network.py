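import numpy as np
import pytest

from cinepc.network import (NetConfig, TrainConfig, build_network, normalize,
                            load_checkpoint, save_checkpoint,
                            symmetrized_inference, train)
from cinepc.phantom import CineMeta, CineMovie

META = CineMeta(90.0, 2.98, 1.37, 60.0, 71.52)


def _movie(data):
    return CineMovie(np.asarray(data, dtype=np.float32), META)


def _random_pair(shape=(4, 24, 24), seed=0):
    rng = np.random.default_rng(seed)
    return _movie(rng.random(shape)), _movie(rng.random(shape))


def _perturbed_model(cfg=None, seed=0, scale=0.05):
    model = build_network(cfg or NetConfig(n_levels=3, base_channels=4), seed=seed)
    rng = np.random.default_rng(seed + 1)
    for p in model.params():
        p.v += scale * rng.standard_normal(p.v.shape).astype(np.float32)
    return model


class TestArchitecture:
    def test_untrained_output_is_the_two_point_average(self):
        model = build_network(NetConfig(n_levels=3, base_channels=4), seed=2)
        p1, p2 = _random_pair()
        out = model.predict(p1.data[None, None], p2.data[None, None])
        assert np.allclose(out[0, 0], 0.5 * (p1.data + p2.data), atol=1e-6)

    @pytest.mark.parametrize("shape", [(8, 96, 96), (4, 50, 46), (12, 64, 64)])
    def test_output_geometry_matches_input(self, shape):
        model = _perturbed_model()
        p1, p2 = _random_pair(shape)
        out = model.predict(p1.data[None, None], p2.data[None, None])
        assert out.shape == (1, 1) + shape

    def test_parameter_count_independent_of_branch_order(self):
        model = build_network(NetConfig(n_levels=3, base_channels=8))
        n = model.n_parameters()
        # the encoder stack is one set of layer objects used for both inputs
        enc_params = {id(p) for b in model.enc for p in b.params()}
        all_params = [id(p) for p in model.params()]
        assert len(all_params) == len(set(all_params))
        assert enc_params <= set(all_params)
        assert n == sum(p.v.size for p in model.params())

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            NetConfig(n_levels=1)


class TestSymmetrizedInference:
    def test_order_invariance_for_random_weights(self):
        model = _perturbed_model(scale=0.1)
        p1, p2 = _random_pair(seed=5)
        a = symmetrized_inference(model, p1, p2).data
        b = symmetrized_inference(model, p2, p1).data
        assert np.allclose(a, b, rtol=1e-5, atol=1e-7)

    def test_identical_inputs_reduce_to_single_pass(self):
        model = _perturbed_model(seed=3)
        p1, _ = _random_pair(seed=6)
        sym = symmetrized_inference(model, p1, p1).data
        an, bn, f = normalize(p1.data, p1.data)
        single = model.predict(an[None, None], bn[None, None])[0, 0] * f
        assert np.array_equal(sym, np.maximum(single, 0.0).astype(np.float32))

    def test_deterministic_across_runs(self):
        p1, p2 = _random_pair(seed=7)
        outs = []
        for _ in range(2):
            model = _perturbed_model(seed=4)
            outs.append(symmetrized_inference(model, p1, p2).data)
        assert np.array_equal(outs[0], outs[1])

    def test_geometry_mismatch_rejected(self):
        model = _perturbed_model()
        with pytest.raises(ValueError):
            symmetrized_inference(model, _movie(np.ones((4, 24, 24))),
                                  _movie(np.ones((4, 24, 22))))

    def test_output_nonnegative(self):
        model = _perturbed_model(scale=0.5, seed=9)
        p1, p2 = _random_pair(seed=8)
        out = symmetrized_inference(model, p1, p2)
        assert np.all(out.data >= 0)


class TestNormalize:
    def test_constant_movies(self):
        a, b, f = normalize(10 * np.ones((2, 8, 8)), 10 * np.ones((2, 8, 8)))
        assert f == pytest.approx(10.0)
        assert np.allclose(a, 1.0) and np.allclose(b, 1.0)

    def test_homogeneity(self):
        rng = np.random.default_rng(10)
        x, y = rng.random((2, 8, 8)), rng.random((2, 8, 8))
        a1, b1, f1 = normalize(x, y)
        a2, b2, f2 = normalize(3 * x, 3 * y)
        assert f2 == pytest.approx(3 * f1, rel=1e-6)
        assert np.allclose(a1, a2, atol=1e-6)

    def test_all_zero_is_noop_with_warning(self):
        with pytest.warns(UserWarning):
            a, b, f = normalize(np.zeros((2, 8, 8)), np.zeros((2, 8, 8)))
        assert f == 1.0
        assert np.all(a == 0)


class TestTraining:
    def test_mean_label_task_converges_immediately(self):
        """label = (p1+p2)/2 is solved by the residual base, so the loss is
        tiny from the start and stays tiny."""
        rng = np.random.default_rng(11)
        triples = [(rng.random((4, 16, 16)), rng.random((4, 16, 16)), None)
                   for _ in range(4)]
        triples = [(a, b, 0.5 * (a + b)) for a, b, _ in triples]
        model = build_network(NetConfig(n_levels=2, base_channels=4), seed=0)
        model, hist = train(model, triples,
                            TrainConfig(lr=1e-3, steps=40, batch=2,
                                        crop=(4, 16, 16), seed=1,
                                        eval_every=20))
        assert hist["val_loss"][-1] < 1e-3

    def test_loss_decreases_on_banding_task(self, lv_scenes):
        triples = [(s.movies[0], s.movies[1], s.reference)
                   for s in lv_scenes[:3]]
        model = build_network(NetConfig(n_levels=2, base_channels=4), seed=1)
        model, hist = train(model, triples,
                            TrainConfig(lr=2e-3, steps=80, batch=2,
                                        crop=(4, 24, 24), seed=2,
                                        val_fraction=0.0))
        assert np.mean(hist["loss"][-10:]) < np.mean(hist["loss"][:10])

    def test_same_seed_reproduces_loss_history(self):
        rng = np.random.default_rng(12)
        triples = [(rng.random((4, 16, 16)), rng.random((4, 16, 16)),
                    rng.random((4, 16, 16))) for _ in range(3)]
        hists = []
        for _ in range(2):
            model = build_network(NetConfig(n_levels=2, base_channels=4), seed=5)
            _, h = train(model, triples,
                         TrainConfig(lr=1e-3, steps=15, batch=2,
                                     crop=(4, 16, 16), seed=3))
            hists.append(h["loss"])
        assert hists[0] == hists[1]

    def test_empty_dataset_rejected(self):
        model = build_network(NetConfig(n_levels=2, base_channels=4))
        with pytest.raises(ValueError):
            train(model, [], TrainConfig())

    def test_invalid_train_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lr=0.0)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path):
        model = _perturbed_model(seed=6)
        p1, p2 = _random_pair(seed=13)
        out1 = symmetrized_inference(model, p1, p2).data
        path = tmp_path / "model.npz"
        save_checkpoint(path, model, train_cfg=TrainConfig(), seed=6)
        restored = load_checkpoint(path)
        out2 = symmetrized_inference(restored, p1, p2).data
        assert np.array_equal(out1, out2)
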