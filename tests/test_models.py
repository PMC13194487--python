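"""Architecture contracts of the shared-private network and baselines."""

import numpy as np
import pytest

from copdord.models import (
    LogisticBaseline,
    ModelConfig,
    fit_logistic_baseline,
    forward,
    init_params,
    load_checkpoint,
    n_parameters,
    param_shapes,
    save_checkpoint,
)


@pytest.fixture
def config():
    return ModelConfig(variant="full_ordinal", d_shared=7, d_source_private=2, d_target_private=2)


def random_blocks(rng, n, config, domain="target"):
    shared = rng.random((n, 2 * config.d_shared))
    d_priv = config.d_target_private if domain == "target" else config.d_source_private
    private = rng.random((n, 2 * d_priv)) * 100
    return shared, private


class TestModelConfig:
    def test_default_head_geometry(self, config):
        # 16-d shared embedding + 8-d private embedding -> 24 -> 3 sigmoids
        assert config.head_inputs == 24
        assert config.head_outputs == 3

    def test_ablation_head_widths(self):
        assert ModelConfig(variant="shared_only_ordinal").head_inputs == 16
        assert ModelConfig(variant="private_only_ordinal").head_inputs == 8
        assert ModelConfig(variant="multiclass").head_outputs == 4

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(variant="transformer")


class TestInitParams:
    def test_deterministic_for_fixed_seed(self, config):
        a = init_params(config, seed=3)
        b = init_params(config, seed=3)
        assert all(np.array_equal(a[k], b[k]) for k in a)
        c = init_params(config, seed=4)
        assert any(not np.array_equal(a[k], c[k]) for k in a)

    def test_shapes_follow_config(self, config):
        params = init_params(config, seed=0)
        assert params["head.W"].shape == (24, 3)
        assert params["shared.0.W"].shape == (14, 32)
        assert params["target_private.W"].shape == (4, 8)

    def test_biases_zero_weights_fan_in_bounded(self, config):
        params = init_params(config, seed=0)
        for key, value in params.items():
            if key.endswith(".b"):
                assert not value.any()
            else:
                bound = 1.0 / np.sqrt(value.shape[0])
                assert (np.abs(value) <= bound).all()

    def test_parameter_count_closed_form(self, config):
        # shared: 14*32+32 + 32*16+16; privates: 2*(4*8+8); head: 24*3+3
        expected = (14 * 32 + 32) + (32 * 16 + 16) + 2 * (4 * 8 + 8) + (24 * 3 + 3)
        assert n_parameters(config) == expected == 1163


class TestForward:
    def test_zero_params_ordinal_gives_half(self, config):
        params = {k: np.zeros(s) for k, s in param_shapes(config).items()}
        rng = np.random.default_rng(0)
        shared, private = random_blocks(rng, 5, config)
        probs = forward(params, config, shared, private, "target")
        assert probs.shape == (5, 3)
        assert np.allclose(probs, 0.5)

    def test_zero_params_multiclass_uniform(self):
        config = ModelConfig(variant="multiclass")
        params = {k: np.zeros(s) for k, s in param_shapes(config).items()}
        rng = np.random.default_rng(0)
        shared, private = random_blocks(rng, 4, config)
        probs = forward(params, config, shared, private, "target")
        assert np.allclose(probs, 0.25)

    def test_multiclass_rows_sum_to_one(self):
        config = ModelConfig(variant="multiclass")
        params = init_params(config, seed=1)
        rng = np.random.default_rng(1)
        shared, private = random_blocks(rng, 10, config)
        probs = forward(params, config, shared, private, "target")
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_outputs_in_open_unit_interval(self, config):
        params = init_params(config, seed=2)
        rng = np.random.default_rng(2)
        shared, private = random_blocks(rng, 10, config)
        probs = forward(params, config, shared, private, "target")
        assert ((probs > 0) & (probs < 1)).all()

    def test_row_equivariance(self, config):
        params = init_params(config, seed=5)
        rng = np.random.default_rng(5)
        shared, private = random_blocks(rng, 8, config)
        probs = forward(params, config, shared, private, "target")
        perm = rng.permutation(8)
        permuted = forward(params, config, shared[perm], private[perm], "target")
        np.testing.assert_allclose(permuted, probs[perm])

    def test_shared_only_ignores_private_block(self):
        config = ModelConfig(variant="shared_only_ordinal")
        params = init_params(config, seed=6)
        rng = np.random.default_rng(6)
        shared, private = random_blocks(rng, 6, config)
        a = forward(params, config, shared, private, "target")
        b = forward(params, config, shared, private * 7.7 + 3, "target")
        np.testing.assert_array_equal(a, b)

    def test_private_only_ignores_shared_block(self):
        config = ModelConfig(variant="private_only_ordinal")
        params = init_params(config, seed=6)
        rng = np.random.default_rng(6)
        shared, private = random_blocks(rng, 6, config)
        a = forward(params, config, shared, private, "target")
        b = forward(params, config, shared * 0.1 - 4, private, "target")
        np.testing.assert_array_equal(a, b)

    def test_domain_routes_private_encoder(self, config):
        params = init_params(config, seed=7)
        rng = np.random.default_rng(7)
        shared, private = random_blocks(rng, 6, config, domain="source")
        a = forward(params, config, shared, private, "source")
        b = forward(params, config, shared, private, "target")
        assert not np.allclose(a, b)

    def test_width_mismatch_rejected(self, config):
        params = init_params(config, seed=0)
        with pytest.raises(ValueError):
            forward(params, config, np.zeros((3, 10)), np.zeros((3, 4)), "target")

    def test_unknown_domain_rejected(self, config):
        params = init_params(config, seed=0)
        with pytest.raises(ValueError):
            forward(params, config, np.zeros((3, 14)), np.zeros((3, 4)), "external")


class TestCheckpointIO:
    def test_round_trip(self, config, tmp_path):
        params = init_params(config, seed=9)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(params, config, path)
        loaded, loaded_config = load_checkpoint(path)
        assert loaded_config == config
        assert all(np.array_equal(params[k], loaded[k]) for k in params)


class TestLogisticBaseline:
    def test_separable_classes_fit_perfectly(self):
        # four linearly separable clusters along one axis; verify separability
        # by checking the cluster supports are disjoint, then demand a
        # perfect training fit
        rng = np.random.default_rng(12)
        centers = {1: 0.0, 2: 10.0, 3: 20.0, 4: 30.0}
        labels = np.repeat([1, 2, 3, 4], 25)
        x = np.array([centers[g] + rng.uniform(-2, 2) for g in labels])
        supports = [(x[labels == g].min(), x[labels == g].max()) for g in (1, 2, 3, 4)]
        assert all(supports[i][1] < supports[i + 1][0] for i in range(3))
        features = np.column_stack([x, rng.normal(size=x.size)])
        baseline = fit_logistic_baseline(features, labels, seed=0)
        assert (baseline.predict(features) == labels).all()

    def test_predictions_always_valid_stages(self):
        rng = np.random.default_rng(13)
        features = rng.normal(size=(40, 3))
        labels = rng.integers(1, 5, 40)
        baseline = fit_logistic_baseline(features, labels, seed=0)
        preds = baseline.predict(rng.normal(size=(100, 3)))
        assert set(np.unique(preds)) <= {1, 2, 3, 4}

    def test_deterministic(self):
        rng = np.random.default_rng(14)
        features = rng.normal(size=(60, 4))
        labels = rng.integers(1, 5, 60)
        a = fit_logistic_baseline(features, labels, seed=1).predict(features)
        b = fit_logistic_baseline(features, labels, seed=1).predict(features)
        assert (a == b).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic_baseline(np.zeros((5, 2)), [2] * 5, seed=0)
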