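import numpy as np
import pytest

from kinstack import nn
from kinstack.genotypes import simulate_genotypes
from kinstack.kinship import build_kinship_set
from kinstack.metrics import pearson
from kinstack.representation import build_stack, optimal_sample_order, slices_for_samples
from kinstack.simulate import scenario_preset, simulate_scenario


def small_cfg(**kw):
    base = dict(conv_filters=(4, 8), dense_nodes=(8,), epochs=5,
                augmentation=(0, 0.1), seed=1)
    base.update(kw)
    return nn.DNNConfig(**base)


class TestBuildModel:
    def test_first_conv_parameter_count(self):
        model = nn.build_model(nn.DNNConfig(augmentation=(0, 0)), 40, 15)
        name, count = model.parameter_counts()[0]
        assert name.startswith("conv32")
        assert count == (3 * 3 * 1) * 32 + 32  # = 320

    def test_dense_weight_count_on_wide_input(self):
        # a 64-node dense layer on a 50,000-long input trains 3.2M weights
        rng = np.random.default_rng(0)
        layer = nn._Dense(50_000, 64, "relu", rng)
        assert layer.w.size == 3_200_000

    def test_layer_sequence_of_final_architecture(self):
        model = nn.build_model(nn.DNNConfig(), 40, 15)
        names = [n for n, _ in model.parameter_counts()]
        assert names == [
            "conv32_3x3_same", "dropout0.25", "conv64_3x3_same", "maxpool2x2",
            "dropout0.25", "flatten", "dense64_relu", "dropout0.25",
            "dense32_relu", "dropout0.25", "dense16_relu", "dropout0.25",
            "dense1_linear",
        ]

    def test_parameter_counts_match_hand_computation(self):
        # three architectures, counts derived by kernel*in*out + bias per layer
        cases = [
            (small_cfg(), 20, 15,
             {"conv4_3x3_same": 9 * 1 * 4 + 4, "conv8_3x3_same": 9 * 4 * 8 + 8,
              "dense8_relu": (10 * 7 * 8) * 8 + 8, "dense1_linear": 8 + 1}),
            (small_cfg(conv_filters=(2,), dense_nodes=(4, 2)), 16, 15,
             {"conv2_3x3_same": 9 * 1 * 2 + 2, "dense4_relu": (8 * 7 * 2) * 4 + 4,
              "dense2_relu": 4 * 2 + 2, "dense1_linear": 2 + 1}),
            (small_cfg(kernel=5, padding="valid", conv_filters=(3,), dense_nodes=(5,)), 21, 15,
             {"conv3_5x5_valid": 25 * 1 * 3 + 3, "dense5_relu": (8 * 5 * 3) * 5 + 5,
              "dense1_linear": 5 + 1}),
        ]
        for cfg, h, w, expected in cases:
            got = dict(nn.build_model(cfg, h, w).parameter_counts())
            for name, count in expected.items():
                assert got[name] == count, name

    def test_output_shape_single_node(self):
        model = nn.build_model(small_cfg(), 12, 15)
        out = model.predict(np.zeros((7, 12, 15)))
        assert out.shape == (7,)

    def test_input_smaller_than_pool_rejected(self):
        with pytest.raises(ValueError):
            nn.build_model(small_cfg(), 1, 15)


@pytest.fixture(scope="module")
def toy_data():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(50, 16, 15))
    # learnable signal: phenotype from mean of one image region
    y = x[:, :4, :4].mean(axis=(1, 2)) * 3.0
    return x, y


class TestTraining:
    def test_loss_descends_on_learnable_signal(self, toy_data):
        x, y = toy_data
        model = nn.build_model(small_cfg(epochs=20), 16, 15)
        hist = nn.train(model, x, y)
        assert hist["loss"][-1] < hist["loss"][0]

    def test_constant_zero_target_fits_quickly(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 8, 15))
        model = nn.build_model(small_cfg(epochs=20, drop_rate=0.0, batch_size=4), 8, 15)
        hist = nn.train(model, x, np.zeros(30))
        assert hist["loss"][-1] < 0.01

    def test_seeded_determinism_of_epoch_losses(self, toy_data):
        x, y = toy_data
        h1 = nn.train(nn.build_model(small_cfg(epochs=2), 16, 15), x, y)
        h2 = nn.train(nn.build_model(small_cfg(epochs=2), 16, 15), x, y)
        assert h1["loss"][0] == h2["loss"][0]

    def test_history_length_matches_epochs(self, toy_data):
        x, y = toy_data
        hist = nn.train(nn.build_model(small_cfg(epochs=4), 16, 15), x, y)
        assert len(hist["loss"]) == 4

    def test_augmentation_requested_through_config(self, toy_data):
        x, y = toy_data
        model = nn.build_model(small_cfg(epochs=1, augmentation=(1, 0.1)), 16, 15)
        hist = nn.train(model, x, y)  # doubles the data internally; smoke only
        assert len(hist["loss"]) == 1


class TestPredict:
    def test_duplicate_slices_identical_predictions(self):
        model = nn.build_model(small_cfg(), 10, 15)
        x = np.tile(np.random.default_rng(2).normal(size=(1, 10, 15)), (4, 1, 1))
        pred = model.predict(x)
        assert np.ptp(pred) == 0.0

    def test_batch_partition_invariance(self):
        model = nn.build_model(small_cfg(), 10, 15)
        x = np.random.default_rng(3).normal(size=(9, 10, 15))
        all_at_once = model.predict(x)
        one_by_one = np.concatenate([model.predict(x[i : i + 1]) for i in range(9)])
        np.testing.assert_allclose(all_at_once, one_by_one, atol=1e-5)

    def test_width_mismatch_rejected(self):
        model = nn.build_model(small_cfg(), 10, 15)
        with pytest.raises(ValueError, match="input"):
            model.predict(np.zeros((2, 12, 15)))


@pytest.fixture(scope="module")
def search_data():
    rng = np.random.default_rng(4)
    x = rng.normal(size=(40, 10, 15))
    y = x[:, :3, :3].mean(axis=(1, 2))
    return x, y


class TestGreedySearch:
    def test_single_candidate_grid_returns_base(self, search_data):
        x, y = search_data
        base = small_cfg(epochs=2)
        grid = {"kernel": [3], "padding": ["same"]}
        cfg, log = nn.greedy_stepwise_search(base, grid, x, y, n_replicates=2, seed=0)
        assert cfg == base
        assert [row["hyperparameter"] for row in log] == ["kernel", "padding"]

    def test_improvement_column_definition(self, search_data):
        x, y = search_data
        base = small_cfg(epochs=2)
        grid = {"kernel": [3], "drop_rate": [0.0, 0.25]}
        _, log = nn.greedy_stepwise_search(base, grid, x, y, n_replicates=2, seed=0)
        expected = 100.0 * (log[1]["score"] - log[0]["score"]) / log[0]["score"]
        assert log[1]["improvement_pct"] == pytest.approx(expected)

    def test_tie_keeps_earlier_candidate(self, search_data):
        x, y = search_data
        base = small_cfg(epochs=2)
        # identical candidates necessarily tie; the first must win
        grid = {"drop_rate": [0.25, 0.25]}
        cfg, log = nn.greedy_stepwise_search(base, grid, x, y, n_replicates=1, seed=0)
        assert cfg.drop_rate == 0.25
        assert log[0]["selected"] == 0.25

    def test_empty_candidate_list_rejected(self, search_data):
        x, y = search_data
        with pytest.raises(ValueError):
            nn.greedy_stepwise_search(small_cfg(), {"kernel": []}, x, y, n_replicates=1)


def test_overfitting_gap_visible_on_scaled_replica():
    """After full training on a small panel, train accuracy exceeds validation
    accuracy — the train/validation gap the architecture is known to keep."""
    g = simulate_genotypes(120, 800, (0.01, 0.5), n_families=12, seed=6)
    kinships = build_kinship_set(g)
    ka = next(k for k in kinships if k.maf_tag == "gt5pct" and k.rel_type == "A")
    stack = build_stack(kinships, optimal_sample_order(ka))
    sim = simulate_scenario(g, scenario_preset("S1", qtn=200, seed=3))
    pos = {s: i for i, s in enumerate(g.samples)}
    y = np.array([sim.phenotype[pos[s]] for s in stack.samples])
    train_ids, val_ids = stack.samples[:96], stack.samples[96:]
    x_train = slices_for_samples(stack, train_ids, reference_ids=train_ids)
    x_val = slices_for_samples(stack, val_ids, reference_ids=train_ids)
    cfg = nn.DNNConfig(conv_filters=(8, 16), dense_nodes=(16, 8), epochs=60,
                       augmentation=(0, 0.1), seed=2)
    model = nn.build_model(cfg, x_train.shape[1], 15)
    nn.train(model, x_train, y[:96])
    r_train = pearson(y[:96], model.predict(x_train))
    r_val = pearson(y[96:], model.predict(x_val))
    assert r_train > r_val
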