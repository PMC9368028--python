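"""Forward-pass correctness of the sharing structures and towers."""

import numpy as np
import pytest

from aquamtl.errors import ConfigError, DataError
from aquamtl.models import (
    DEFAULT_TOWER_DEPTHS,
    ModelDims,
    StructureConfig,
    build_model,
    count_params,
    dense_layer,
    forward,
    forward_gate,
    forward_gh,
    forward_hard,
    load_checkpoint,
    relu,
    save_checkpoint,
    softmax,
    tower_forward,
)
from oracles import ORACLES

TASKS = ("pH", "DO", "CODMn", "NH3N")


def make_inputs(rng, tasks, n, dim):
    return {t: rng.uniform(-1, 1, size=(n, dim)) for t in tasks}


def test_relu_branches():
    np.testing.assert_array_equal(relu(np.array([-3.0, 5.0, 0.0])), [0.0, 5.0, 0.0])


def test_softmax_values_and_stability():
    np.testing.assert_allclose(softmax(np.zeros(4)), np.full(4, 0.25))
    np.testing.assert_allclose(
        softmax(np.log(np.array([2.0, 1.0, 1.0]))), [0.5, 0.25, 0.25]
    )
    big = softmax(np.array([1000.0, 0.0]))
    assert np.isfinite(big).all()
    assert big[0] == pytest.approx(1.0)


def test_dense_layer_examples():
    out = dense_layer(np.array([1.0, 2.0]), np.eye(2), np.array([-3.0, 0.0]))
    np.testing.assert_allclose(out, [0.0, 2.0])
    np.testing.assert_allclose(
        dense_layer(np.array([5.0, -1.0]), np.zeros((2, 3)), np.zeros(3)), np.zeros(3)
    )
    assert dense_layer(np.array([1.0]), np.array([[2.0]]), np.array([1.0]),
                       activation=False) == pytest.approx(3.0)
    with pytest.raises(DataError):
        dense_layer(np.ones(3), np.eye(2), np.zeros(2))


def test_encoders_are_task_specific_and_sized():
    cfg = StructureConfig(structure="hard", hidden_width=5)
    dims = ModelDims(lookback=3, n_stations=2)
    params = build_model(cfg, dims, seed=0)
    encs = params["encoders"]
    for a in TASKS:
        assert encs[a]["W"].shape == (6, 5)
        for b in TASKS:
            if a < b:
                assert not np.array_equal(encs[a]["W"], encs[b]["W"])
    rng = np.random.default_rng(0)
    _, act = forward_hard(params, cfg, make_inputs(rng, TASKS, 4, 6),
                          return_activations=True)
    for t in TASKS:
        assert act.outs[t].shape == (4, 5)
    # concatenated shared vector stacks the four encoder outputs
    assert act.out_shared.shape == (4, 20)


def test_encoder_identity_example():
    cfg = StructureConfig(structure="single_task", tasks=("pH",), hidden_width=2,
                          tower_depths={"pH": 1})
    params = build_model(cfg, ModelDims(1, 2), seed=0)
    params["encoders"]["pH"] = {"W": np.eye(2), "b": np.zeros(2)}
    from aquamtl.models import encode_indicators
    # inputs are centered by 1/2 before the dense layer
    outs = encode_indicators({"pH": np.array([[2.5, -1.5]])}, params, cfg)
    np.testing.assert_allclose(outs["pH"], [[2.0, 0.0]])


def test_forward_zero_weights_zero_predictions():
    for structure in ("hard", "soft", "gate", "gh"):
        cfg = StructureConfig(structure=structure, hidden_width=3)
        params = build_model(cfg, ModelDims(2, 2), seed=0)
        flatzero(params)
        rng = np.random.default_rng(1)
        preds = forward(params, cfg, make_inputs(rng, TASKS, 3, 4))
        for t in TASKS:
            np.testing.assert_array_equal(preds[t], np.zeros((3, 2)))
            assert preds[t].shape == (3, 2)


def flatzero(tree):
    if isinstance(tree, dict):
        for v in tree.values():
            flatzero(v)
    elif isinstance(tree, list):
        for v in tree:
            flatzero(v)
    else:
        tree[...] = 0.0


def test_hard_identity_composition_single_task():
    # encoder and tower identity layers: prediction is
    # ReLU(ReLU(x - 1/2)) = ReLU(x - 1/2) (centering applies once)
    cfg = StructureConfig(structure="hard", tasks=("pH",), hidden_width=2,
                          tower_depths={"pH": 1})
    params = build_model(cfg, ModelDims(1, 2), seed=0)
    eye = {"W": np.eye(2), "b": np.zeros(2)}
    params["encoders"]["pH"] = {k: v.copy() for k, v in eye.items()}
    params["towers"]["pH"]["layers"] = [
        {k: v.copy() for k, v in eye.items()},
        {k: v.copy() for k, v in eye.items()},
    ]
    x = np.array([[2.0, -1.5]])
    preds = forward_hard(params, cfg, {"pH": x})
    np.testing.assert_allclose(preds["pH"], [[1.5, 0.0]])


def test_gate_uniform_and_one_hot_weights():
    cfg = StructureConfig(structure="gate", hidden_width=3)
    params = build_model(cfg, ModelDims(2, 2), seed=1)
    rng = np.random.default_rng(2)
    inputs = make_inputs(rng, TASKS, 5, 4)
    # zero gate layer -> uniform weights -> fused vector is the mean
    for t in TASKS:
        params["gates"][t]["W"][:] = 0.0
        params["gates"][t]["b"][:] = 0.0
    _, act = forward_gate(params, cfg, inputs, return_activations=True)
    for t in TASKS:
        np.testing.assert_allclose(act.gate_weights[t], 0.25)
        mean = np.mean([act.hiddens[s] for s in TASKS], axis=0)
        np.testing.assert_allclose(act.v[t], mean, atol=1e-12)
    # one-hot logits select a single hidden vector
    params["gates"]["DO"]["b"][:] = [40.0, -40.0, -40.0, -40.0]
    _, act = forward_gate(params, cfg, inputs, return_activations=True)
    np.testing.assert_allclose(act.v["DO"], act.hiddens["pH"], atol=1e-9)


def test_gate_two_task_convex_combination():
    cfg = StructureConfig(structure="gate", tasks=("pH", "DO"), hidden_width=1)
    params = build_model(cfg, ModelDims(1, 1), seed=0)
    flatzero(params)
    # hand-set: hidden vectors [2] and [4], equal gate weights -> fused [3]
    params["encoders"]["pH"]["b"][:] = 2.0
    params["encoders"]["DO"]["b"][:] = 4.0
    params["hidden_map"]["W"][:] = 1.0
    _, act = forward_gate(params, cfg, {"pH": np.zeros((1, 1)), "DO": np.zeros((1, 1))},
                          return_activations=True)
    np.testing.assert_allclose(act.gate_weights["pH"], 0.5)
    np.testing.assert_allclose(act.v["pH"], [[3.0]])


def test_gh_gate_degenerate_cases():
    cfg = StructureConfig(structure="gh", hidden_width=3)
    params = build_model(cfg, ModelDims(2, 2), seed=3)
    rng = np.random.default_rng(4)
    inputs = make_inputs(rng, TASKS, 4, 4)
    for t in TASKS:
        params["gates"][t]["W"][:] = 0.0
        params["gates"][t]["b"][:] = 0.0
    _, act = forward_gh(params, cfg, inputs, return_activations=True)
    for t in TASKS:
        np.testing.assert_allclose(act.gate_weights[t], 0.5)
    # forcing the task branch weight to 1 makes v equal the mapped hidden
    params["gates"]["pH"]["b"][:] = [60.0, -60.0]
    _, act = forward_gh(params, cfg, inputs, return_activations=True)
    np.testing.assert_allclose(act.v["pH"], act.hiddens["pH"], atol=1e-9)


def test_gh_literal_fusion_collapses_gate():
    # under the literal fusion rule both branches multiply the same vector,
    # so the gate weights cancel: v equals the mapped hidden exactly
    cfg = StructureConfig(structure="gh", hidden_width=3, gh_literal_fusion=True)
    params = build_model(cfg, ModelDims(2, 2), seed=5)
    rng = np.random.default_rng(6)
    _, act = forward_gh(params, cfg, make_inputs(rng, TASKS, 3, 4),
                        return_activations=True)
    for t in TASKS:
        np.testing.assert_allclose(act.v[t], act.hiddens[t], atol=1e-12)


def test_soft_zero_hidden_block_pads_with_zeros():
    cfg = StructureConfig(structure="soft", hidden_width=3)
    params = build_model(cfg, ModelDims(2, 2), seed=7)
    for lay in params["hidden"]:
        lay["W"][:] = 0.0
        lay["b"][:] = 0.0
    rng = np.random.default_rng(8)
    from aquamtl.models import forward_soft
    _, act = forward_soft(params, cfg, make_inputs(rng, TASKS, 3, 4),
                          return_activations=True)
    for t in TASKS:
        assert act.v[t].shape == (3, 6)
        np.testing.assert_array_equal(act.v[t][:, 3:], np.zeros((3, 3)))
        np.testing.assert_array_equal(act.v[t][:, :3], act.outs[t])


@pytest.mark.parametrize("structure", ["hard", "soft", "gate", "gh"])
def test_forward_matches_straight_line_oracle(structure):
    """Batched forwards agree with per-sample straight-line transcriptions."""
    cfg = StructureConfig(structure=structure, hidden_width=3)
    dims = ModelDims(lookback=2, n_stations=2)
    params = build_model(cfg, dims, seed=11)
    rng = np.random.default_rng(12)
    inputs = make_inputs(rng, TASKS, 6, dims.input_dim)
    preds = forward(params, cfg, inputs)
    oracle = ORACLES[structure]
    for k in range(6):
        x = {t: inputs[t][k] for t in TASKS}
        expected = oracle(params, TASKS, x)
        for t in TASKS:
            np.testing.assert_allclose(preds[t][k], expected[t], atol=1e-9)


def test_hard_param_count_closed_form():
    h, L, S = 4, 3, 2
    cfg = StructureConfig(structure="hard", hidden_width=h)
    dims = ModelDims(lookback=L, n_stations=S)
    params = build_model(cfg, dims, seed=0)
    D = L * S
    enc = 4 * (D * h + h)
    towers = 0
    for t in TASKS:
        d = DEFAULT_TOWER_DEPTHS[t]
        towers += (4 * h) * h + h          # first layer reads concat(4 outs)
        towers += (d - 1) * (h * h + h)    # remaining hidden layers
        towers += h * S + S                # station-sized head
    assert count_params(params) == enc + towers


def test_gh_has_four_two_way_gates():
    cfg = StructureConfig(structure="gh", hidden_width=5)
    params = build_model(cfg, ModelDims(2, 3), seed=0)
    assert set(params["gates"]) == set(TASKS)
    for t in TASKS:
        assert params["gates"][t]["W"].shape == (10, 2)
        assert params["gates"][t]["b"].shape == (2,)


def test_mlp_tower_depth_parameter_count():
    h, S, n_in = 4, 3, 4
    for depth, task in ((3, "pH"), (2, "CODMn")):
        cfg = StructureConfig(structure="gate", hidden_width=h)
        params = build_model(cfg, ModelDims(2, S), seed=0)
        layers = params["towers"][task]["layers"]
        assert len(layers) == depth + 1
        expected = (n_in * h + h) + (depth - 1) * (h * h + h) + (h * S + S)
        assert count_params({"layers": layers}) == expected


@pytest.mark.parametrize("tower_type", ["mlp", "lstm", "gru", "cnn", "attention"])
def test_tower_types_output_station_vector(tower_type):
    cfg = StructureConfig(structure="gh", tower_type=tower_type, hidden_width=4,
                          tower_seq_len=2)
    dims = ModelDims(lookback=3, n_stations=3)
    params = build_model(cfg, dims, seed=2)
    rng = np.random.default_rng(3)
    preds = forward(params, cfg, make_inputs(rng, TASKS, 5, dims.input_dim))
    for t in TASKS:
        assert preds[t].shape == (5, 3)
        assert np.isfinite(preds[t]).all()
        assert (preds[t] >= 0).all()


def test_mlp_tower_zero_weights_zero_output():
    tower = {"layers": [{"W": np.zeros((3, 2)), "b": np.zeros(2)}]}
    np.testing.assert_array_equal(
        tower_forward(np.ones((4, 3)), tower), np.zeros((4, 2))
    )


def test_unknown_tower_kind_rejected():
    with pytest.raises(ConfigError):
        tower_forward(np.ones((1, 4)), {"core": {}, "head": {}}, kind="wavelet")
    with pytest.raises(ConfigError):
        StructureConfig(tower_type="wavelet")
    with pytest.raises(ConfigError):
        StructureConfig(structure="very_hard")


def test_build_determinism_and_seed_sensitivity():
    cfg = StructureConfig(structure="gh", hidden_width=4)
    dims = ModelDims(2, 2)
    a = build_model(cfg, dims, seed=9)
    b = build_model(cfg, dims, seed=9)
    c = build_model(cfg, dims, seed=10)
    np.testing.assert_array_equal(a["encoders"]["pH"]["W"], b["encoders"]["pH"]["W"])
    assert not np.array_equal(a["encoders"]["pH"]["W"], c["encoders"]["pH"]["W"])


def test_station_permutation_consistency():
    """Permuting stations in inputs and weights permutes predictions."""
    S, L = 3, 2
    cfg = StructureConfig(structure="hard", tasks=("pH", "DO"), hidden_width=4)
    dims = ModelDims(lookback=L, n_stations=S)
    params = build_model(cfg, dims, seed=13)
    rng = np.random.default_rng(14)
    inputs = make_inputs(rng, cfg.tasks, 4, dims.input_dim)
    preds = forward(params, cfg, inputs)

    perm = np.array([2, 0, 1])
    # input features are (lookback, station) flattened time-major
    col_perm = np.concatenate([lag * S + perm for lag in range(L)])
    permuted_params = build_model(cfg, dims, seed=13)
    for t in cfg.tasks:
        permuted_params["encoders"][t]["W"] = params["encoders"][t]["W"][col_perm, :]
        permuted_params["towers"][t]["layers"][-1]["W"] = \
            params["towers"][t]["layers"][-1]["W"][:, perm]
        permuted_params["towers"][t]["layers"][-1]["b"] = \
            params["towers"][t]["layers"][-1]["b"][perm]
    permuted_inputs = {t: inputs[t][:, col_perm] for t in cfg.tasks}
    preds_perm = forward(permuted_params, cfg, permuted_inputs)
    for t in cfg.tasks:
        np.testing.assert_allclose(preds_perm[t], preds[t][:, perm], atol=1e-12)


def test_checkpoint_round_trip_bit_exact(tmp_path):
    cfg = StructureConfig(structure="gh", hidden_width=4)
    dims = ModelDims(3, 2)
    params = build_model(cfg, dims, seed=21)
    path = tmp_path / "model.npz"
    save_checkpoint(path, params, cfg, dims, extra={"note": "fixture"})
    loaded, cfg2, dims2, extra = load_checkpoint(path)
    assert cfg2 == cfg and dims2 == dims and extra == {"note": "fixture"}
    rng = np.random.default_rng(22)
    inputs = make_inputs(rng, cfg.tasks, 3, dims.input_dim)
    a = forward(params, cfg, inputs)
    b = forward(loaded, cfg2, inputs)
    for t in cfg.tasks:
        np.testing.assert_array_equal(a[t], b[t])


def test_task_subset_mismatch_raises():
    cfg = StructureConfig(structure="hard", hidden_width=3)
    params = build_model(cfg, ModelDims(2, 2), seed=0)
    with pytest.raises(DataError):
        forward(params, cfg, {"pH": np.zeros((1, 4))})
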