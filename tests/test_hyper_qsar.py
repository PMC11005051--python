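"""Schema bookkeeping, PWI moments, forward passes and composition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hyperqsar._tensor import Tensor
from hyperqsar.data_model_io import EmbeddingStore
from hyperqsar.hyper_qsar import (
    HyperNetSpec,
    HyperQSAR,
    MainNetSpec,
    build_param_schema,
    distribute,
    flatten_params,
    hyper_forward,
    naive_initialize,
    pwi_initialize,
    qsar_forward,
)


class TestParamSchema:
    def test_enumeration_and_total(self):
        schema = build_param_schema(MainNetSpec((4, 3, 1)))
        assert [e.name for e in schema.entries] == ["W1", "b1", "W2", "b2"]
        assert [e.shape for e in schema.entries] == [(3, 4), (3,), (1, 3), (1,)]
        assert [e.fan_in for e in schema.entries] == [4, 4, 3, 3]
        # 12 + 3 + 3 + 1
        assert schema.total_count == 19

    def test_no_hidden_layer_errors(self):
        with pytest.raises(ValueError):
            MainNetSpec((2, 1))

    def test_deeper_net(self):
        schema = build_param_schema(MainNetSpec((8, 6, 4, 1)))
        assert schema.total_count == 8 * 6 + 6 + 6 * 4 + 4 + 4 * 1 + 1


class TestPWI:
    def test_weight_head_std_matches_closed_form(self):
        """fan-in 64, c_in 128, var_t 1, linear: std = sqrt(1/(2*64*128))."""
        main = MainNetSpec((64, 64, 1), activation="linear")
        schema = build_param_schema(main)
        state = pwi_initialize(
            HyperNetSpec((32, 128)), schema, var_t=1.0, main_spec=main,
            rng=np.random.default_rng(0),
        )
        H = state.heads["W1"][0].numpy()
        assert H.std() == pytest.approx(np.sqrt(1 / (2 * 64 * 128)), rel=0.05)
        assert H.std() == pytest.approx(0.0078125, rel=0.05)

    def test_relu_gain_doubles_hidden_head_variance(self):
        main = MainNetSpec((64, 64, 1), activation="relu")
        schema = build_param_schema(main)
        state = pwi_initialize(
            HyperNetSpec((32, 128)), schema, var_t=1.0, main_spec=main,
            rng=np.random.default_rng(0),
        )
        v1 = state.heads["W1"][0].numpy().var()  # feeds relu -> gain 2
        v2 = state.heads["W2"][0].numpy().var()  # output layer -> no gain
        assert v1 / (1 / (64 * 128)) == pytest.approx(1.0, rel=0.1)
        assert v2 / (1 / (2 * 64 * 128)) == pytest.approx(1.0, rel=0.1)

    def test_single_linear_layer_variance_preserved(self):
        """Monte-Carlo: Var(z)/Var(x) within [0.9, 1.1] for a one-linear-layer
        main net with standard-normal t and x (trunk-free hypernetwork)."""
        d, c_in = 64, 128
        main = MainNetSpec((d, d, 1), activation="linear")
        schema = build_param_schema(main)
        rng = np.random.default_rng(1)
        zs = []
        for _ in range(5):  # average over head draws
            state = pwi_initialize(HyperNetSpec((c_in,)), schema, 1.0, main, rng)
            t = rng.standard_normal((2000, c_in))
            flat = hyper_forward(t, state).numpy()
            for row in range(0, 2000, 10):
                params = distribute(Tensor(flat[row]), schema)
                W1 = params["W1"].numpy()
                b1 = params["b1"].numpy()
                x = rng.standard_normal(d)
                zs.append(W1 @ x + b1)
        ratio = np.var(np.concatenate(zs))  # Var(x) = 1
        assert 0.9 <= ratio <= 1.1

    def test_predicted_parameter_moments(self):
        """theta entries: mean ~ 0 and Var(theta_W) ~ gain/(2*d_in) at var_t=1."""
        main = MainNetSpec((32, 32, 1), activation="relu")
        schema = build_param_schema(main)
        rng = np.random.default_rng(2)
        state = pwi_initialize(HyperNetSpec((64,)), schema, 1.0, main, rng)
        t = rng.standard_normal((5000, 64))
        flat = hyper_forward(t, state).numpy()
        assert abs(flat.mean()) < 0.01
        lo, hi = 0, 32 * 32
        w1_entries = flat[:, lo:hi]
        # gain 2 (feeds relu): Var = 2/(2*32) = 1/32
        assert w1_entries.var() == pytest.approx(1 / 32, rel=0.2)

    def test_var_t_zero_errors(self):
        schema = build_param_schema(MainNetSpec((4, 3, 1)))
        with pytest.raises(ValueError):
            pwi_initialize(HyperNetSpec((8, 8)), schema, 0.0)


def _mc_output_variance(state, schema, main, n=10_000, rng=None):
    rng = rng or np.random.default_rng(0)
    d_t = state.spec.trunk_dims[0]
    d_x = main.layer_dims[0]
    t = rng.standard_normal((n // 10, d_t))
    flat = hyper_forward(t, state).numpy()
    outs = []
    for row in range(flat.shape[0]):
        params = distribute(Tensor(flat[row]), schema)
        x = rng.standard_normal((10, d_x))
        # pre-activation output: identity head
        outs.append(qsar_forward(x, params, main).numpy())
    return np.var(np.concatenate(outs))


class TestSignalPropagation:
    @pytest.mark.parametrize("depth", [1, 2, 3])
    def test_pwi_keeps_variance_in_band(self, depth):
        dims = (16,) + (16,) * depth + (1,)
        main = MainNetSpec(dims, activation="relu")
        schema = build_param_schema(main)
        rng = np.random.default_rng(3)
        ratios = []
        for _ in range(5):  # average over initialization draws
            state = pwi_initialize(
                HyperNetSpec((16, 64), activation="linear"), schema, 1.0, main, rng,
                calibration=rng.standard_normal((2000, 16)),
            )
            ratios.append(_mc_output_variance(state, schema, main, n=4000, rng=rng))
        assert 0.5 <= np.mean(ratios) <= 2.0

    def test_naive_control_explodes_at_depth_3(self):
        dims = (16, 16, 16, 16, 1)
        main = MainNetSpec(dims, activation="relu")
        schema = build_param_schema(main)
        rng = np.random.default_rng(4)
        state = naive_initialize(
            HyperNetSpec((16, 64), activation="linear"), schema, main, rng
        )
        ratio = _mc_output_variance(state, schema, main, rng=rng)
        assert not (0.5 <= ratio <= 2.0)


class TestHyperForward:
    def test_zero_state_gives_zero_params(self):
        main = MainNetSpec((4, 3, 1))
        schema = build_param_schema(main)
        state = pwi_initialize(HyperNetSpec((6, 8)), schema, 1.0, main, np.random.default_rng(0))
        for W, b in state.trunk:
            W.data[:] = 0
        for H, hb in state.heads.values():
            H.data[:] = 0
            hb.data[:] = 0
        out = hyper_forward(np.ones(6), state).numpy()
        np.testing.assert_array_equal(out, np.zeros(schema.total_count))

    def test_distinct_inputs_distinct_outputs(self):
        main = MainNetSpec((4, 3, 1))
        schema = build_param_schema(main)
        state = pwi_initialize(HyperNetSpec((6, 8)), schema, 1.0, main, np.random.default_rng(1))
        a = hyper_forward(np.ones(6), state).numpy()
        b = hyper_forward(np.arange(6.0), state).numpy()
        assert not np.allclose(a, b)

    def test_batching_matches_per_row(self):
        main = MainNetSpec((4, 3, 1))
        schema = build_param_schema(main)
        state = pwi_initialize(HyperNetSpec((6, 8)), schema, 1.0, main, np.random.default_rng(2))
        T = np.random.default_rng(3).standard_normal((5, 6))
        batch = hyper_forward(T, state).numpy()
        for i in range(5):
            np.testing.assert_allclose(batch[i], hyper_forward(T[i], state).numpy(), atol=1e-12)

    def test_dim_mismatch(self):
        main = MainNetSpec((4, 3, 1))
        schema = build_param_schema(main)
        state = pwi_initialize(HyperNetSpec((6, 8)), schema, 1.0, main, np.random.default_rng(0))
        with pytest.raises(ValueError):
            hyper_forward(np.ones(7), state)


class TestDistribute:
    def test_stated_convention(self):
        schema = build_param_schema(MainNetSpec((4, 3, 1)))
        v = np.arange(19.0)
        params = distribute(Tensor(v), schema)
        np.testing.assert_array_equal(params["W1"].numpy(), np.arange(12.0).reshape(3, 4))
        np.testing.assert_array_equal(params["b1"].numpy(), [12, 13, 14])

    @given(st.lists(st.integers(1, 6), min_size=2, max_size=4))
    @settings(max_examples=30, deadline=None)
    def test_roundtrip_identity_random_shapes(self, hidden):
        dims = tuple([4] + hidden + [1])
        schema = build_param_schema(MainNetSpec(dims))
        v = np.random.default_rng(0).standard_normal(schema.total_count)
        params = distribute(Tensor(v.copy()), schema)
        np.testing.assert_array_equal(flatten_params(params, schema), v)

    def test_short_vector_errors(self):
        schema = build_param_schema(MainNetSpec((4, 3, 1)))
        with pytest.raises(ValueError):
            distribute(Tensor(np.zeros(5)), schema)


class TestQSARForward:
    def test_zero_params(self):
        main = MainNetSpec((2, 2, 1))
        schema = build_param_schema(main)
        params = distribute(Tensor(np.zeros(schema.total_count)), schema)
        assert qsar_forward(np.ones(2), params, main).numpy()[0] == 0.0
        sig = MainNetSpec((2, 2, 1), output_activation="sigmoid")
        assert qsar_forward(np.ones(2), params, sig).numpy()[0] == pytest.approx(0.5)

    def test_hand_built_two_layer(self):
        """W1=[[1,2],[3,4]], b1=[1,-1], W2=[1,-1], b2=0.5, x=(1,0) -> 0.5."""
        main = MainNetSpec((2, 2, 1))
        params = {
            "W1": np.array([[1.0, 2.0], [3.0, 4.0]]),
            "b1": np.array([1.0, -1.0]),
            "W2": np.array([[1.0, -1.0]]),
            "b2": np.array([0.5]),
        }
        out = qsar_forward(np.array([1.0, 0.0]), params, main).numpy()
        assert out[0] == pytest.approx(0.5)

    def test_batched_matches_per_row(self):
        main = MainNetSpec((3, 4, 1))
        schema = build_param_schema(main)
        rng = np.random.default_rng(5)
        params = distribute(Tensor(rng.standard_normal(schema.total_count)), schema)
        X = rng.standard_normal((6, 3))
        batch = qsar_forward(X, params, main).numpy()
        for i in range(6):
            np.testing.assert_allclose(batch[i], qsar_forward(X[i], params, main).numpy()[0])

    def test_shape_mismatch(self):
        main = MainNetSpec((3, 4, 1))
        schema = build_param_schema(main)
        params = distribute(Tensor(np.zeros(schema.total_count)), schema)
        with pytest.raises(ValueError):
            qsar_forward(np.zeros(5), params, main)


class TestHyperQSARModel:
    @staticmethod
    def fitted_model(dataset):
        drugs, targets, table, _ = dataset
        model = HyperQSAR(
            MainNetSpec((drugs.dim, 8, 1)),
            HyperNetSpec((targets.dim, 16)),
            use_context=True,
            residual=True,
            seed=0,
        )
        model.fit_context(targets, table.unique_targets())
        return model, drugs, targets, table

    def test_predict_pair_equals_explicit_composition(self, small_dataset):
        model, drugs, targets, table = self.fitted_model(small_dataset)
        rng = np.random.default_rng(0)
        for _ in range(5):
            r = table[int(rng.integers(len(table)))]
            direct = model.predict_pair(r.drug_id, r.target_id, drugs, targets)
            flat = model.predict_flat(targets[r.target_id]).numpy()
            params = distribute(Tensor(flat), model.schema)
            composed = qsar_forward(drugs[r.drug_id], params, model.main_spec).numpy()[0]
            assert direct == pytest.approx(composed, abs=1e-12)

    def test_param_cache_consistent(self, small_dataset):
        model, drugs, targets, table = self.fitted_model(small_dataset)
        a = model.predict_pair("D01", "T03", drugs, targets)
        cached = model._param_cache["T03"].copy()
        b = model.predict_pair("D02", "T03", drugs, targets)
        np.testing.assert_array_equal(cached, model._param_cache["T03"])
        model.clear_cache()
        assert model.predict_pair("D01", "T03", drugs, targets) == pytest.approx(a)

    def test_unknown_ids_error(self, small_dataset):
        model, drugs, targets, _ = self.fitted_model(small_dataset)
        with pytest.raises(KeyError):
            model.predict_pair("nope", "T01", drugs, targets)
        with pytest.raises(KeyError):
            model.predict_pair("D01", "nope", drugs, targets)

    def test_context_memory_excludes_unseen_targets(self, small_dataset):
        drugs, targets, table, _ = small_dataset
        model = HyperQSAR(
            MainNetSpec((drugs.dim, 8, 1)), HyperNetSpec((targets.dim, 16)), seed=0
        )
        train_ids = table.unique_targets()[:6]
        model.fit_context(targets, train_ids)
        assert model.memory.ids == sorted(train_ids)

    def test_save_load_roundtrip(self, small_dataset, tmp_path):
        model, drugs, targets, table = self.fitted_model(small_dataset)
        p = tmp_path / "ckpt.json"
        model.save(str(p))
        back = HyperQSAR.load(str(p))
        r = table[0]
        assert back.predict_pair(r.drug_id, r.target_id, drugs, targets) == pytest.approx(
            model.predict_pair(r.drug_id, r.target_id, drugs, targets), abs=1e-9
        )


def test_end_to_end_gradient_check():
    """Finite differences through enrich -> hyper -> qsar on a 4-dim toy."""
    rng = np.random.default_rng(10)
    drugs = EmbeddingStore(4, {"d": rng.standard_normal(4)})
    targets = EmbeddingStore(4, {f"t{i}": rng.standard_normal(4) for i in range(3)})
    model = HyperQSAR(MainNetSpec((4, 3, 1)), HyperNetSpec((4, 6)), residual=True, seed=1)
    model.fit_context(targets, targets.ids())

    def loss_value():
        flat = model.predict_flat(targets["t0"])
        params = distribute(flat, model.schema)
        out = qsar_forward(drugs["d"], params, model.main_spec)
        return (out * out).sum()

    loss = loss_value()
    loss.backward()
    checked = 0
    eps = 1e-6
    for p in model.parameters():
        if p.grad is None:
            continue
        flat_data = p.data.reshape(-1)
        flat_grad = p.grad.reshape(-1)
        for k in range(0, flat_data.size, max(1, flat_data.size // 3)):
            orig = flat_data[k]
            flat_data[k] = orig + eps
            fp = float(loss_value().numpy())
            flat_data[k] = orig - eps
            fm = float(loss_value().numpy())
            flat_data[k] = orig
            fd = (fp - fm) / (2 * eps)
            if abs(fd) > 1e-8:
                assert flat_grad[k] == pytest.approx(fd, rel=1e-4, abs=1e-6)
            checked += 1
    assert checked > 10
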