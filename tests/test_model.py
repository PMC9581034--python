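import numpy as np
import pytest

from dgann.graphs import ResidueGraph
from dgann.model import (
    Hyper,
    attention_coefficients,
    compile_graph,
    forward,
    forward_backward,
    gat_layer,
    init_params,
    load_params,
    save_params,
    score_head,
    topk_pool,
)


def toy_graph(n=5, seed=0, mask=None, edges=None):
    rng = np.random.default_rng(seed)
    if edges is None:
        edges = [[0, 1], [1, 2], [2, 3], [3, 4], [0, 4], [1, 3]]
    if mask is None:
        mask = [True, True, False, True, False]
    return ResidueGraph(
        n_nodes=n,
        edges=np.asarray(edges),
        interface_mask=np.asarray(mask[:n]),
        partition_tag=np.asarray(["receptor"] * 3 + ["ligand"] * (n - 3)),
        node_features=rng.normal(size=(n, 26)),
        label="positive",
        model_id="toy",
    )


def directed(edges, n, self_loops=False):
    e = np.asarray(edges)
    ei = list(e[:, 0]) + list(e[:, 1])
    ej = list(e[:, 1]) + list(e[:, 0])
    if self_loops:
        ei += list(range(n))
        ej += list(range(n))
    return np.asarray(ei), np.asarray(ej)


class TestAttention:
    def test_identical_neighbors_split_evenly(self):
        h = np.array([[1.0, 0.0], [0.5, 0.5], [0.5, 0.5]])
        ei = np.array([0, 0])
        ej = np.array([1, 2])
        alpha = attention_coefficients(h, np.eye(2), ei, ej)
        np.testing.assert_allclose(alpha, [0.5, 0.5])

    def test_single_neighbor_gets_all(self):
        h = np.random.default_rng(0).normal(size=(2, 3))
        alpha = attention_coefficients(h, np.eye(3), np.array([0]), np.array([1]))
        assert alpha[0] == pytest.approx(1.0)

    def test_matches_explicit_softmax(self):
        rng = np.random.default_rng(3)
        n, d = 6, 4
        h = rng.normal(size=(n, d))
        W = rng.normal(size=(d, d))
        edges = [[0, 1], [0, 2], [1, 3], [2, 4], [4, 5], [3, 5]]
        ei, ej = directed(edges, n, self_loops=True)
        alpha = attention_coefficients(h, W, ei, ej)
        z = h @ W
        for idx in range(len(ei)):
            i = ei[idx]
            nbrs = [k for k in range(len(ei)) if ei[k] == i]
            logits = np.array([z[i] @ z[ej[k]] for k in nbrs])
            expected = np.exp(logits) / np.exp(logits).sum()
            assert alpha[idx] == pytest.approx(
                expected[nbrs.index(idx)], abs=1e-9
            )

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(4)
        n = 8
        h = rng.normal(size=(n, 5))
        edges = [[i, (i + 1) % n] for i in range(n)]
        ei, ej = directed(edges, n, self_loops=True)
        alpha = attention_coefficients(h, rng.normal(size=(5, 3)), ei, ej)
        sums = np.zeros(n)
        np.add.at(sums, ei, alpha)
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)


class TestGatLayer:
    def test_zero_input_zero_output(self):
        n = 4
        edges = [[0, 1], [1, 2], [2, 3]]
        ei, ej = directed(edges, n, self_loops=True)
        out = gat_layer(np.zeros((n, 26)), np.zeros((26, 32)), ei, ej)
        assert np.array_equal(out, np.zeros((n, 32)))

    def test_self_loop_identity_weight(self):
        h = np.array([[0.3, -0.7, 0.2]])
        ei = ej = np.array([0])
        out = gat_layer(h, np.eye(3), ei, ej)
        np.testing.assert_allclose(out, np.tanh(h), atol=1e-12)

    def test_matches_dense_loop_reference(self):
        rng = np.random.default_rng(5)
        n, d_in, d_out = 7, 6, 4
        h = rng.normal(size=(n, d_in))
        W = rng.normal(size=(d_in, d_out))
        edges = [[0, 1], [1, 2], [2, 3], [3, 4], [4, 5], [5, 6], [0, 6], [2, 5]]
        ei, ej = directed(edges, n, self_loops=True)
        got = gat_layer(h, W, ei, ej)

        # hand-rolled dense reference
        z = h @ W
        nbrs = {i: [] for i in range(n)}
        for a, b in edges:
            nbrs[a].append(b)
            nbrs[b].append(a)
        for i in range(n):
            nbrs[i].append(i)
        expected = np.zeros((n, d_out))
        for i in range(n):
            logits = np.array([z[i] @ z[j] for j in nbrs[i]])
            a = np.exp(logits - logits.max())
            a /= a.sum()
            expected[i] = np.tanh(sum(ai * z[j] for ai, j in zip(a, nbrs[i])))
        np.testing.assert_allclose(got, expected, atol=1e-6)


class TestTopkPool:
    def test_padding_rows_zero(self):
        rng = np.random.default_rng(6)
        feats = rng.normal(size=(6, 32))
        imp = rng.normal(size=6)
        emb, sel = topk_pool(feats, imp, np.array([0, 2, 4]), k=5)
        assert emb.shape == (5, 33)
        assert np.array_equal(emb[3:], np.zeros((2, 33)))
        assert len(sel) == 3

    def test_selection_matches_argsort(self):
        rng = np.random.default_rng(7)
        feats = rng.normal(size=(20, 8))
        imp = rng.normal(size=20)
        iface = np.arange(0, 20, 2)
        _, sel = topk_pool(feats, imp, iface, k=5)
        expected = iface[np.argsort(-imp[iface], kind="stable")][:5]
        assert np.array_equal(sel, expected)

    def test_k1_takes_max_importance(self):
        feats = np.zeros((4, 2))
        imp = np.array([0.1, 0.9, 0.5, 0.3])
        emb, sel = topk_pool(feats, imp, np.arange(4), k=1)
        assert sel.tolist() == [1]
        assert emb[0, -1] == pytest.approx(0.9)

    def test_tie_break_by_ordinal(self):
        feats = np.zeros((4, 2))
        imp = np.array([0.5, 0.5, 0.5, 0.5])
        _, sel = topk_pool(feats, imp, np.arange(4), k=2)
        assert sel.tolist() == [0, 1]

    def test_empty_mask_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="empty interface"):
            emb, sel = topk_pool(np.zeros((3, 4)), np.zeros(3), np.array([], int), k=2)
        assert np.array_equal(emb, np.zeros((2, 5)))


class TestScoreHead:
    def test_output_in_open_interval(self):
        hyper = Hyper(k=4, dropout=0.0)
        params = init_params(hyper, np.random.default_rng(8))
        emb = np.random.default_rng(9).normal(size=(4, hyper.concat_dim))
        p = score_head(emb, params)
        assert 0.0 < p < 1.0

    def test_zero_embedding_deterministic(self):
        hyper = Hyper(k=4, dropout=0.0)
        params = init_params(hyper, np.random.default_rng(8))
        emb = np.zeros((4, hyper.concat_dim))
        assert score_head(emb, params) == score_head(emb, params)

    def test_matches_matrix_arithmetic_oracle(self):
        hyper = Hyper(k=3, conv_channels=5, dropout=0.0)
        params = init_params(hyper, np.random.default_rng(10))
        emb = np.random.default_rng(11).normal(size=(3, hyper.concat_dim))
        got = score_head(emb, params)
        conv = np.maximum(emb @ params.conv_w + params.conv_b, 0.0)
        logit = conv.reshape(-1) @ params.fc_w + params.fc_b
        expected = 1.0 / (1.0 + np.exp(-logit))
        assert got == pytest.approx(expected, abs=1e-6)


class TestForward:
    def test_deterministic(self):
        g = toy_graph()
        params = init_params(Hyper(k=3, dropout=0.0), np.random.default_rng(12))
        cg = compile_graph(g)
        assert forward(cg, params) == forward(cg, params)

    def test_permutation_invariance(self):
        g = toy_graph(seed=13)
        perm = np.array([2, 0, 4, 1, 3])
        inv = np.argsort(perm)
        g2 = ResidueGraph(
            n_nodes=5,
            edges=np.array([[min(inv[i], inv[j]), max(inv[i], inv[j])]
                            for i, j in g.edges]),
            interface_mask=g.interface_mask[perm],
            partition_tag=g.partition_tag[perm],
            node_features=g.node_features[perm],
            label=g.label,
        )
        params = init_params(Hyper(k=3, dropout=0.0), np.random.default_rng(14))
        assert forward(compile_graph(g), params) == pytest.approx(
            forward(compile_graph(g2), params), abs=1e-6
        )

    def test_empty_interface_uses_zero_embedding(self):
        g = toy_graph(mask=[False] * 5)
        params = init_params(Hyper(k=3, dropout=0.0), np.random.default_rng(15))
        with pytest.warns(UserWarning):
            p = forward(compile_graph(g), params)
        zero_emb = np.zeros((3, params.hyper.concat_dim))
        assert p == pytest.approx(score_head(zero_emb, params))

    def test_features_unset_raises(self):
        g = toy_graph()
        g.node_features = None
        with pytest.raises(ValueError, match="features"):
            compile_graph(g)

    def test_attention_rows_sum_to_one_through_stack(self):
        g = toy_graph(seed=16)
        cg = compile_graph(g)
        params = init_params(Hyper(k=3, dropout=0.0), np.random.default_rng(17))
        h = cg.x
        for W, att in zip(params.Ws, params.atts):
            alpha = attention_coefficients(h, W, cg.ei, cg.ej)
            sums = np.zeros(cg.n)
            np.add.at(sums, cg.ei, alpha)
            np.testing.assert_allclose(sums, 1.0, atol=1e-6)
            h = gat_layer(h, W, cg.ei, cg.ej)

    @pytest.mark.parametrize("n_layers", [1, 2, 3, 4])
    def test_layer_count_variants_run(self, n_layers):
        g = toy_graph(seed=18)
        params = init_params(
            Hyper(n_layers=n_layers, k=3, dropout=0.0), np.random.default_rng(19)
        )
        assert 0.0 < forward(compile_graph(g), params) < 1.0

    def test_global_poolings_agree_on_single_interface_node(self):
        g = toy_graph(mask=[False, False, True, False, False], seed=20)
        cg = compile_graph(g)
        outs = []
        for readout in ("topk", "mean", "max"):
            hyper = Hyper(k=1, readout=readout, dropout=0.0)
            params = init_params(hyper, np.random.default_rng(21))
            outs.append(forward(cg, params))
        assert outs[0] == pytest.approx(outs[1], abs=1e-12)
        assert outs[0] == pytest.approx(outs[2], abs=1e-12)


class TestGradients:
    @pytest.mark.parametrize("mode", ["dot", "gat_v1"])
    def test_finite_difference_w1(self, mode):
        g = toy_graph(seed=22)
        hyper = Hyper(k=3, dropout=0.0, attention=mode)
        params = init_params(hyper, np.random.default_rng(23))
        cg = compile_graph(g)
        _, _, grads = forward_backward(cg, params, 1.0)
        eps = 1e-6
        W1 = params.Ws[0]
        worst = 0.0
        for idx in np.ndindex(W1.shape):
            orig = W1[idx]
            W1[idx] = orig + eps
            _, lp, _ = forward_backward(cg, params, 1.0)
            W1[idx] = orig - eps
            _, lm, _ = forward_backward(cg, params, 1.0)
            W1[idx] = orig
            num = (lp - lm) / (2 * eps)
            ana = grads["W1"][idx]
            rel = abs(num - ana) / max(1e-6, abs(num) + abs(ana))
            worst = max(worst, rel)
        assert worst < 1e-4


class TestCheckpoints:
    def test_roundtrip(self, tmp_path):
        params = init_params(Hyper(k=7), np.random.default_rng(24))
        path = tmp_path / "ckpt.json"
        save_params(params, path)
        back = load_params(path)
        assert back.hyper == params.hyper
        for a, b in zip(params.Ws, back.Ws):
            np.testing.assert_allclose(a, b)
        np.testing.assert_allclose(params.fc_w, back.fc_w)

    def test_hash_mismatch_rejected(self, tmp_path):
        import json

        params = init_params(Hyper(k=7), np.random.default_rng(25))
        path = tmp_path / "ckpt.json"
        save_params(params, path)
        payload = json.loads(path.read_text())
        payload["hyper"]["k"] = 9
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="hash"):
            load_params(path)
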