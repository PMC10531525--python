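import numpy as np
import pytest

from dtifusion.autodiff import Tensor
from dtifusion.featurize import smiles_to_graph
from dtifusion.gat_encoder import DrugEncoder, GATLayer
from dtifusion.io_datasets import Vocabulary
from dtifusion.nn import TrainContext

from oracles import gat_attention_loops

CTX = TrainContext.eval()


def make_layer(d=8, heads=2, seed=0):
    return GATLayer(d, heads, np.random.default_rng(seed))


class TestAttentionCoefficients:
    def test_isolated_atom_self_weight_one(self, rng):
        layer = make_layer()
        h = Tensor(rng.standard_normal((1, 1, 8)))
        attn = layer.attention(h, np.eye(1)[None]).data
        np.testing.assert_allclose(attn, 1.0)

    def test_symmetric_pair_uniform_attention(self, rng):
        layer = make_layer()
        row = rng.standard_normal(8)
        h = Tensor(np.stack([row, row])[None])
        attn = layer.attention(h, np.ones((1, 2, 2))).data
        np.testing.assert_allclose(attn, 0.5, atol=1e-7)

    def test_rows_sum_to_one_and_match_loop_oracle(self, rng):
        layer = make_layer(d=6, heads=3)
        n = 5
        adj = np.eye(n)
        for (i, j) in [(0, 1), (1, 2), (2, 3), (0, 4), (3, 4)]:
            adj[i, j] = adj[j, i] = 1
        h0 = rng.standard_normal((n, 6))
        attn = layer.attention(Tensor(h0[None]), adj[None]).data[0]
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(attn[:, adj == 0] == 0) if adj.ndim == 1 else True
        oracle = gat_attention_loops(h0, adj, layer.w.data,
                                     layer.a_src.data, layer.a_dst.data)
        np.testing.assert_allclose(attn, oracle, atol=1e-6)

    def test_non_neighbors_get_zero_weight(self, rng):
        layer = make_layer()
        adj = np.eye(3)
        adj[0, 1] = adj[1, 0] = 1
        h = Tensor(rng.standard_normal((1, 3, 8)))
        attn = layer.attention(h, adj[None]).data[0]
        assert np.all(attn[:, :, 2][:, :2] == 0)
        assert np.all(attn[:, 2, :2] == 0)

    def test_nan_features_fatal(self, rng):
        layer = make_layer()
        h = np.ones((1, 2, 8)); h[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            layer(Tensor(h), np.ones((1, 2, 2)), CTX)


class TestGatLayer:
    def test_single_atom_single_head_is_relu_lift(self, rng):
        layer = GATLayer(4, 1, np.random.default_rng(3))
        layer.proj.weight.data = np.eye(4)  # identity output projection
        h0 = rng.standard_normal((1, 1, 4))
        out = layer(Tensor(h0), np.eye(1)[None], CTX).data
        expected = np.maximum(h0 @ layer.w.data, 0.0)
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_permutation_equivariance(self, rng):
        layer = make_layer(d=8, heads=2)
        n = 6
        adj = np.eye(n)
        for (i, j) in [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0)]:
            adj[i, j] = adj[j, i] = 1
        h0 = rng.standard_normal((n, 8))
        out = layer(Tensor(h0[None]), adj[None], CTX).data[0]
        perm = rng.permutation(n)
        out_p = layer(Tensor(h0[perm][None]), adj[np.ix_(perm, perm)][None], CTX).data[0]
        np.testing.assert_allclose(out_p, out[perm], atol=1e-6)

    def test_eight_heads_concat_width(self):
        layer = GATLayer(64, 8, np.random.default_rng(0))
        assert layer.d_head == 8
        assert layer.n_heads * layer.d_head == 64


class TestDrugEncoder:
    def _graph(self, smiles):
        v = Vocabulary()
        return smiles_to_graph(smiles, 0, v, update_vocab=True)

    def test_benzene_rows_identical_by_symmetry(self, rng):
        g = self._graph("c1ccccc1")
        enc = DrugEncoder(4, 16, 2, 2, rng)
        out = enc(g.atom_ids[None], g.adjacency[None], CTX).data[0]
        for i in range(1, 6):
            np.testing.assert_allclose(out[i], out[0], atol=1e-6)

    def test_ethanol_shape_and_finite(self, rng):
        g = self._graph("CCO")
        enc = DrugEncoder(4, 64, 3, 8, rng)
        out = enc(g.atom_ids[None], g.adjacency[None], CTX).data
        assert out.shape == (1, 3, 64)
        assert np.all(np.isfinite(out))

    def test_zero_layers_gives_embeddings(self, rng):
        g = self._graph("CCO")
        enc = DrugEncoder(4, 8, 0, 2, rng)
        out = enc(g.atom_ids[None], g.adjacency[None], CTX).data
        np.testing.assert_allclose(out[0], enc.embedding.weight.data[g.atom_ids])

    def test_empty_neighborhood_fatal(self, rng):
        enc = DrugEncoder(4, 8, 1, 2, rng)
        adj = np.zeros((1, 2, 2)); adj[0, 0, 0] = 1  # atom 1 has no edges at all
        with pytest.raises(ValueError):
            enc(np.array([[1, 2]]), adj, CTX)

    def test_full_encoder_permutation_equivariance(self, rng):
        g = self._graph("CC(C)CO")
        enc = DrugEncoder(6, 16, 3, 2, rng)
        out = enc(g.atom_ids[None], g.adjacency[None], CTX).data[0]
        perm = rng.permutation(g.n_atom)
        adj_p = g.adjacency[np.ix_(perm, perm)]
        out_p = enc(g.atom_ids[perm][None], adj_p[None], CTX).data[0]
        np.testing.assert_allclose(out_p, out[perm], atol=1e-6)
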