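import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtifusion.featurize import (FeaturizationError, atom_environment_tokens,
                                 protein_to_ngrams, sequence_ngrams,
                                 smiles_to_graph, train_ngram_embeddings)
from dtifusion.io_datasets import Vocabulary, build_vocab
from rdkit import Chem


def fresh_vocab():
    return Vocabulary()


class TestSmilesToGraph:
    def test_ethanol_radius0(self):
        g = smiles_to_graph("CCO", radius=0, vocab=fresh_vocab(), update_vocab=True)
        assert g.n_atom == 3
        assert len(set(g.atom_ids)) == 2  # C token and O token
        assert g.atom_ids[0] == g.atom_ids[1] != g.atom_ids[2]
        off_diag = {(i, j) for i in range(3) for j in range(3)
                    if i < j and g.adjacency[i, j] == 1}
        assert off_diag == {(0, 1), (1, 2)}

    def test_benzene_radius0(self):
        g = smiles_to_graph("c1ccccc1", radius=0, vocab=fresh_vocab(), update_vocab=True)
        assert g.n_atom == 6
        assert len(set(g.atom_ids)) == 1  # one aromatic-carbon token
        neighbor_counts = g.adjacency.sum(axis=1) - 1  # minus self-loop
        assert np.all(neighbor_counts == 2)

    def test_aromatic_vs_aliphatic_carbon_distinct(self):
        v = fresh_vocab()
        g1 = smiles_to_graph("c1ccccc1", 0, v, update_vocab=True)
        g2 = smiles_to_graph("CC", 0, v, update_vocab=True)
        assert set(g1.atom_ids).isdisjoint(set(g2.atom_ids))

    @pytest.mark.parametrize("bad", ["", "not_a_smiles", "C(("])
    def test_unparsable_smiles_raises(self, bad):
        with pytest.raises(FeaturizationError):
            smiles_to_graph(bad, 2, fresh_vocab(), update_vocab=True)

    def test_single_atom_molecule(self):
        g = smiles_to_graph("C", radius=2, vocab=fresh_vocab(), update_vocab=True)
        assert g.n_atom == 1
        assert g.adjacency.tolist() == [[1.0]]

    def test_adjacency_symmetric_with_self_loops(self):
        g = smiles_to_graph("CC(C)Cc1ccccc1", 2, fresh_vocab(), update_vocab=True)
        assert np.array_equal(g.adjacency, g.adjacency.T)
        assert np.all(np.diag(g.adjacency) == 1)

    def test_invariant_to_smiles_rewriting(self):
        v = fresh_vocab()
        g1 = smiles_to_graph("CCO", 2, v, update_vocab=True)
        g2 = smiles_to_graph("OCC", 2, v)  # same molecule, reversed spelling
        assert sorted(g1.atom_ids) == sorted(g2.atom_ids)
        assert np.sort(g1.adjacency.sum(axis=1)).tolist() == \
               np.sort(g2.adjacency.sum(axis=1)).tolist()

    @pytest.mark.parametrize("smiles", ["CCO", "CC(C)CO", "c1ccc(CC#N)cc1",
                                        "CC(=O)NC", "C1CCCCC1O"])
    def test_radius_refinement(self, smiles):
        """Atoms sharing a radius-r token must share the radius-(r-1) token."""
        mol = Chem.MolFromSmiles(smiles)
        for r in (1, 2, 3):
            coarse = atom_environment_tokens(mol, r - 1)
            fine = atom_environment_tokens(mol, r)
            for i in range(mol.GetNumAtoms()):
                for j in range(mol.GetNumAtoms()):
                    if fine[i] == fine[j]:
                        assert coarse[i] == coarse[j]


class TestProteinNgrams:
    def test_single_window(self):
        t = protein_to_ngrams("MKV", 3, fresh_vocab(), update_vocab=True)
        assert t.length == 1

    def test_two_windows_stride_one(self):
        v = fresh_vocab()
        t = protein_to_ngrams("MKVL", 3, v, update_vocab=True)
        assert t.length == 2
        assert list(v.token_to_id) == ["MKV", "KVL"]

    def test_mean_length_sequence(self, rng):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 623))
        assert protein_to_ngrams(seq, 3, fresh_vocab(), update_vocab=True).length == 621

    def test_too_short_sequence_raises(self):
        with pytest.raises(FeaturizationError):
            protein_to_ngrams("MK", 3, fresh_vocab())

    @settings(max_examples=60, deadline=None)
    @given(seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=3, max_size=120),
           n=st.integers(2, 3))
    def test_token_count_property(self, seq, n):
        assert len(sequence_ngrams(seq, n)) == len(seq) - n + 1


class TestNgramEmbeddings:
    def _tokens(self, vocab, seq):
        return protein_to_ngrams(seq, 3, vocab, update_vocab=True)

    def test_degenerate_single_token_corpus(self):
        v = fresh_vocab()
        corpus = [self._tokens(v, "MKV"), self._tokens(v, "MKVL")]
        table = train_ngram_embeddings(corpus, v, dim=8, epochs=1, seed=0)
        assert np.all(np.isfinite(table.vectors))
        assert np.allclose(table.vectors[0], 0.0)  # pad row

    def test_cooccurring_tokens_more_similar(self):
        # sentences: tokens 1 and 2 always together; token 3 always alone
        v = build_vocab(["A", "B", "C"])
        rng = np.random.default_rng(4)
        from dtifusion.featurize import ProteinTokens
        corpus = []
        for _ in range(200):
            if rng.random() < 0.5:
                ids = np.array([1, 2] * 4)
            else:
                ids = np.array([3] * 8)
            corpus.append(ProteinTokens(ids, len(ids)))
        table = train_ngram_embeddings(corpus, v, dim=16, window=2, epochs=30,
                                       negatives=2, lr=0.05, seed=13)

        def cos(a, b):
            return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))

        vec = table.vectors
        assert cos(vec[1], vec[2]) > cos(vec[1], vec[3])
        assert cos(vec[1], vec[2]) > cos(vec[2], vec[3])

    def test_deterministic_given_seed(self):
        v = fresh_vocab()
        corpus = [self._tokens(v, "MKVLAAGMKV"), self._tokens(v, "GGMKVLAA")]
        t1 = train_ngram_embeddings(corpus, v, dim=8, epochs=2, seed=13)
        t2 = train_ngram_embeddings(corpus, v, dim=8, epochs=2, seed=13)
        assert np.array_equal(t1.vectors, t2.vectors)

    def test_empty_corpus_fatal(self):
        with pytest.raises(ValueError):
            train_ngram_embeddings([], fresh_vocab(), dim=8)
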