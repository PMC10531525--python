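"""Featurize one drug and one protein the way the model sees them.

A SMILES string becomes a molecular graph whose atoms carry radius-2
environment tokens; a protein sequence becomes overlapping 3-gram
tokens. Both token streams are vocabulary-indexed integers.
"""

from dtifusion import Vocabulary, protein_to_ngrams, smiles_to_graph

drug_vocab = Vocabulary()
graph = smiles_to_graph("CC(C)Cc1ccc(cc1)C(C)C(=O)O", radius=2,
                        vocab=drug_vocab, update_vocab=True)
print(f"ibuprofen: {graph.n_atom} heavy atoms, "
      f"{len(set(graph.atom_ids))} distinct radius-2 environment tokens")
print(f"adjacency row sums (degree + self-loop): "
      f"{graph.adjacency.sum(axis=1).astype(int).tolist()}")

protein_vocab = Vocabulary()
sequence = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
tokens = protein_to_ngrams(sequence, 3, protein_vocab, update_vocab=True)
print(f"\nprotein of length {len(sequence)}: {tokens.length} overlapping 3-grams "
      f"(= L - n + 1), vocabulary size {protein_vocab.size}")
print("first five token ids:", tokens.token_ids[:5].tolist())
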