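# dtifusion

Multi-view attention model for **drug–target interaction (DTI) prediction**,
for computational chemists and method developers who want a fully inspectable,
CPU-trainable implementation of the attention/multi-view-fusion family of
DTI classifiers — with a synthetic benchmark generator so the whole pipeline
is exercisable without downloading any external dataset.

## The model

A pair (drug SMILES string, protein amino-acid sequence) is classified as
interacting / non-interacting:

* **Drug encoder** — the molecule becomes a heavy-atom graph; each atom
  carries a radius-2 *atom-environment token* (a Weisfeiler–Lehman-style
  hash of the atom and its bond-annotated neighborhood). A 3-layer
  multi-head **graph attention network** (GAT) updates atom features
  `h_i' = ReLU(Σ_{j∈N_i} a_ij W h_j)` with
  `a_ij = softmax_j LeakyReLU(αᵀ[W h_i ∥ W h_j])`.
* **Protein encoder** — the sequence becomes overlapping 3-gram tokens
  embedded with skip-gram (word2vec) pre-training, plus sinusoidal
  positional encodings, through a 3-layer post-norm **transformer encoder**.
* **Attention pooling (ATT)** — two masked self-attention layers, masked
  average pooling and `tanh`, then a learned down-projection, give one
  graph-level vector per molecule, `h_drug` and `h_pro`.
* **Node-level interaction (ITM)** — two parallel **cross-attention**
  encoders: drug atoms attend protein n-grams and vice versa
  (`softmax(QKᵀ/√d)V`, multi-head, residual + layer norm), mean-pooled to
  `v_com_p` and `v_pro_c`.
* **Graph-level interaction (NTN)** — a **neural tensor network** with
  K = 16 bilinear slices:
  `g_k = ReLU(h_drugᵀ W_k h_pro + V_k[h_drug ∥ h_pro] + b_k)`.
* **Head** — `ŷ = sigmoid(W₂ ReLU(W₁ concat(v_scores, v_com_p, v_pro_c)))`,
  trained with cross-entropy, Adam (lr 1e-3, weight decay 1e-4), Xavier
  initialization, dropout 0.1, 40 epochs by default.

Ablation variants (`wo_ntn_itm`, `wo_itm`, `wo_ntn`, `wo_att`) drop
individual views and are first-class configurations.

The neural core (autodiff tape, attention layers, GAT, NTN, Adam) is
self-contained numpy; chemistry goes through RDKit, folds and metrics
through scikit-learn.

## Worked example

```bash
python examples/03_train_and_evaluate.py
```

trains a half-width model for 8 epochs on a 300-pair noiseless synthetic
benchmark (the planted rule: a pair interacts iff the molecule carries
fragment *j* — e.g. a trifluoromethyl or nitrile group — and the protein
carries the matched 5-residue motif *j*) and prints:

```
epoch mean loss: [0.798, 0.696, 0.656, 0.651, 0.563, 0.502, 0.48, 0.409]

held-out AUC=0.832 precision=0.647 recall=0.733  (30 pos / 30 neg)
```

The loss falls from chance (ln 2 ≈ 0.693) as the planted rule is picked
up; a longer run or a larger benchmark drives the held-out AUC toward
its ceiling (compare `scripts/acceptance.py`, which reaches ≈0.88–0.90
against a ≈0.90 noise ceiling at 2000 pairs).

AUC is the probability that a random interacting pair outscores a random
non-interacting one; precision and recall are taken at threshold 0.5. The
other example scripts cover dataset generation (`01`), featurization
(`02`) and cross-validation with an ablation comparison (`04`).

A thin CLI wraps the same calls:

```bash
dtifusion synth --n 2000 --noise 0.1 --seed 42 --out synth.tsv
dtifusion data validate synth.tsv
dtifusion train --data synth.tsv --out run/
dtifusion cv --data synth.tsv --k 5
dtifusion predict --model run/model.npz --smiles "CCOC(C(F)(F)F)C" --sequence "MKTAYIAK..."
```

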