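# deepnc

Drug–target binding affinity regression with graph neural networks.

Screening a compound library against a protein target is dominated by
the cost of measuring binding affinity (typically the dissociation
constant K_d, reported on the pK_d = −log10 K_d(M) scale). This package
predicts real-valued affinities directly from a compound's SMILES string
and a target's amino-acid sequence, for people building or evaluating
computational screening pipelines.

## Model

A drug is featurized as its heavy-atom molecular graph; each atom
carries five concatenated indicator blocks (element symbol, degree,
attached hydrogens, implicit valence, aromaticity; 78 features). A
target sequence is encoded as an integer label vector over the 20
standard amino acids, truncated/padded to a fixed length.

Two variants of the drug branch are provided:

* **GEN** — three generalized-aggregation convolutions followed by
  global add pooling. Each layer computes, per node *i*,

      x_i' = MLP( x_i + s·‖x_i‖₂ · m_i / ‖m_i‖₂ ),
      m_i  = AGG_{j∈N(i)} ( ReLU(x_j) + ε ),   ε = 10⁻⁷,

  where AGG is SoftMax aggregation Σ_j softmax_j(β·m_ij) ⊙ m_ij
  (interpolating the mean at β→0 and the max at β→∞) or PowerMean
  aggregation ((1/|N(i)|) Σ m_ij^p)^{1/p}, and *s* is a learnable
  message-norm scale initialized to 1.

* **HGC-GCN** — two hypergraph convolutions with attention,

      X' = D⁻¹ H W B⁻¹ Hᵀ X Θ,   D_ii = Σ_e W_ee H_ie,  B_ee = Σ_i H_ie,

  (H the node×hyperedge incidence, by default one size-2 hyperedge per
  bond; attention replaces H by a learned real-valued H̃), then one
  plain graph convolution X' = D̂^{-1/2} Â D̂^{-1/2} X Θ with Â = A + I,
  and global max pooling.

The protein branch is an embedding plus 1-D convolution with global max
over sequence positions. Both embeddings are concatenated and passed
through fully-connected layers with dropout to a single affinity
output. Training minimizes mean squared error with Adam (default lr
5·10⁻⁴, batch 256). Evaluation reports MSE, the concordance index
CI = (1/Z) Σ_{δ_i>δ_j} h(b_i − b_j) with the 0/0.5/1 step function h,
and the QSAR external-predictivity statistic r²m = r²(1 − √|r² − r₀²|).

All tensor math runs on a compact numpy reverse-mode autodiff core
(`deepnc.autodiff`); RDKit handles chemistry, Biopython FASTA.

## Worked example

Fit the GEN variant to 160 synthetic pairs (known linear
descriptor→affinity structure, noise σ = 0.3) and evaluate on 40
held-out pairs:

```python
from deepnc import AffinityModel, ModelConfig, SyntheticSpec, make_dataset, split_dataset

data = make_dataset(SyntheticSpec(n_drugs=20, n_targets=10, noise_sd=0.3, seed=1))
train_ds, test_ds = split_dataset(data, "random", fraction=0.8, seed=1)

config = ModelConfig(variant="GEN", gnn_hidden_dims=[32, 32, 32],
                     graph_embed_dim=32, protein_embed_dim=16,
                     protein_conv_filters=16, protein_kernel_size=8,
                     protein_max_len=220, fc_dims=[64], dropout_rate=0.1, seed=1)
result = AffinityModel(train_ds, config).fit(
    learning_rate=0.003, batch_size=32, epochs=150, seed=1)
print(result.summary())
print(result.evaluate(test_ds))
pair = (test_ds.smiles[0], test_ds.sequences[0])
print("predicted", round(float(result.predict([pair])[0]), 3),
      "observed", round(test_ds.affinities[0], 3))
```

prints

```
Affinity regression results
==============================================
variant                     GEN
graph layers                3
trainable parameters        16052
training pairs              160
epochs run                  150
final training MSE          0.3976
==============================================
n=40  MSE=0.1128  CI=0.9192  r2m=0.9291
predicted 8.929 observed 9.281
```

Held-out MSE 0.11 is far below the label variance (≈1.5), CI 0.92 means
92% of strictly-ordered test pairs are ranked correctly, and r²m above
0.5 marks the fit as externally predictive by the usual QSAR criterion.
The final training MSE sits near the irreducible noise floor
(σ² = 0.09) plus dropout jitter. The same surface is exposed on the
shell: `deepnc synth`, `deepnc train`, `deepnc eval`, `deepnc predict`,
`deepnc featurize` (see `deepnc --help`).

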