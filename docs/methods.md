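# Methods

## Problem and model

The package regresses the binding affinity of a (compound, protein)
pair from structure alone. Compounds are heavy-atom molecular graphs:
hydrogens are counted per atom but never appear as nodes, each covalent
bond is stored as two directed arcs, and atom order is the SMILES
parser's canonical order (stable for a fixed input string, so
featurization is bit-reproducible). Per-atom features are five one-hot
blocks — a fixed 44-element symbol vocabulary plus an "other" slot,
degree, attached-hydrogen count and implicit valence each clamped at 10,
and an aromaticity bit — 78 indicators in total. The schema is frozen
alongside any checkpoint so a model is never applied to features laid
out differently.

Proteins are integer label vectors over the 20 standard amino acids
(index 0 reserved for padding; the non-standard letters B, J, O, U, X, Z
share one "unknown" index, since real UniProt sequences contain them),
truncated or zero-padded to `protein_max_len` (default 1000, the
convention of the sequence-based affinity models this package follows).

### Drug branch

Two interchangeable stacks produce the drug embedding.

**GEN.** Three generalized-aggregation convolutions. Messages are
ReLU(x_j) + ε with ε = 10⁻⁷, which keeps every message strictly
positive so PowerMean aggregation is defined for fractional exponents.
Aggregation is either SoftMax_β (the softmax-weighted sum
Σ softmax(β·m) ⊙ m, computed per feature channel) or PowerMean_p; both
belong to the generalized mean–max family — β→0 or p=1 give the mean,
β→∞ or p→∞ the channel-wise max — and the tests assert these limits
numerically. β is a fixed (non-trained) scalar, default 1. The update
is MLP(x_i + s·‖x_i‖₂·m_i/‖m_i‖₂) with s learnable (initialized 1) and
the MLP two affine maps with an interior ReLU, hidden width equal to
the output width. Pooling is global add.

Two printed forms of this construction required interpretation. The
SoftMax-aggregation formula we implement multiplies the softmax weights
back onto the messages; the weight-only sum (which is identically 1)
cannot be what is meant, and the weighted sum is the form with the
stated mean–max limits. Likewise the aggregated message of node *v* is
written with a stray neighbor subscript in one intermediate equation;
we read it as the aggregate for *v*. Both readings are asserted by the
oracle tests rather than assumed.

**HGC-GCN.** The molecular graph is re-expressed as a hypergraph. How
hyperedges should be built from a molecule is genuinely open (the
operator is defined on an arbitrary incidence matrix); the default here
is one size-2 hyperedge per bond with unit weight — the molecular graph
itself as a degenerate hypergraph, which keeps the variant comparable
to the others on identical input — with an opt-in "bond+ring" mode that
adds one hyperedge per smallest ring. Two hypergraph convolutions
X' = D⁻¹ H W B⁻¹ Hᵀ X Θ are followed by one plain graph convolution and
global max pooling. The row-normalized D⁻¹ form is the operator used;
the symmetric D^{-1/2}·…·D^{-1/2} normalization is available behind a
flag. Attention (on by default for this variant) replaces H by a
real-valued H̃: a hyperedge is represented by the mean of its incident
nodes' projected features, each (node, hyperedge) pair is scored by a
LeakyReLU (slope 0.2) of a learned linear form on the concatenated node
and hyperedge representations, and scores are softmax-normalized over
each node's incident hyperedges; D and B are recomputed from H̃. The
scoring function itself is a design choice of this package, following
the additive-attention convention of the hypergraph-attention
literature; structural zeros of H are preserved.

Zero-degree conventions make every forward total: an isolated node
receives a zero aggregated message (GEN) or a zero output row
(hypergraph, zero D_ii), and a bond-free molecule passes through GEN as
a row-wise MLP.

### Protein branch and head

Embedding (dim 128) → one 1-D convolution (32 filters, kernel 8,
implemented as a window-gather and matrix product) → ReLU → global max
over positions → linear projection → ReLU. The two branch embeddings
(128 each by default) are concatenated and passed through
fully-connected layers [1024, 512] with ReLU and dropout 0.2 to a
single output. Widths, kernel size and dropout are package defaults in
the style of the lineage this model family belongs to, not mandated
values; everything is exposed in `ModelConfig`.

## Numerical core

No deep-learning framework is used: `deepnc.autodiff` is a small
reverse-mode automatic-differentiation engine over float64 numpy
arrays, providing exactly the primitives the layers need (broadcasting
arithmetic, matmul, gather with scatter-add backward, segment
sum/max/softmax, channel-wise max with tie-splitting gradients,
dropout). Gradients are verified against central finite differences,
and every layer forward against a dense-matrix or double-loop oracle on
random graphs (n ≤ 12, tolerance 1e-6). Sub-gradient conventions: ReLU
and max take 0 at kinks resolved toward zero; ties in a max split the
gradient evenly; √x at 0 gets sub-gradient 0. The per-segment softmax
subtracts a detached per-segment maximum (the shift cancels in the
gradient), keeping large-β aggregation stable.

## Training and evaluation

Adam (standard moment coefficients) minimizes the MSE loss, learning
rate 5·10⁻⁴, batch 256, 1000 epochs by default — the published
settings; one source table also mentions batch 512, and both are
accepted through configuration, with 256 the default. Shuffling,
initialization (Glorot uniform) and dropout derive from one seed; runs
are reproducible on one device. Optional validation (a seeded 80/20
split of the training set, or the dataset's stored folds) tracks
per-epoch validation MSE/CI and restores the best-validation
parameters; without validation the final epoch is kept, since the
reporting convention of the source results does not state which epoch
is used. Divergence (non-finite loss) aborts with the epoch named.
Checkpoints are single archives holding parameters, configuration and
the featurization schema, and round-trip bit-exactly.

Metrics: MSE; the concordance index over pairs with strictly different
true affinities (truth ties excluded from numerator and normalizer,
prediction ties scored 0.5 — so all-tied predictions give CI 0.5, and
all-tied labels make CI undefined and reported as absent); and
r²m = r²·(1 − √|r² − r₀²|) with r² the squared Pearson correlation and
r₀² from the least-squares fit through the origin. The r²m formula is
the standard QSAR external-validation definition, adopted because the
metric is reported in this model family without a printed formula; the
one-direction (observed-vs-predicted) variant is implemented rather
than the bidirectional average.

Affinity scales: Davis-style K_d data in nM can be mapped opt-in to
pK_d = 9 − log10(K_d/nM); the 10 μM assay cap maps to 5.0, the lower
end of the familiar 5.0–10.8 range. Kiba scores and flat tables load
untransformed by default.

## Synthetic data

The generator emulates the shape of affinity benchmarks, not their
physics. Molecules come from a seeded grammar of branched
alkane/heteroatom chains and benzene scaffolds (1–20 heavy atoms, all
RDKit-parseable); proteins are uniform random sequences (default length
50–200); affinity is c₀ + c₁·(heavy atoms) + c₂·(aromatic fraction) +
c₃·(hydrophobic residue fraction) + N(0, σ), default coefficients
(4.0, 0.25, 1.0, 2.0) and σ = 0.3, chosen once to land affinities in
the 5–11 pK_d-like range with the molecular term dominating the
signal. The deterministic part is exposed for recovery tests. Passing
tests on this data demonstrates that the architecture can extract
size-, aromaticity- and composition-like signals end-to-end from raw
SMILES and sequences; it says nothing about real binding physics,
activity cliffs, scaffold generalization or assay noise structure.
Writers for both on-disk dialects (benchmark directory with fold lists;
flat CSV) exercise both loaders.

## Problem sizes

Tests and the acceptance script run desk-scale by choice: oracle checks
on graphs of ≤ 12 nodes; capacity checks on 16 noise-free pairs (MSE
< 0.05); generalization checks on 200 pairs (160/40 split, 150 epochs,
32-wide layers, protein length cap 220), where both variants reach
held-out CI ≈ 0.9 and MSE ≈ 0.1 against a label variance of ≈ 1.5.
Full-scale benchmark training (10⁵ pairs, 1000 epochs) uses the same
code paths with the default configuration.

## Known limitations

No bond/edge features, stereochemistry, 3-D conformers or charged-
species normalization in featurization; no GAT/GIN baselines; no
multi-device or mini-batch-parallel training; the dense float64 numpy
core favors exactness and testability over speed and is roughly an
order of magnitude slower than a GPU framework at large scale; the
hypergraph attention scoring and the hyperedge construction are
documented package choices where the source construction is silent.
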