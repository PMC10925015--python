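# Methods

`edgecdr` regresses the natural-log half-maximal inhibitory concentration
(ln IC50) of a drug against a cancer cell line from two complementary drug
representations and four omics layers. This note records the model, the
choices made where the design was genuinely open, the synthetic study
conditions, and what the tests do and do not demonstrate.

## Model

**Drug graph encoder.** A drug is a heavy-atom graph: node features
`V ∈ R^{N×C_node}` (one-hot element over {C,N,O,S,F,Cl,Br,I,P,other},
one-hot degree 0–5, aromatic flag, ring flag, formal charge; C_node = 19)
and an edge-channel adjacency tensor `A ∈ R^{N×N×C_edge}` with C_edge = 6
channels: one-hot bond order (single/double/triple/aromatic) plus
conjugation and ring flags. Hydrogens are implicit; aromatic perception is
RDKit's default model, without kekulization. Each layer slices `A` into
per-channel adjacency matrices `E_k` and computes messages
`M_k = σ(E_k V W_k + b_k)`, summed over channels. The layer's update
functions are learnable single-layer combines:
`V' = σ(W_n [V ‖ ΣM_k] + b_n)` for nodes and
`E'_ij = σ(W_e [E_ij ‖ e_ij] + b_e)` for edges, where the relation vector is
`e_ij = σ((V'_i ‖ V'_j) W_r + b_r)`, with `W_r` shared across all pairs
(a per-pair weight would not transfer across molecules of different size).
Because the concatenation is order-dependent while chemical bonds are
undirected, relations are symmetrized, `e_ij ← (e_ij + e_ji)/2`, which
preserves the edge tensor's symmetry invariant exactly. Non-bonded pairs are
masked to zero throughout. The network has two layers; only the first
updates edges. How the updated edge embeddings feed the second layer is an
open design point: here a learned linear map projects the layer-1 edge
embeddings back to C_edge scalar channels, which the second layer consumes
as its adjacency channels. Readout is mean-pool ‖ max-pool over nodes
followed by a linear map — symmetric by construction, which is what the
atom-relabeling invariance test exercises. σ is ReLU (configurable).

**Substructure tokenizer and transformer encoder.** SMILES strings are
split into single characters and a byte-pair-style vocabulary is grown by
repeatedly merging the most frequent adjacent token pair, until the best
pair's corpus frequency falls below μ (default 2) or the vocabulary reaches
δ tokens (default 2000). Pair counting is per adjacent occurrence,
non-overlapping left-to-right within a string; frequency ties break
lexicographically on (left, right) so the merge list is byte-stable.
Tokenization replays the recorded merges in order, which makes it lossless
before truncation; sequences are truncated/padded to ζ = 64 positions (a
truncation is logged). Raw characters, not chemical atoms, form the base
alphabet: multi-character element symbols such as `Cl` are learned as
merges. A token sequence is embedded as token embedding + position
embedding, then passed through 2 blocks of multi-head scaled dot-product
self-attention (4 heads, model width 128) and a position-wise feed-forward
net, each wrapped in residual connection + layer normalization (the usual
encoder block; without them the stack does not train). Attention scores are
scaled by √d_head (= √(d/n_heads)), the standard multi-head choice. Padded
key positions receive −1e9 scores pre-softmax, and pooling is a masked mean
over real tokens, so padding provably never leaks into the embedding.

**Omics encoder.** Each cell line contributes four gene-aligned vectors:
expression (log2(TPM+1), quantile-normalized across cell lines), per-gene
mutation counts (binary site indicators summed per gene), promoter
methylation level, and copy number. Missing entries are imputed by the
per-gene mean across cell lines. Quantile normalization is rank-based with
stable sorting, hence deterministic and idempotent. Four independent fully
connected towers (n_genes → 256 → 100 → d, ReLU) embed the layers, and a
single-query additive attention `a = softmax(wᵀ tanh(U y_m))` assigns four
nonnegative weights summing to one; the fused gene embedding is the weighted
sum. The additive form is the simplest mechanism that yields per-layer
contribution weights; the exact form of this attention was an open design
choice.

**Fusion head and training.** The graph, sequence and omics embeddings
(100 each by default) are concatenated and read as a one-channel 1D signal
by two convolution blocks (channels 40→10, kernel 5, max-pool 2), then a
dense layer (128) to a scalar. Training minimizes mean squared error with
AdamW at learning rate 1e-3 and batch size 256. Epoch count defaults to 100
with early stopping on validation RMSE (patience 10) when a VALID split is
present. Augmentation (below) is applied before training and a leakage
guard re-checks every epoch. All parameters are float64; runs are exactly
reproducible given a seed, and checkpoints (npz arrays + JSON metadata)
round-trip bitwise.

**SMILES enumeration augmentation.** Alternative renderings of a training
drug are produced by renumbering the atoms randomly and emitting a
non-canonical SMILES rooted at a random atom, retrying up to 10 times to
avoid string collisions; every variant must canonicalize back to the
parent's canonical form. A factor-f augmentation adds f−1 virtual drugs per
training record, each paired with the original cell line and ln IC50.
Augmentation is restricted to TRAIN records; virtual drugs keep a pointer to
their parent so per-drug evaluation groups variants with the parent and
VALID/TEST can be proven free of augmentation-created pairs.

**Gradient-sum attribution.** For a pair (drug, cell line), the scalar
prediction is differentiated with respect to the four omics input vectors at
the observed point (no baseline or path integration; mutation counts are
treated as continuous), and gene i's score is
`GradSum_i = |∂y/∂exp_i| + |∂y/∂met_i| + |∂y/∂mut_i| + |∂y/∂copy_i|`.
No per-layer normalization precedes the sum. Genes are ranked by GradSum
descending with lexicographic tie-breaks.

## Numerical engine

All neural components run on a small reverse-mode automatic differentiation
engine over NumPy float64 arrays written for this package
(`edgecdr/autodiff.py`), with AdamW implemented on top. Every primitive's
gradient is tested against central finite differences, and attribution
gradients are additionally checked against finite differences through the
whole model.

## Synthetic study conditions

The fixture generator emulates the three real input tables with a known
generative rule:

    ln IC50(d, c) = α · exp[g*, c] + β · z(d) + ε,   ε ~ N(0, σ²)

with a planted causal gene g*, a structural covariate z(d) = heavy-atom
count / 10, and defaults α = 1, β = 0.5, σ = 0.1, 20 drugs × 50 cell lines
× 100 genes. Drugs are drawn from a fixed pool of 64 valid, distinct
drug-like SMILES. Omics layers are exp ~ N(0,1) (treated as already
log-scale; the log2 transform is skipped for synthetic data),
mut ~ Poisson(0.3), meth ~ U(0,1), copy ~ N(2, 0.5), with 2% of entries
masked to exercise mean imputation. Missing-response masks use exact counts
(`round(fraction · n_drugs · n_cells)`), so grid bookkeeping is
deterministic. These distributions exercise the code paths; they do not
mimic the marginal distributions of real pharmacogenomic databases, so
passing tests demonstrate mechanical and statistical correctness of the
pipeline, not transferability to real screens.

## Problem sizes and protocols used in tests

Tests and the acceptance script use a narrow configuration
(`TrainConfig.small`: widths 32, 1–2 layer encoders, small head) and small
studies — 50-pair memorization (5 drugs × 10 cells), an 80/20 train/test
study of 10 drugs × 60 cells × 50 genes, and the recovery experiment below —
chosen as the smallest sizes at which each property is informative.

**Planted-gene recovery.** The attribution experiment uses 6 drugs × 200
cell lines × 100 genes (α = 1, σ = 0.1), 100 epochs, weight decay 1e-3, and
scores genes by GradSum averaged over 10 cell lines for one drug. Two
findings shaped this protocol. First, with few cell lines (≲100) any
sufficiently flexible model can fit responses by memorizing cell-line
fingerprints rather than the causal gene, and attribution legitimately
fails; ~200 cell lines make the planted rule the easier solution. Second,
single-pair local gradients of a ReLU network are noisy (the planted gene's
single-pair rank varied from 1 to ~40 across cells even when the averaged
ranking was 1), so the recovery criterion is evaluated on the 10-cell
average, which is the natural estimator of which genes the model relies on.
Per-pair reports remain available and are what the CLI emits.

## Known limitations

- CPU-only, float64, and deliberately small: the engine favours clarity and
  exact reproducibility over throughput; real-database scale (hundreds of
  drugs × hundreds of cell lines × deep widths) is out of reach.
- The tokenizer is purely character-statistical: ring-closure digits and
  bracket atoms are not treated atomically beyond what merging learns.
- Stereochemistry, 3D geometry and charge-distribution descriptors are not
  represented.
- Attribution is a local gradient at one input point; it identifies
  influential inputs of the fitted model, not causal biology.
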