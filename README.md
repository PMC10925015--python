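# edgecdr

Predicting how strongly a drug inhibits a cancer cell line — the natural-log
half-maximal inhibitory concentration, ln IC50 — from the drug's molecular
structure and the cell line's multi-omics profile. The package is aimed at
computational pharmacogenomics work: screening-panel style data (a drug
table of SMILES strings, four genes × cell-lines omics matrices, a response
table of measured ln IC50 values) goes in; a trained regressor, held-out
metrics, imputed values for unmeasured drug–cell pairs, and per-gene
attribution scores come out. A synthetic-data module generates all three
inputs with a known planted rule, so the whole pipeline runs and is testable
offline.

## Model

Three encoders feed one regression head:

- **Graph encoder with edge co-update.** A drug is a heavy-atom graph
  `(V, A)` with node features `V ∈ R^{N×C_node}` and an edge-channel
  adjacency tensor `A ∈ R^{N×N×C_edge}` (one-hot bond order + conjugation
  and ring flags). Each layer passes messages per channel,
  `M_k = σ(E_k V W_k + b_k)`, and — in the first layer — collaboratively
  updates edge embeddings from the adjacent node pair:
  `e_ij = σ((V_i ‖ V_j) W + b)`, symmetrized, then
  `E'_ij = Update(E_ij, e_ij)`. A symmetric mean/max readout yields the
  graph embedding, invariant to atom relabeling.
- **Substructure transformer.** SMILES are decomposed by a frequency-driven
  pair-merging vocabulary (byte-pair-encoding style, thresholds μ and δ);
  token + position embeddings pass through multi-head self-attention
  `Z = softmax(QKᵀ/√d) V` and a position-wise feed-forward network, with
  masked mean pooling.
- **Omics fusion.** Expression (log2 TPM, quantile-normalized), per-gene
  mutation counts, promoter methylation and copy number are embedded by four
  independent fully connected subnetworks; additive attention assigns four
  contribution weights (nonnegative, summing to 1) and mixes them.

The concatenated embeddings are regressed to ln IC50 through a 1D-conv
head, trained with AdamW (learning rate 1e-3, batch 256) under mean squared
error. Training-set SMILES can be augmented by enumeration: alternative
renderings of the same molecule, each re-paired with the parent's genomic
data; validation/test sets are provably untouched. For a trained model,
`GradSum_i = Σ_layers |∂y/∂x_{layer,i}|` ranks genes by their influence on
one prediction.

See `docs/methods.md` for design details, synthetic study conditions, and
limitations. Everything neural runs on a small NumPy reverse-mode autodiff
engine included in the package (`edgecdr.autodiff`); no deep-learning
framework is required.

## Worked example

```python
import numpy as np
import edgecdr as e

spec = e.FixtureSpec(n_drugs=6, n_cells=200, n_genes=100, seed=7)
drugs, omics, records, truth = e.make_dataset(spec)
profiles = e.preprocess_omics(omics["exp"], omics["mut"], omics["meth"],
                              omics["copy"], log_transform_exp=False)
records = e.split_dataset(records, "random", 0.8, seed=7)
cfg = e.TrainConfig.small(epochs=100, seed=7, batch_size=256, weight_decay=1e-3)
result = e.train(records, drugs, profiles, cfg)

test = [r for r in records if r.split == e.TEST]
preds = result.model.predict([(r.drug_id, r.cell_line_id) for r in test], profiles)
m = e.evaluate(preds, np.array([r.ln_ic50 for r in test]))
print(f"test RMSE={m.rmse:.3f}  PCC={m.pcc:.3f}  SCC={m.scc:.3f}  (n={m.n})")

total = np.zeros(spec.n_genes)
for cell in sorted(profiles)[:10]:
    total += e.grad_sum(result.model, "D000", profiles[cell])
top = e.top_genes(total, profiles["c000"].gene_ids, 5)
print("top-5 genes by mean GradSum over 10 cells:", ", ".join(top))
print("planted causal gene:", truth["planted_gene"])
```

prints

```
test RMSE=0.131  PCC=0.992  SCC=0.990  (n=240)
top-5 genes by mean GradSum over 10 cells: g045, g000, g066, g075, g034
planted causal gene: g000
```

The synthetic responses follow `ln IC50 = exp[g*, c] + 0.5·z(d) + ε` with
planted gene `g* = g000` and noise sd 0.1: held-out RMSE of 0.131
approaches the noise floor, the correlations show the model captures both
the genomic and the structural effect, and the planted causal gene surfaces
near the top of the attribution ranking.

The same workflow is available from a shell:

```bash
edgecdr make-fixtures --seed 7 --out-dir fx/
edgecdr train --drugs fx/drugs.csv --omics-dir fx/omics --responses fx/responses.csv \
              --no-log-exp --seed 7 --out model.ckpt
edgecdr predict --model model.ckpt --pairs pairs.csv --omics-dir fx/omics \
                --no-log-exp --out pred.csv
edgecdr attribute --model model.ckpt --drug D000 --cell c000 \
                  --omics-dir fx/omics --no-log-exp --top-k 5 --out report.csv
```

plus `augment`, `evaluate` and `impute-missing` subcommands.

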