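"""Gradient-sum gene attribution for a trained model.

For one drug–cell-line pair the scalar prediction
``y = g(f_exp(exp), f_met(met), f_mut(mut), f_copy(copy), f_drug(drug))``
is differentiated with respect to each of the four omics input vectors at
the observed input point, and each gene's score is the sum of the absolute
partials across the four layers:

    GradSum_i = |∂y/∂exp_i| + |∂y/∂met_i| + |∂y/∂mut_i| + |∂y/∂copy_i|

Genes are ranked by GradSum descending (ties broken by gene id), so the
first entry realizes argmax_i GradSum_i.  Mutation counts are treated as
continuous for differentiation; no per-layer normalization is applied.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .model import DrugResponseModel
from .omics import OMICS_LAYERS, OmicsProfile

__all__ = ["AttributionReport", "grad_sum", "top_genes", "attribute_pair"]


@dataclass
class AttributionReport:
    drug_id: str
    cell_line_id: str
    grad_sum: np.ndarray          # (n_genes,), nonnegative
    ranked_genes: list[str]       # permutation of gene ids, best first
    top_k: int

    @property
    def top(self) -> list[str]:
        return self.ranked_genes[:self.top_k]

    def write_csv(self, path: str | Path) -> None:
        scores_desc = np.sort(self.grad_sum)[::-1]
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["gene_id", "grad_sum", "rank"])
            for rank, (g, s) in enumerate(zip(self.ranked_genes, scores_desc),
                                          start=1):
                w.writerow([g, repr(float(s)), rank])


def grad_sum(model: DrugResponseModel, drug_id: str,
             profile: OmicsProfile) -> np.ndarray:
    """Per-gene sum of absolute input gradients for one pair."""
    inputs = {name: Tensor(profile.layer(name)[None, :].astype(float),
                           requires_grad=True)
              for name in OMICS_LAYERS}
    y = model.forward_batch([(drug_id, profile.cell_line_id)],
                            omics_inputs=inputs)
    y.backward(np.ones_like(y.data))
    total = np.zeros(profile.n_genes)
    for name in OMICS_LAYERS:
        g = inputs[name].grad
        total += np.abs(g[0]) if g is not None else 0.0
    return total


def top_genes(scores: np.ndarray, gene_ids: list[str], k: int) -> list[str]:
    """Gene ids sorted by score descending, ties by id; first k returned."""
    if k < 1:
        raise ValueError("k must be >= 1")
    order = sorted(range(len(gene_ids)), key=lambda i: (-scores[i], gene_ids[i]))
    return [gene_ids[i] for i in order[:k]]


def attribute_pair(model: DrugResponseModel, drug_id: str,
                   profile: OmicsProfile, top_k: int = 5) -> AttributionReport:
    scores = grad_sum(model, drug_id, profile)
    full_order = top_genes(scores, profile.gene_ids, k=len(profile.gene_ids))
    return AttributionReport(drug_id=drug_id,
                             cell_line_id=profile.cell_line_id,
                             grad_sum=scores, ranked_genes=full_order,
                             top_k=min(top_k, profile.n_genes))
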