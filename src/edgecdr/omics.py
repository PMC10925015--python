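"""Multi-omics preprocessing and attention-fused encoding of cell lines.

Each cancer cell line is characterized by four gene-indexed vectors —
expression (log2(TPM+1), quantile-normalized across cell lines), mutation
(per-gene count of binary site indicators), promoter methylation level, and
copy number.  Missing entries are imputed with the per-gene mean across cell
lines.  Four independent fully connected subnetworks embed the vectors, and
a single-query additive attention assigns nonnegative contribution weights
(summing to one) that mix them into the fused gene embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autodiff import Tensor, concat
from .errors import EmptyIntersectionError, ShapeError
from .nn import Linear, Module, glorot, zeros

OMICS_LAYERS = ("exp", "mut", "meth", "copy")


@dataclass
class OmicsProfile:
    """Per-cell-line quadruple of gene-aligned omics vectors."""
    cell_line_id: str
    gene_ids: list[str]
    exp: np.ndarray
    mut: np.ndarray
    meth: np.ndarray
    copy: np.ndarray

    def layer(self, name: str) -> np.ndarray:
        return getattr(self, name)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class FusedGeneEmbedding:
    y_exp: np.ndarray
    y_met: np.ndarray
    y_mut: np.ndarray
    y_copy: np.ndarray
    attention_weights: np.ndarray  # (4,), nonnegative, sums to 1
    x_gene: np.ndarray             # (d,), the attention-weighted sum


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Force every column (cell line) to share the mean sorted profile.

    Rank-based: column values are replaced by the across-column mean of the
    order statistics; stable argsort makes ties deterministic.  Idempotent.
    """
    ranks = np.argsort(matrix, axis=0, kind="stable")
    reference = np.sort(matrix, axis=0).mean(axis=1)
    out = np.empty_like(matrix, dtype=float)
    for j in range(matrix.shape[1]):
        out[ranks[:, j], j] = reference
    return out


def mean_impute(matrix: np.ndarray) -> np.ndarray:
    """Replace NaNs with the per-gene (row) mean across cell lines."""
    out = matrix.astype(float).copy()
    row_mean = np.nanmean(np.where(np.isnan(out), np.nan, out), axis=1)
    row_mean = np.nan_to_num(row_mean)  # all-NaN rows fall back to 0
    nan_r, nan_c = np.nonzero(np.isnan(out))
    out[nan_r, nan_c] = row_mean[nan_r]
    return out


def preprocess_omics(
    exp: pd.DataFrame, mut: pd.DataFrame, meth: pd.DataFrame,
    copy: pd.DataFrame, gene_list: list[str] | None = None,
    log_transform_exp: bool = True,
) -> dict[str, OmicsProfile]:
    """Align four genes × cell-lines matrices and build per-cell profiles.

    ``mut`` may carry multiple rows per gene (binary site indicators); they
    are summed into a per-gene mutation count.  Expression is log2(TPM+1)
    transformed (unless already transformed) and quantile-normalized across
    cell lines.  NaNs in every layer are mean-imputed per gene.
    """
    mut = mut.groupby(level=0).sum(min_count=1)  # site rows → per-gene count
    genes = exp.index.intersection(mut.index).intersection(
        meth.index).intersection(copy.index)
    if gene_list is not None:
        genes = genes.intersection(pd.Index(gene_list))
    cells = exp.columns.intersection(mut.columns).intersection(
        meth.columns).intersection(copy.columns)
    if len(genes) == 0:
        raise EmptyIntersectionError("no genes shared across omics matrices")
    if len(cells) == 0:
        raise EmptyIntersectionError("no cell lines shared across omics matrices")
    genes = sorted(genes)
    cells = sorted(cells)

    e = mean_impute(exp.loc[genes, cells].to_numpy(dtype=float))
    if log_transform_exp:
        e = np.log2(e + 1.0)
    e = quantile_normalize(e)
    m = mean_impute(mut.loc[genes, cells].to_numpy(dtype=float))
    me = mean_impute(meth.loc[genes, cells].to_numpy(dtype=float))
    cp = mean_impute(copy.loc[genes, cells].to_numpy(dtype=float))

    return {
        cell: OmicsProfile(cell_line_id=cell, gene_ids=list(genes),
                           exp=e[:, j], mut=m[:, j], meth=me[:, j],
                           copy=cp[:, j])
        for j, cell in enumerate(cells)
    }


def read_omics_dir(path) -> dict[str, pd.DataFrame]:
    """Read {exp,mut,meth,copy}.csv matrices (rows=genes, cols=cell lines)."""
    from pathlib import Path
    path = Path(path)
    return {name: pd.read_csv(path / f"{name}.csv", index_col=0)
            for name in OMICS_LAYERS}


def read_gene_list(path) -> list[str]:
    return [ln.strip() for ln in open(path) if ln.strip()]


@dataclass(frozen=True)
class OmicsEncoderConfig:
    n_genes: int
    hidden: tuple[int, int] = (256, 100)
    d: int = 100              # fused embedding width
    d_att: int = 32           # additive-attention scorer width


class OmicsSubnet(Module):
    """Fully connected tower for one omics layer: n_genes → hidden → d."""

    def __init__(self, cfg: OmicsEncoderConfig, rng: np.random.Generator):
        h1, h2 = cfg.hidden
        self.l1 = Linear(cfg.n_genes, h1, rng)
        self.l2 = Linear(h1, h2, rng)
        self.l3 = Linear(h2, cfg.d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.l3(self.l2(self.l1(x).relu()).relu())


class OmicsEncoder(Module):
    """Four independent subnetworks fused by single-query additive attention."""

    def __init__(self, config: OmicsEncoderConfig, rng: np.random.Generator):
        self.config = config
        self.subnets = [OmicsSubnet(config, rng) for _ in OMICS_LAYERS]
        self.U = glorot(rng, config.d, config.d_att)
        self.w = glorot(rng, config.d_att, 1)

    def encode_batch(self, inputs: dict[str, Tensor]) -> tuple[Tensor, Tensor]:
        """Encode a batch of profiles.

        ``inputs`` maps each omics layer name to a (B, n_genes) tensor.
        Returns (fused (B, d), attention weights (B, 4)).
        """
        cfg = self.config
        ys = []
        for name, net in zip(OMICS_LAYERS, self.subnets):
            x = inputs[name]
            if x.shape[-1] != cfg.n_genes:
                raise ShapeError(f"{name} has {x.shape[-1]} genes, "
                                 f"encoder expects {cfg.n_genes}")
            ys.append(net(x))                                 # (B, d)
        scores = concat(
            [(y @ self.U).tanh() @ self.w for y in ys], axis=1)  # (B, 4)
        weights = scores.softmax(axis=1)
        fused = None
        for m, y in enumerate(ys):
            term = y * weights[:, m:m + 1]
            fused = term if fused is None else fused + term
        return fused, weights

    def encode(self, profile: OmicsProfile) -> FusedGeneEmbedding:
        """Encode one profile, exposing the per-layer embeddings and weights."""
        inputs = {name: Tensor(profile.layer(name)[None, :])
                  for name in OMICS_LAYERS}
        ys = [net(inputs[name]) for name, net in zip(OMICS_LAYERS, self.subnets)]
        scores = concat([(y @ self.U).tanh() @ self.w for y in ys], axis=1)
        weights = scores.softmax(axis=1)
        fused = ys[0] * weights[:, 0:1]
        for m in range(1, 4):
            fused = fused + ys[m] * weights[:, m:m + 1]
        return FusedGeneEmbedding(
            y_exp=ys[0].data[0], y_mut=ys[1].data[0], y_met=ys[2].data[0],
            y_copy=ys[3].data[0], attention_weights=weights.data[0],
            x_gene=fused.data[0])
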