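"""End-to-end drug-response regressor: fusion, training, evaluation, imputation.

The drug-graph embedding, the drug-sequence embedding and the fused omics
embedding are concatenated and treated as a one-channel 1D signal by a small
convolutional head that regresses ln IC50.  Training minimizes mean squared
error with AdamW; evaluation reports RMSE and Pearson/Spearman correlations;
imputation predicts every unobserved drug–cell-line pair and ranks drugs by
mean predicted response (ascending ln IC50 = most sensitive first).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .autodiff import AdamW, Tensor, concat
from .augment import augment_training_set, check_no_leakage
from .cgcn import CgcnConfig, CgcnEncoder
from .drug_graph import FeatureSchema, graph_from_smiles
from .errors import (DataError, DegenerateInputError, InfeasibleSplitError,
                     ShapeError)
from .espf import EspfVocab, build_vocab, tokenize
from .nn import Linear, Module, glorot, zeros
from .omics import OMICS_LAYERS, OmicsEncoder, OmicsEncoderConfig, OmicsProfile
from .records import TEST, TRAIN, VALID, ResponseRecord
from .seq_encoder import SeqEncoder, SeqEncoderConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization recipe plus the architecture widths.

    The optimizer settings follow the published recipe (AdamW, learning rate
    1e-3, batch size 256, MSE loss); architecture widths are configurable and
    default to CPU-friendly values.
    """
    learning_rate: float = 1e-3
    batch_size: int = 256
    epochs: int = 100
    weight_decay: float = 1e-4
    seed: int = 0
    augment_factor: int = 1
    early_stop_patience: int = 10
    # tokenizer
    mu: int = 2
    delta: int = 2000
    zeta: int = 64
    # graph encoder
    d_node: int = 75
    d_edge: int = 32
    d_graph: int = 100
    # sequence encoder
    d_model: int = 128
    n_heads: int = 4
    n_seq_layers: int = 2
    d_ff: int = 256
    d_seq: int = 100
    # omics encoder
    omics_hidden: tuple[int, int] = (256, 100)
    d_omics: int = 100
    d_att: int = 32
    # head
    conv_channels: tuple[int, int] = (40, 10)
    kernel_size: int = 5
    pool_size: int = 2
    dense_size: int = 128

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    @classmethod
    def small(cls, **overrides) -> "TrainConfig":
        """A narrow configuration for quick desk-scale experiments."""
        base = dict(d_node=32, d_edge=16, d_graph=32, d_model=32, n_heads=2,
                    n_seq_layers=1, d_ff=64, d_seq=32,
                    omics_hidden=(64, 32), d_omics=32, d_att=16,
                    conv_channels=(8, 4), dense_size=32)
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class Metrics:
    rmse: float
    pcc: float
    scc: float
    n: int


class ConvHead(Module):
    """1D-conv regression head over the concatenated embedding."""

    def __init__(self, input_len: int, cfg: TrainConfig, rng: np.random.Generator):
        c1, c2 = cfg.conv_channels
        k, p = cfg.kernel_size, cfg.pool_size
        self.conv1_w = glorot(rng, c1, 1, k)
        self.conv1_b = zeros(c1)
        self.conv2_w = glorot(rng, c2, c1, k)
        self.conv2_b = zeros(c2)
        l1 = (input_len - k + 1) // p
        l2 = (l1 - k + 1) // p
        if l2 < 1:
            raise ShapeError(f"embedding length {input_len} too short for head")
        self.flat = c2 * l2
        self.dense1 = Linear(self.flat, cfg.dense_size, rng)
        self.dense2 = Linear(cfg.dense_size, 1, rng)
        self.pool = p

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, L) concatenated embeddings → (B, 1) predictions."""
        B, L = x.shape
        h = x.reshape(B, 1, L)
        h = h.conv1d(self.conv1_w, self.conv1_b).relu().maxpool1d(self.pool)
        h = h.conv1d(self.conv2_w, self.conv2_b).relu().maxpool1d(self.pool)
        h = h.reshape(B, self.flat)
        return self.dense2(self.dense1(h).relu())


class DrugResponseModel(Module):
    """All encoders plus the head, with per-drug featurization caches."""

    def __init__(self, config: TrainConfig, vocab: EspfVocab,
                 schema: FeatureSchema, gene_ids: list[str],
                 rng: np.random.Generator):
        cfg = config
        self.config = cfg
        self.vocab = vocab
        self.schema = schema
        self.gene_ids = list(gene_ids)
        self.cgcn = CgcnEncoder(CgcnConfig(
            c_node=schema.n_node_features, c_edge=schema.n_edge_channels,
            d_node=cfg.d_node, d_edge=cfg.d_edge, d_graph=cfg.d_graph), rng)
        self.seq = SeqEncoder(SeqEncoderConfig(
            vocab_size=len(vocab.tokens), zeta=cfg.zeta, d_model=cfg.d_model,
            n_heads=cfg.n_heads, n_layers=cfg.n_seq_layers, d_ff=cfg.d_ff,
            d_seq=cfg.d_seq), rng)
        self.omics_enc = OmicsEncoder(OmicsEncoderConfig(
            n_genes=len(gene_ids), hidden=cfg.omics_hidden, d=cfg.d_omics,
            d_att=cfg.d_att), rng)
        self.head = ConvHead(cfg.d_graph + cfg.d_seq + cfg.d_omics, cfg, rng)
        self._graphs: dict[str, object] = {}
        self._seqs: dict[str, object] = {}

    # -- featurization caches ---------------------------------------------

    def register_drugs(self, drug_table: dict[str, str]) -> None:
        for drug_id, smiles in drug_table.items():
            if drug_id not in self._graphs:
                self._graphs[drug_id] = graph_from_smiles(smiles, self.schema)
                self._seqs[drug_id] = tokenize(smiles, self.vocab,
                                               self.config.zeta)

    # -- forward ----------------------------------------------------------

    def drug_embedding(self, drug_id: str) -> Tensor:
        """(1, d_graph + d_seq) concatenation of both drug encoders."""
        if drug_id not in self._graphs:
            raise DataError(f"drug {drug_id!r} not registered")
        g = self.cgcn.encode(self._graphs[drug_id])
        s = self.seq.encode(self._seqs[drug_id])
        return concat([g, s], axis=1)

    def forward_batch(self, pairs: list[tuple[str, str]],
                      omics_inputs: dict[str, Tensor] | None = None,
                      profiles: dict[str, OmicsProfile] | None = None) -> Tensor:
        """Predict ln IC50 for a batch of (drug_id, cell_line_id) pairs.

        Omics inputs may be given directly as (B, n_genes) tensors (used by
        the attribution module to differentiate w.r.t. them) or gathered
        from ``profiles``.
        """
        uniq = sorted({d for d, _ in pairs})
        demb = {d: self.drug_embedding(d) for d in uniq}
        drug_mat = concat([demb[d] for d, _ in pairs], axis=0)
        if omics_inputs is None:
            missing = [c for _, c in pairs if c not in profiles]
            if missing:
                raise DataError(f"no omics profile for cell lines {missing[:5]}")
            omics_inputs = {
                name: Tensor(np.stack([profiles[c].layer(name)
                                       for _, c in pairs]))
                for name in OMICS_LAYERS}
        fused, _ = self.omics_enc.encode_batch(omics_inputs)
        return self.head(concat([drug_mat, fused], axis=1))

    def predict(self, pairs: list[tuple[str, str]],
                profiles: dict[str, OmicsProfile],
                batch_size: int = 256) -> np.ndarray:
        out = []
        for lo in range(0, len(pairs), batch_size):
            chunk = pairs[lo:lo + batch_size]
            out.append(self.forward_batch(chunk, profiles=profiles).data[:, 0])
        return np.concatenate(out) if out else np.array([])


def fuse_and_predict(graph_emb, seq_emb, gene_emb, head: ConvHead) -> float:
    """Scalar prediction from the three embeddings through the conv head."""
    row = np.concatenate([np.asarray(graph_emb).ravel(),
                          np.asarray(seq_emb).ravel(),
                          np.asarray(gene_emb).ravel()])[None, :]
    return float(head(Tensor(row)).data[0, 0])


# -- dataset splitting ----------------------------------------------------

def split_dataset(records: list[ResponseRecord], mode: str = "random",
                  fraction: float = 0.8, seed: int = 0,
                  valid_fraction: float = 0.0) -> list[ResponseRecord]:
    """Label records TRAIN/TEST (and optionally VALID, carved from TRAIN).

    ``random`` splits per record; ``drug_blind`` / ``cell_blind`` keep every
    drug (cell line) on one side only.  Blind splits that cannot reach the
    requested fraction within ±5 percentage points raise
    :class:`InfeasibleSplitError`.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(records)
    if mode == "random":
        order = rng.permutation(n)
        n_train = round(fraction * n)
        train_idx = set(order[:n_train].tolist())
        labeled = [r.with_split(TRAIN if i in train_idx else TEST)
                   for i, r in enumerate(records)]
    elif mode in ("drug_blind", "cell_blind"):
        key = (lambda r: r.parent) if mode == "drug_blind" \
            else (lambda r: r.cell_line_id)
        groups: dict[str, int] = {}
        for r in records:
            groups[key(r)] = groups.get(key(r), 0) + 1
        names = list(groups)
        rng.shuffle(names)
        target = fraction * n
        train_groups, acc = set(), 0
        for name in names:
            if acc >= target:
                break
            train_groups.add(name)
            acc += groups[name]
        if abs(acc - target) > 0.05 * n:
            raise InfeasibleSplitError(
                f"{mode} split reaches {acc/n:.3f}, requested {fraction:.3f}")
        labeled = [r.with_split(TRAIN if key(r) in train_groups else TEST)
                   for r in records]
    else:
        raise ValueError(f"unknown split mode {mode!r}")

    if valid_fraction > 0:
        train_pos = [i for i, r in enumerate(labeled) if r.split == TRAIN]
        n_valid = round(valid_fraction * len(labeled))
        for i in rng.permutation(train_pos)[:n_valid]:
            labeled[i] = labeled[i].with_split(VALID)
    return labeled


# -- metrics --------------------------------------------------------------

def evaluate(predictions: np.ndarray, truth: np.ndarray) -> Metrics:
    """RMSE, Pearson and Spearman correlation of predictions vs. truth."""
    predictions = np.asarray(predictions, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predictions.shape != truth.shape or predictions.ndim != 1:
        raise ValueError("predictions and truth must be equal-length vectors")
    if len(truth) < 2:
        raise DegenerateInputError("need at least 2 points")
    if np.allclose(truth, truth[0]):
        raise DegenerateInputError("constant ground-truth vector")
    if np.allclose(predictions, predictions[0]):
        raise DegenerateInputError("constant prediction vector")
    rmse = float(np.sqrt(np.mean((predictions - truth) ** 2)))
    pcc = float(stats.pearsonr(predictions, truth).statistic)
    scc = float(stats.spearmanr(predictions, truth).statistic)
    return Metrics(rmse=rmse, pcc=pcc, scc=scc, n=len(truth))


# -- training -------------------------------------------------------------

@dataclass
class TrainResult:
    model: DrugResponseModel
    history: list[dict]
    drug_table: dict[str, str]


def train(records: list[ResponseRecord], drug_table: dict[str, str],
          profiles: dict[str, OmicsProfile], config: TrainConfig,
          verbose: bool = False) -> TrainResult:
    """Fit the full model by MSE/AdamW on the TRAIN split.

    Augmentation (``config.augment_factor`` > 1) expands only TRAIN records;
    a leakage guard re-checks every epoch that no augmentation-created
    record sits in VALID/TEST.  With a VALID split present, training stops
    early when validation RMSE has not improved for
    ``config.early_stop_patience`` epochs and the best parameters are kept.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    if cfg.augment_factor > 1:
        records, drug_table = augment_training_set(
            records, drug_table, cfg.augment_factor,
            seed=int(rng.integers(2 ** 31)))

    train_recs = [r for r in records if r.split == TRAIN]
    valid_recs = [r for r in records if r.split == VALID]
    if not train_recs:
        raise DataError("TRAIN split is empty")
    bad_drugs = sorted({r.drug_id for r in records} - set(drug_table))
    bad_cells = sorted({r.cell_line_id for r in records} - set(profiles))
    if bad_drugs or bad_cells:
        raise DataError(f"unresolvable references: drugs={bad_drugs[:5]} "
                        f"cells={bad_cells[:5]}")

    vocab = build_vocab(sorted(drug_table.values()), mu=cfg.mu, delta=cfg.delta)
    gene_ids = next(iter(profiles.values())).gene_ids
    model = DrugResponseModel(cfg, vocab, FeatureSchema(), gene_ids, rng)
    model.register_drugs(drug_table)
    logger.info("training: %d TRAIN / %d VALID records, %d drugs, seed %d",
                len(train_recs), len(valid_recs), len(drug_table), cfg.seed)

    opt = AdamW(model.parameters(), lr=cfg.learning_rate,
                weight_decay=cfg.weight_decay)
    history: list[dict] = []
    best_rmse, best_state, since_best = np.inf, None, 0

    for epoch in range(cfg.epochs):
        check_no_leakage(records)
        order = rng.permutation(len(train_recs))
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            batch = [train_recs[i] for i in order[lo:lo + cfg.batch_size]]
            pairs = [(r.drug_id, r.cell_line_id) for r in batch]
            y = np.array([[r.ln_ic50] for r in batch])
            pred = model.forward_batch(pairs, profiles=profiles)
            loss = ((pred - Tensor(y)) ** 2).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        entry = {"epoch": epoch, "train_mse": float(np.mean(losses))}
        if valid_recs:
            vp = model.predict([(r.drug_id, r.cell_line_id) for r in valid_recs],
                               profiles)
            vt = np.array([r.ln_ic50 for r in valid_recs])
            entry["valid_rmse"] = float(np.sqrt(np.mean((vp - vt) ** 2)))
        history.append(entry)
        if verbose or epoch % 10 == 0:
            logger.info("epoch %d: %s", epoch, entry)
        if valid_recs:
            if entry["valid_rmse"] < best_rmse - 1e-9:
                best_rmse = entry["valid_rmse"]
                best_state = {k: v.copy() for k, v in model.state_dict().items()}
                since_best = 0
            else:
                since_best += 1
                if since_best >= cfg.early_stop_patience:
                    logger.info("early stop at epoch %d", epoch)
                    break
    if best_state is not None:
        model.load_state_dict(best_state)
    return TrainResult(model=model, history=history, drug_table=dict(drug_table))


# -- missing-response imputation ------------------------------------------

def pair_bookkeeping(all_drugs: list[str], all_cells: list[str],
                     observed_pairs: set[tuple[str, str]]) -> dict:
    """Grid accounting: total, observed and missing pair counts."""
    total = len(all_drugs) * len(all_cells)
    n_obs = len(observed_pairs)
    missing = total - n_obs
    return {"total_pairs": total, "n_observed": n_obs, "n_missing": missing,
            "missing_percent": 100.0 * missing / total}


def predict_missing(model: DrugResponseModel, all_drugs: list[str],
                    all_cells: list[str],
                    observed_pairs: set[tuple[str, str]],
                    profiles: dict[str, OmicsProfile]):
    """Impute unobserved pairs and rank drugs by mean predicted ln IC50.

    Returns (imputed list of (drug, cell, prediction), ranking) where the
    ranking is a list of (drug_id, mean_prediction) sorted ascending — most
    sensitive (lowest predicted ln IC50) first.
    """
    missing = [(d, c) for d in all_drugs for c in all_cells
               if (d, c) not in observed_pairs]
    preds = model.predict(missing, profiles)
    imputed = [(d, c, float(p)) for (d, c), p in zip(missing, preds)]
    by_drug: dict[str, list[float]] = {}
    for d, _, p in imputed:
        by_drug.setdefault(d, []).append(p)
    ranking = sorted(((d, float(np.mean(v))) for d, v in by_drug.items()),
                     key=lambda t: (t[1], t[0]))
    return imputed, ranking


# -- checkpointing --------------------------------------------------------

def save_checkpoint(result: TrainResult, path: str | Path) -> None:
    """Serialize parameters + vocab + schema + config to one .npz file."""
    model = result.model
    meta = {
        "config": dataclasses.asdict(model.config),
        "vocab": {"merges": model.vocab.merges,
                  "alphabet": [t for t in model.vocab.tokens if len(t) == 1],
                  "mu": model.vocab.mu, "delta": model.vocab.delta},
        "schema": {"elements": list(model.schema.elements),
                   "other_bucket": model.schema.other_bucket,
                   "max_degree": model.schema.max_degree},
        "gene_ids": model.gene_ids,
        "drug_table": result.drug_table,
    }
    arrays = {f"param::{k}": v for k, v in model.state_dict().items()}
    with open(path, "wb") as fh:  # plain open avoids savez's suffix magic
        np.savez(fh, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> TrainResult:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k[len("param::"):]: data[k] for k in data.files
                 if k.startswith("param::")}
    cfg_d = meta["config"]
    for key in ("omics_hidden", "conv_channels"):
        cfg_d[key] = tuple(cfg_d[key])
    cfg = TrainConfig(**cfg_d)
    voc = meta["vocab"]
    merges = [tuple(m) for m in voc["merges"]]
    vocab = EspfVocab(tokens=list(voc["alphabet"]) + [a + b for a, b in merges],
                      merges=merges, mu=voc["mu"], delta=voc["delta"])
    schema = FeatureSchema(elements=tuple(meta["schema"]["elements"]),
                           other_bucket=meta["schema"]["other_bucket"],
                           max_degree=meta["schema"]["max_degree"])
    model = DrugResponseModel(cfg, vocab, schema, meta["gene_ids"],
                              np.random.default_rng(0))
    model.load_state_dict(state)
    model.register_drugs(meta["drug_table"])
    return TrainResult(model=model, history=[], drug_table=meta["drug_table"])
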