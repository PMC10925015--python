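"""Edge-collaborative graph convolutional drug encoder.

Each layer performs per-channel message passing over the edge-channel
adjacency matrices and, in the first layer only, collaboratively updates
edge embeddings from the adjacent node pair:

* node update: ``M_k = σ(E_k V W_k + b_k)`` per channel ``k``, messages
  summed over channels, then a learnable combine
  ``V' = σ(W_n [V || Σ_k M_k] + b_n)``;
* edge relation: ``e_ij = σ((V'_i || V'_j) W_ij + b_ij)``, symmetrized as
  ``(e_ij + e_ji) / 2`` since chemical bonds are undirected;
* edge update: ``E'_ij = σ(W_e [E_ij || e_ij] + b_e)`` on bonded pairs,
  zeros elsewhere.

The second layer consumes the layer-1 edge embeddings projected to scalar
channels by a learned linear map, runs the node update only, and a symmetric
readout (mean-pool ‖ max-pool, then linear) produces the drug embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .drug_graph import MolecularGraph
from .errors import ShapeError
from .nn import ACTIVATIONS, Module, glorot, zeros

__all__ = ["CgcnConfig", "CgcnLayerParams", "CgcnEncoder", "GraphState",
           "channel_decompose", "node_update", "edge_relation", "edge_update"]


@dataclass(frozen=True)
class CgcnConfig:
    c_node: int = 19          # input atom-feature width
    c_edge: int = 6           # input bond channels
    d_node: int = 75          # node embedding width per layer
    d_edge: int = 32          # edge embedding width after layer-1 update
    d_graph: int = 100        # readout embedding width
    n_layers: int = 2
    activation: str = "relu"


@dataclass
class GraphState:
    """Node and edge embeddings flowing between layers."""
    V: Tensor                  # (N, d)
    E: Tensor                  # (N, N, d_e); symmetric, zero off-bond
    bond_mask: np.ndarray      # (N, N) 0/1, zero diagonal
    layer_index: int = 0


class CgcnLayerParams(Module):
    """One layer's learnable parameters.

    ``W_k``/``b_k`` are the per-channel message weights; ``W_n``/``b_n`` the
    node combine; the relation weight ``W_ij`` is stored as its two stacked
    halves ``W_rel_a``/``W_rel_b`` (acting on V_i and V_j) and is shared
    across all pairs.  Edge parameters exist only when the layer updates
    edges.
    """

    def __init__(self, n_channels: int, d_in: int, d_out: int,
                 e_in: int, d_edge: int, activation: str,
                 edge_update_enabled: bool, rng: np.random.Generator):
        self.W_k = glorot(rng, n_channels, d_in, d_out)
        self.b_k = zeros(n_channels, d_out)
        self.W_n = glorot(rng, d_in + d_out, d_out)
        self.b_n = zeros(d_out)
        self.edge_update_enabled = edge_update_enabled
        self.activation = activation
        if edge_update_enabled:
            self.W_rel_a = glorot(rng, d_out, d_edge)
            self.W_rel_b = glorot(rng, d_out, d_edge)
            self.b_rel = zeros(d_edge)
            self.W_e = glorot(rng, e_in + d_edge, d_edge)
            self.b_e = zeros(d_edge)

    @property
    def sigma(self):
        return ACTIVATIONS[self.activation]


def channel_decompose(A: np.ndarray) -> list[np.ndarray]:
    """Slice the (N, N, C_edge) edge tensor into C_edge adjacency matrices."""
    if A.ndim != 3 or A.shape[0] != A.shape[1]:
        raise ShapeError(f"edge tensor must be (N, N, C), got {A.shape}")
    return [A[:, :, k] for k in range(A.shape[2])]


def node_update(state: GraphState, params: CgcnLayerParams,
                channels: list[Tensor | np.ndarray]) -> Tensor:
    """Per-channel message passing followed by the learnable node combine."""
    sigma = params.sigma
    V = state.V
    n_channels = params.W_k.shape[0]
    if len(channels) != n_channels:
        raise ShapeError(f"{len(channels)} channels vs {n_channels} weights")
    msg_sum = None
    for k, E_k in enumerate(channels):
        E_k = E_k if isinstance(E_k, Tensor) else Tensor(E_k)
        m = sigma(E_k @ V @ params.W_k[k] + params.b_k[k])
        msg_sum = m if msg_sum is None else msg_sum + m
    return sigma(concat([V, msg_sum], axis=1) @ params.W_n + params.b_n)


def edge_relation(V_next: Tensor, params: CgcnLayerParams) -> Tensor:
    """Symmetrized relation vectors for all pairs: (N, N, d_edge)."""
    sigma = params.sigma
    n = V_next.shape[0]
    d_e = params.W_rel_a.shape[1]
    a = (V_next @ params.W_rel_a).reshape(n, 1, d_e)
    b = (V_next @ params.W_rel_b).reshape(1, n, d_e)
    raw = sigma(a + b + params.b_rel)
    return (raw + raw.transpose(1, 0, 2)) * 0.5


def edge_update(E_prev: Tensor, e_new: Tensor, params: CgcnLayerParams,
                bond_mask: np.ndarray) -> Tensor:
    """Learnable combine of previous edge features with new relations."""
    sigma = params.sigma
    combined = sigma(concat([E_prev, e_new], axis=2) @ params.W_e + params.b_e)
    return combined * Tensor(bond_mask[:, :, None])


class CgcnEncoder(Module):
    """Two-layer CGCN with edge update in layer 1 only, plus readout."""

    def __init__(self, config: CgcnConfig, rng: np.random.Generator):
        cfg = config
        self.config = cfg
        self.layer1 = CgcnLayerParams(
            n_channels=cfg.c_edge, d_in=cfg.c_node, d_out=cfg.d_node,
            e_in=cfg.c_edge, d_edge=cfg.d_edge, activation=cfg.activation,
            edge_update_enabled=True, rng=rng)
        # bridge: learned projection of layer-1 edge embeddings back to
        # c_edge scalar channels consumed by layer 2
        self.W_proj = glorot(rng, cfg.d_edge, cfg.c_edge)
        self.layer2 = CgcnLayerParams(
            n_channels=cfg.c_edge, d_in=cfg.d_node, d_out=cfg.d_node,
            e_in=cfg.c_edge, d_edge=cfg.d_edge, activation=cfg.activation,
            edge_update_enabled=False, rng=rng)
        self.W_out = glorot(rng, 2 * cfg.d_node, cfg.d_graph)
        self.b_out = zeros(cfg.d_graph)

    def __call__(self, graph: MolecularGraph) -> Tensor:
        return self.encode(graph)

    def encode(self, graph: MolecularGraph) -> Tensor:
        """Drug graph embedding of length d_graph (shape (1, d_graph))."""
        cfg = self.config
        A = graph.edge_tensor
        if A.shape[2] != cfg.c_edge:
            raise ShapeError(f"graph has {A.shape[2]} edge channels, "
                             f"encoder expects {cfg.c_edge}")
        if graph.node_features.shape[1] != cfg.c_node:
            raise ShapeError(f"graph has {graph.node_features.shape[1]} node "
                             f"features, encoder expects {cfg.c_node}")
        bond_mask = (np.abs(A).sum(axis=2) > 0).astype(float)
        state = GraphState(V=Tensor(graph.node_features), E=Tensor(A),
                           bond_mask=bond_mask, layer_index=0)

        # layer 1: node update on raw one-hot channels + collaborative edge update
        channels = [Tensor(E_k) for E_k in channel_decompose(A)]
        V1 = node_update(state, self.layer1, channels)
        e_rel = edge_relation(V1, self.layer1)
        E1 = edge_update(state.E, e_rel, self.layer1, bond_mask)

        # layer 2: node update only, over projected edge channels
        proj = E1 @ self.W_proj                     # (N, N, c_edge)
        channels2 = [proj[:, :, k] for k in range(cfg.c_edge)]
        state2 = GraphState(V=V1, E=E1, bond_mask=bond_mask, layer_index=1)
        V2 = node_update(state2, self.layer2, channels2)

        pooled = concat([V2.mean(axis=0, keepdims=True),
                         V2.max(axis=0, keepdims=True)], axis=1)
        return pooled @ self.W_out + self.b_out
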