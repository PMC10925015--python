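"""Graph encoder: message passing, edge co-update, and the loop oracle."""

import numpy as np
import pytest

import edgecdr as e
from edgecdr.autodiff import Tensor
from edgecdr.cgcn import (CgcnConfig, CgcnEncoder, CgcnLayerParams,
                          GraphState, channel_decompose, edge_relation,
                          edge_update, node_update)
from edgecdr.drug_graph import Bond, Molecule
from edgecdr.errors import ShapeError

RNG = np.random.default_rng(7)


def make_params(n_channels, d_in, d_out, e_in, d_edge, activation="identity",
                edge=True, rng=None):
    return CgcnLayerParams(n_channels=n_channels, d_in=d_in, d_out=d_out,
                           e_in=e_in, d_edge=d_edge, activation=activation,
                           edge_update_enabled=edge,
                           rng=rng or np.random.default_rng(0))


def identity_combine(params, d):
    """W_n = [I; I] stacked: combine(x, m) = x + m under identity sigma."""
    params.W_n.data = np.vstack([np.eye(d), np.eye(d)])
    params.b_n.data[:] = 0.0


# -- channel decomposition -------------------------------------------------

def test_channel_decompose_reconstructs_tensor():
    A = RNG.normal(size=(4, 4, 3))
    A = (A + A.transpose(1, 0, 2)) / 2
    mats = channel_decompose(A)
    np.testing.assert_array_equal(np.stack(mats, axis=2), A)


def test_channel_decompose_zero_tensor():
    mats = channel_decompose(np.zeros((3, 3, 2)))
    assert all(np.all(m == 0) for m in mats)


def test_ethanol_single_bond_channel_sparsity():
    g = e.graph_from_smiles("CCO")
    mats = channel_decompose(g.edge_tensor)
    assert np.count_nonzero(mats[0]) == 4      # single-bond channel
    assert all(np.count_nonzero(mats[k]) == 0 for k in (1, 2, 3))


def test_channel_decompose_rejects_nonsquare():
    with pytest.raises(ShapeError):
        channel_decompose(np.zeros((3, 4, 2)))


# -- node update -----------------------------------------------------------

def test_node_update_hand_oracle_path_graph():
    # bonds 0-1 and 1-2; single channel; W=I, b=0, sigma=identity, combine=sum
    E1 = np.array([[0., 1, 0], [1, 0, 1], [0, 1, 0]])
    V = np.array([[1., 0], [0, 1], [1, 1]])
    p = make_params(1, 2, 2, 1, 2)
    p.W_k.data[0] = np.eye(2)
    p.b_k.data[:] = 0.0
    identity_combine(p, 2)
    state = GraphState(V=Tensor(V), E=Tensor(np.zeros((3, 3, 1))),
                       bond_mask=(E1 > 0).astype(float))
    out = node_update(state, p, [E1])
    np.testing.assert_allclose(out.data, [[1, 1], [2, 2], [1, 2]])


def test_node_update_no_messages_is_identity():
    V = RNG.normal(size=(4, 3))
    p = make_params(2, 3, 3, 1, 2)
    p.W_k.data[:] = RNG.normal(size=p.W_k.shape)
    p.b_k.data[:] = 0.0
    identity_combine(p, 3)
    state = GraphState(V=Tensor(V), E=Tensor(np.zeros((4, 4, 1))),
                       bond_mask=np.zeros((4, 4)))
    out = node_update(state, p, [np.zeros((4, 4))] * 2)
    np.testing.assert_allclose(out.data, V)


def test_node_update_permutation_equivariance():
    V = RNG.normal(size=(5, 3))
    E1 = RNG.random((5, 5))
    E1 = np.triu(E1, 1) > 0.5
    E1 = (E1 | E1.T).astype(float)
    p = make_params(1, 3, 4, 1, 2, activation="relu")
    state = GraphState(V=Tensor(V), E=Tensor(np.zeros((5, 5, 1))),
                       bond_mask=E1)
    out = node_update(state, p, [E1]).data
    perm = RNG.permutation(5)
    state_p = GraphState(V=Tensor(V[perm]), E=Tensor(np.zeros((5, 5, 1))),
                         bond_mask=E1[np.ix_(perm, perm)])
    out_p = node_update(state_p, p, [E1[np.ix_(perm, perm)]]).data
    np.testing.assert_allclose(out_p, out[perm], atol=1e-12)


# -- edge relation / update ------------------------------------------------

def test_edge_relation_hand_example():
    p = make_params(1, 2, 2, 1, 2)
    p.W_rel_a.data = np.eye(2)
    p.W_rel_b.data = np.eye(2)
    p.b_rel.data[:] = 0.0
    V = Tensor(np.array([[0., 0], [1, 0], [0, 1]]))
    rel = edge_relation(V, p)
    np.testing.assert_allclose(rel.data[1, 2], [1.0, 1.0])
    np.testing.assert_allclose(rel.data[0, 0], [0.0, 0.0])  # sigma(0)


def test_edge_relation_is_symmetric():
    p = make_params(1, 3, 3, 1, 4, activation="relu",
                    rng=np.random.default_rng(3))
    V = Tensor(RNG.normal(size=(6, 3)))
    rel = edge_relation(V, p).data
    np.testing.assert_allclose(rel, rel.transpose(1, 0, 2))


def test_edge_update_identity_parameterization_is_addition():
    p = make_params(1, 2, 2, 2, 2)
    p.W_e.data = np.vstack([np.eye(2), np.eye(2)])
    p.b_e.data[:] = 0.0
    E_prev = Tensor(np.array([[1., 0]])[None, :, :])   # (1,1,2)
    e_new = Tensor(np.array([[0., 1]])[None, :, :])
    out = edge_update(E_prev, e_new, p, np.ones((1, 1)))
    np.testing.assert_allclose(out.data[0, 0], [1.0, 1.0])


# -- naive loop oracle for the full layer ----------------------------------

def naive_layer(V, A, p):
    """Explicit per-node / per-channel / per-pair loops over the layer math."""
    sig = (lambda x: np.maximum(x, 0)) if p.activation == "relu" else (lambda x: x)
    N, _, C = A.shape
    d_out = p.W_k.shape[2]
    M = np.zeros((N, d_out))
    for k in range(C):
        mk = np.zeros((N, d_out))
        for i in range(N):
            acc = np.zeros(V.shape[1])
            for j in range(N):
                acc += A[i, j, k] * V[j]
            mk[i] = acc @ p.W_k.data[k] + p.b_k.data[k]
        M += sig(mk)
    Vn = np.zeros((N, d_out))
    for i in range(N):
        Vn[i] = sig(np.concatenate([V[i], M[i]]) @ p.W_n.data + p.b_n.data)
    d_e = p.W_rel_a.shape[1]
    raw = np.zeros((N, N, d_e))
    for i in range(N):
        for j in range(N):
            raw[i, j] = sig(Vn[i] @ p.W_rel_a.data + Vn[j] @ p.W_rel_b.data
                            + p.b_rel.data)
    rel = np.zeros_like(raw)
    for i in range(N):
        for j in range(N):
            rel[i, j] = (raw[i, j] + raw[j, i]) / 2
    En = np.zeros((N, N, d_e))
    bonded = np.abs(A).sum(axis=2) > 0
    for i in range(N):
        for j in range(N):
            if bonded[i, j]:
                En[i, j] = sig(np.concatenate([A[i, j], rel[i, j]])
                               @ p.W_e.data + p.b_e.data)
    return Vn, rel, En


def random_graph(rng, n, c):
    A = np.zeros((n, n, c))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.6:
                vec = rng.random(c)
                A[i, j] = vec
                A[j, i] = vec
    V = rng.normal(size=(n, 3))
    return V, A


@pytest.mark.parametrize("activation", ["identity", "relu"])
def test_vectorized_layer_matches_loop_oracle(activation):
    rng = np.random.default_rng(11)
    for trial in range(10):
        n = int(rng.integers(2, 6))
        c = int(rng.integers(1, 3))
        V, A = random_graph(rng, n, c)
        p = make_params(c, 3, 4, c, 3, activation=activation,
                        rng=np.random.default_rng(trial))
        state = GraphState(V=Tensor(V), E=Tensor(A),
                           bond_mask=(np.abs(A).sum(2) > 0).astype(float))
        Vn = node_update(state, p, channel_decompose(A))
        rel = edge_relation(Vn, p)
        En = edge_update(state.E, rel, p, state.bond_mask)
        Vn_ref, rel_ref, En_ref = naive_layer(V, A, p)
        np.testing.assert_allclose(Vn.data, Vn_ref, atol=1e-6)
        np.testing.assert_allclose(rel.data, rel_ref, atol=1e-6)
        np.testing.assert_allclose(En.data, En_ref, atol=1e-6)


# -- full encoder ----------------------------------------------------------

def _encoder(seed=0):
    schema = e.FeatureSchema()
    cfg = CgcnConfig(c_node=schema.n_node_features,
                     c_edge=schema.n_edge_channels,
                     d_node=16, d_edge=8, d_graph=12)
    return CgcnEncoder(cfg, np.random.default_rng(seed))


def test_single_atom_graph_encodes():
    enc = _encoder()
    emb = enc.encode(e.graph_from_smiles("C"))
    assert emb.shape == (1, 12)
    assert np.all(np.isfinite(emb.data))


def test_embeddings_distinguish_molecules():
    enc = _encoder()
    a = enc.encode(e.graph_from_smiles("CCO")).data
    b = enc.encode(e.graph_from_smiles("c1ccccc1")).data
    assert not np.array_equal(a, b)


def test_encoder_permutation_invariance():
    enc = _encoder()
    rng = np.random.default_rng(1)
    for smiles in e.SMILES_POOL[:5]:
        g = e.graph_from_smiles(smiles)
        ref = enc.encode(g).data
        for _ in range(4):
            p = rng.permutation(g.n_atoms)
            g2 = e.MolecularGraph(node_features=g.node_features[p],
                                  edge_tensor=g.edge_tensor[np.ix_(p, p)],
                                  n_atoms=g.n_atoms)
            np.testing.assert_allclose(enc.encode(g2).data, ref, atol=1e-5)


def test_gradients_reach_layer1_node_and_edge_weights():
    enc = _encoder()
    emb = enc.encode(e.graph_from_smiles("CC(=O)Oc1ccccc1C(=O)O"))
    loss = (emb ** 2).sum()
    loss.backward()
    assert np.abs(enc.layer1.W_k.grad).max() > 0
    assert np.abs(enc.layer1.W_e.grad).max() > 0
    assert np.abs(enc.layer1.W_rel_a.grad).max() > 0


def test_layer1_edge_output_symmetric_and_bond_sparse():
    enc = _encoder()
    g = e.graph_from_smiles("CCO")
    A = g.edge_tensor
    mask = (np.abs(A).sum(2) > 0).astype(float)
    state = GraphState(V=Tensor(g.node_features), E=Tensor(A), bond_mask=mask)
    V1 = node_update(state, enc.layer1, channel_decompose(A))
    E1 = edge_update(state.E, edge_relation(V1, enc.layer1), enc.layer1, mask)
    np.testing.assert_allclose(E1.data, E1.data.transpose(1, 0, 2), atol=1e-12)
    assert np.all(E1.data[mask == 0] == 0)
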