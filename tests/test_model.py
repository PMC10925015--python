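"""Metrics, splits, fusion head, training behaviour, checkpointing."""

import numpy as np
import pytest
from scipy.stats import rankdata

import edgecdr as e
from edgecdr.autodiff import Tensor
from edgecdr.errors import (DataError, DegenerateInputError,
                            InfeasibleSplitError)
from edgecdr.model import ConvHead, pair_bookkeeping
from edgecdr.records import TEST, TRAIN, VALID, ResponseRecord

RNG = np.random.default_rng(13)


# -- evaluate --------------------------------------------------------------

def test_perfect_prediction_metrics():
    m = e.evaluate(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
    assert m.rmse == 0 and m.pcc == pytest.approx(1) and m.scc == pytest.approx(1)
    assert m.n == 3


def test_reversed_prediction_metrics():
    m = e.evaluate(np.array([3.0, 2, 1]), np.array([1.0, 2, 3]))
    assert m.pcc == pytest.approx(-1)
    assert m.scc == pytest.approx(-1)
    assert m.rmse == pytest.approx(np.sqrt(8 / 3))


def test_shifted_prediction_keeps_correlation():
    t = np.array([1.0, 2, 3])
    m = e.evaluate(t + 5, t)
    assert m.rmse == pytest.approx(5)
    assert m.pcc == pytest.approx(1) and m.scc == pytest.approx(1)


def test_constant_truth_rejected():
    with pytest.raises(DegenerateInputError):
        e.evaluate(np.array([1.0, 2, 3]), np.array([2.0, 2, 2]))


def _pearson(a, b):
    a = a - a.mean()
    b = b - b.mean()
    return float((a @ b) / np.sqrt((a @ a) * (b @ b)))


def test_evaluate_matches_textbook_formulas():
    for _ in range(10):
        p = RNG.normal(size=40)
        t = RNG.normal(size=40)
        m = e.evaluate(p, t)
        assert m.rmse == pytest.approx(np.sqrt(np.mean((p - t) ** 2)),
                                       abs=1e-10)
        assert m.pcc == pytest.approx(_pearson(p, t), abs=1e-10)
        assert m.scc == pytest.approx(_pearson(rankdata(p), rankdata(t)),
                                      abs=1e-10)


# -- splits ----------------------------------------------------------------

def _records(n, n_drugs=10, n_cells=10):
    return [ResponseRecord(f"d{i % n_drugs}", f"c{i % n_cells}",
                           float(np.sin(i)))
            for i in range(n)]


def test_random_split_80_20():
    labeled = e.split_dataset(_records(100), "random", 0.8, seed=0)
    counts = {s: sum(1 for r in labeled if r.split == s)
              for s in (TRAIN, TEST)}
    assert counts == {TRAIN: 80, TEST: 20}


def test_drug_blind_split_has_disjoint_drugs():
    labeled = e.split_dataset(_records(200), "drug_blind", 0.8, seed=1)
    train_drugs = {r.drug_id for r in labeled if r.split == TRAIN}
    test_drugs = {r.drug_id for r in labeled if r.split == TEST}
    assert train_drugs.isdisjoint(test_drugs) and test_drugs


def test_cell_blind_split_has_disjoint_cells():
    labeled = e.split_dataset(_records(200), "cell_blind", 0.8, seed=1)
    a = {r.cell_line_id for r in labeled if r.split == TRAIN}
    b = {r.cell_line_id for r in labeled if r.split == TEST}
    assert a.isdisjoint(b) and b


def test_split_deterministic_under_seed():
    a = e.split_dataset(_records(60), "random", 0.7, seed=9)
    b = e.split_dataset(_records(60), "random", 0.7, seed=9)
    assert a == b


def test_infeasible_blind_split_raises():
    # one drug holds 99% of records: no drug partition hits 50% +- 5%
    recs = [ResponseRecord("big", f"c{i}", 0.0) for i in range(99)]
    recs.append(ResponseRecord("small", "c0", 0.0))
    with pytest.raises(InfeasibleSplitError):
        e.split_dataset(recs, "drug_blind", 0.5, seed=0)


def test_valid_fraction_carved_from_train():
    labeled = e.split_dataset(_records(100), "random", 0.8, seed=0,
                              valid_fraction=0.1)
    counts = {s: sum(1 for r in labeled if r.split == s)
              for s in (TRAIN, VALID, TEST)}
    assert counts == {TRAIN: 70, VALID: 10, TEST: 20}


# -- pair bookkeeping ------------------------------------------------------

def test_pair_bookkeeping_small_grid():
    info = pair_bookkeeping(["d0", "d1", "d2"], ["c0", "c1"],
                            {("d0", "c0"), ("d1", "c1"), ("d2", "c0"),
                             ("d0", "c1"), ("d2", "c1")})
    assert info["total_pairs"] == 6
    assert info["n_missing"] == 1


# -- fusion head -----------------------------------------------------------

def test_zeroed_head_outputs_bias():
    cfg = e.TrainConfig.small()
    head = ConvHead(96, cfg, np.random.default_rng(0))
    for p in head.parameters():
        p.data[:] = 0.0
    head.dense2.b.data[:] = 1.25
    out = e.fuse_and_predict(np.zeros(32), np.zeros(32), np.zeros(32), head)
    assert out == pytest.approx(1.25)


def test_head_deterministic():
    cfg = e.TrainConfig.small()
    head = ConvHead(96, cfg, np.random.default_rng(1))
    x = RNG.normal(size=96)
    a = e.fuse_and_predict(x[:32], x[32:64], x[64:], head)
    b = e.fuse_and_predict(x[:32], x[32:64], x[64:], head)
    assert a == b


def test_head_sensitive_to_gene_embedding(tiny_trained):
    result, _, profiles, records = tiny_trained
    head = result.model.head
    x = RNG.normal(size=96)
    base = e.fuse_and_predict(x[:32], x[32:64], x[64:], head)
    bumped = e.fuse_and_predict(x[:32], x[32:64], x[64:] + 0.1, head)
    assert base != bumped


# -- training --------------------------------------------------------------

def test_training_is_seed_deterministic(tiny_dataset):
    drugs, profiles, records, _ = tiny_dataset
    cfg = e.TrainConfig.small(epochs=3, seed=4, batch_size=25)
    h1 = e.train(records, drugs, profiles, cfg).history
    h2 = e.train(records, drugs, profiles, cfg).history
    assert h1 == h2


def test_training_loss_decreases(tiny_trained):
    result, *_ = tiny_trained
    mses = [h["train_mse"] for h in result.history]
    assert mses[-1] < mses[0] / 2


def test_unresolvable_references_raise(tiny_dataset):
    drugs, profiles, records, _ = tiny_dataset
    bad = records + [ResponseRecord("ghost", "c000", 0.0)]
    cfg = e.TrainConfig.small(epochs=1)
    with pytest.raises(DataError):
        e.train(bad, drugs, profiles, cfg)


def test_augment_factor_multiplies_train_size(tiny_dataset):
    drugs, profiles, records, _ = tiny_dataset
    expanded, table = e.augment_training_set(records, drugs, 3, seed=0)
    n_train = sum(1 for r in records if r.split == TRAIN)
    assert sum(1 for r in expanded if r.split == TRAIN) == 3 * n_train
    assert len(table) == 3 * len(drugs)


def test_checkpoint_round_trip_is_bitwise(tmp_path, tiny_trained):
    result, drugs, profiles, records = tiny_trained
    path = tmp_path / "model.ckpt"
    e.save_checkpoint(result, path)
    loaded = e.load_checkpoint(path)
    pairs = [(r.drug_id, r.cell_line_id) for r in records[:10]]
    np.testing.assert_array_equal(result.model.predict(pairs, profiles),
                                  loaded.model.predict(pairs, profiles))


# -- missing-pair imputation ----------------------------------------------

def test_predict_missing_bookkeeping(tiny_trained):
    result, drugs, profiles, _ = tiny_trained
    cells = sorted(profiles)
    observed = {(d, c) for d in drugs for c in cells}
    removed = [("D000", "c001"), ("D002", "c005")]
    for pair in removed:
        observed.discard(pair)
    imputed, ranking = e.predict_missing(result.model, sorted(drugs), cells,
                                         observed, profiles)
    assert {(d, c) for d, c, _ in imputed} == set(removed)
    assert [d for d, _ in ranking] == sorted({d for d, _ in removed}) or \
        len(ranking) == len({d for d, _ in removed})
    assert all(m1 <= m2 for (_, m1), (_, m2) in zip(ranking, ranking[1:]))


def test_predict_missing_full_grid_is_empty(tiny_trained):
    result, drugs, profiles, _ = tiny_trained
    cells = sorted(profiles)
    observed = {(d, c) for d in drugs for c in cells}
    imputed, ranking = e.predict_missing(result.model, sorted(drugs), cells,
                                         observed, profiles)
    assert imputed == [] and ranking == []
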