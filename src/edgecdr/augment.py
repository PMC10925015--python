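"""SMILES enumeration and train-only data augmentation.

One molecule admits many valid SMILES renderings; re-rooting the traversal at
a random atom with a random atom order produces alternative strings that
canonicalize back to the same molecule.  Each alternative rendering is paired
with the original record's cell line and ln IC50 as an independent training
instance.  Augmentation is restricted to TRAIN records so that validation and
test sets never contain augmentation-created pairs.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem

from .drug_graph import canonical_smiles
from .errors import LeakageError, ParseError
from .records import TRAIN, ResponseRecord

_MAX_RETRIES = 10


def enumerate_smiles(smiles: str, n_variants: int, seed: int = 0) -> list[str]:
    """Up to ``n_variants`` distinct non-canonical renderings of ``smiles``.

    Every returned string differs from the input and from the other variants
    as a string while canonicalizing to the same molecule.  Molecules with too
    few distinct renderings (e.g. single atoms) yield fewer variants.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"invalid SMILES: {smiles!r}")
    if n_variants == 0:
        return []
    rng = np.random.default_rng(seed)
    seen = {smiles}
    out: list[str] = []
    n_atoms = mol.GetNumAtoms()
    while len(out) < n_variants:
        for _ in range(_MAX_RETRIES):
            order = rng.permutation(n_atoms).tolist()
            shuffled = Chem.RenumberAtoms(mol, order)
            root = int(rng.integers(n_atoms))
            variant = Chem.MolToSmiles(shuffled, canonical=False,
                                       rootedAtAtom=root)
            if variant not in seen:
                seen.add(variant)
                out.append(variant)
                break
        else:
            break  # molecule admits no further distinct renderings
    return out


def augment_training_set(
    records: list[ResponseRecord],
    drug_table: dict[str, str],
    factor: int,
    seed: int = 0,
) -> tuple[list[ResponseRecord], dict[str, str]]:
    """Expand TRAIN records ``factor``-fold with virtual SMILES variants.

    Each TRAIN record gains ``factor - 1`` copies referencing virtual drug ids
    whose SMILES are enumerated renderings of the parent; the cell line and
    ln IC50 are copied unchanged.  VALID/TEST records pass through untouched.
    ``factor=1`` is the identity.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return list(records), dict(drug_table)

    train_drugs = sorted({r.drug_id for r in records if r.split == TRAIN})
    variants: dict[str, list[str]] = {}
    expanded_table = dict(drug_table)
    rng = np.random.default_rng(seed)
    for drug_id in train_drugs:
        v = enumerate_smiles(drug_table[drug_id], factor - 1,
                             seed=int(rng.integers(2 ** 31)))
        variants[drug_id] = []
        for k, smi in enumerate(v):
            vid = f"{drug_id}__aug{k + 1}"
            expanded_table[vid] = smi
            variants[drug_id].append(vid)

    out = list(records)
    for r in records:
        if r.split != TRAIN:
            continue
        out.extend(_augment_record(r, variants[r.drug_id]))
    return out, expanded_table


def _augment_record(record: ResponseRecord,
                    virtual_ids: list[str]) -> list[ResponseRecord]:
    if record.split != TRAIN:
        raise LeakageError(
            f"cannot augment {record.split} record ({record.drug_id}, "
            f"{record.cell_line_id})")
    return [
        ResponseRecord(drug_id=vid, cell_line_id=record.cell_line_id,
                       ln_ic50=record.ln_ic50, split=TRAIN,
                       tcga_type=record.tcga_type,
                       parent_drug_id=record.drug_id)
        for vid in virtual_ids
    ]


def check_no_leakage(records: list[ResponseRecord]) -> None:
    """Assert no augmentation-created record sits in VALID/TEST."""
    for r in records:
        if r.parent_drug_id is not None and r.split != TRAIN:
            raise LeakageError(
                f"augmented record ({r.drug_id}, {r.cell_line_id}) labeled "
                f"{r.split}")
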