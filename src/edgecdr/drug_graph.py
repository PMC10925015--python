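"""SMILES parsing and molecular-graph featurization.

A drug is represented as a heavy-atom graph: a node feature matrix
``V ∈ R^{N × C_node}`` and an edge-channel adjacency tensor
``A ∈ R^{N × N × C_edge}``.  Bonded pairs carry a one-hot bond-order vector
plus conjugation and ring flags; absent bonds and the diagonal are all-zero.
Chemistry (validity, aromatic perception, canonical forms) is delegated to
RDKit; this module only fixes the numeric layout the graph encoder consumes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem, RDLogger

from .errors import ParseError, SchemaError

RDLogger.DisableLog("rdApp.*")  # rdkit warnings go to stderr otherwise

BOND_KINDS = ("single", "double", "triple", "aromatic")

_RDKIT_BOND = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


@dataclass(frozen=True)
class Atom:
    element: str
    degree: int
    aromatic: bool
    formal_charge: int
    in_ring: bool


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    kind: str  # one of BOND_KINDS
    conjugated: bool = False
    in_ring: bool = False


@dataclass(frozen=True)
class Molecule:
    """Heavy-atom graph of one drug; indices 0-based and contiguous."""
    atoms: tuple[Atom, ...]
    bonds: tuple[Bond, ...]
    smiles: str = ""

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass(frozen=True)
class FeatureSchema:
    """Layout of atom features and bond channels.

    ``C_node`` = |elements| + 6 degree bins + aromatic flag + ring flag +
    formal charge; ``C_edge`` = 4 bond-order channels + conjugation + ring.
    """
    elements: tuple[str, ...] = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P")
    other_bucket: bool = True
    max_degree: int = 5

    @property
    def n_node_features(self) -> int:
        return len(self.elements) + int(self.other_bucket) + (self.max_degree + 1) + 3

    @property
    def n_edge_channels(self) -> int:
        return len(BOND_KINDS) + 2


@dataclass
class MolecularGraph:
    node_features: np.ndarray  # (N, C_node)
    edge_tensor: np.ndarray    # (N, N, C_edge), symmetric, zero diagonal
    n_atoms: int
    smiles: str = ""


def parse_smiles(smiles: str) -> Molecule:
    """Parse a SMILES string into a heavy-atom :class:`Molecule`.

    Raises :class:`ParseError` on malformed or chemically impossible input.
    """
    if not smiles or not isinstance(smiles, str):
        raise ParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"invalid SMILES: {smiles!r}")
    atoms = tuple(
        Atom(
            element=a.GetSymbol(),
            degree=a.GetDegree(),
            aromatic=a.GetIsAromatic(),
            formal_charge=a.GetFormalCharge(),
            in_ring=a.IsInRing(),
        )
        for a in mol.GetAtoms()
    )
    bonds = []
    for b in mol.GetBonds():
        kind = _RDKIT_BOND.get(b.GetBondType())
        if kind is None:
            raise ParseError(f"unsupported bond type {b.GetBondType()} in {smiles!r}")
        bonds.append(Bond(
            i=b.GetBeginAtomIdx(), j=b.GetEndAtomIdx(), kind=kind,
            conjugated=b.GetIsConjugated(), in_ring=b.IsInRing(),
        ))
    return Molecule(atoms=atoms, bonds=tuple(bonds), smiles=smiles)


def canonical_smiles(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"invalid SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def featurize(mol: Molecule, schema: FeatureSchema | None = None) -> MolecularGraph:
    """Encode a molecule as node features + edge-channel adjacency tensor."""
    schema = schema or FeatureSchema()
    n = mol.n_atoms
    V = np.zeros((n, schema.n_node_features))
    n_el = len(schema.elements) + int(schema.other_bucket)
    for idx, atom in enumerate(mol.atoms):
        if atom.element in schema.elements:
            V[idx, schema.elements.index(atom.element)] = 1.0
        elif schema.other_bucket:
            V[idx, len(schema.elements)] = 1.0
        else:
            raise SchemaError(f"element {atom.element!r} outside schema")
        deg = min(atom.degree, schema.max_degree)
        V[idx, n_el + deg] = 1.0
        base = n_el + schema.max_degree + 1
        V[idx, base] = float(atom.aromatic)
        V[idx, base + 1] = float(atom.in_ring)
        V[idx, base + 2] = float(atom.formal_charge)

    A = np.zeros((n, n, schema.n_edge_channels))
    for bond in mol.bonds:
        vec = np.zeros(schema.n_edge_channels)
        vec[BOND_KINDS.index(bond.kind)] = 1.0
        vec[len(BOND_KINDS)] = float(bond.conjugated)
        vec[len(BOND_KINDS) + 1] = float(bond.in_ring)
        A[bond.i, bond.j] = vec
        A[bond.j, bond.i] = vec
    return MolecularGraph(node_features=V, edge_tensor=A, n_atoms=n,
                          smiles=mol.smiles)


def graph_from_smiles(smiles: str, schema: FeatureSchema | None = None) -> MolecularGraph:
    return featurize(parse_smiles(smiles), schema)


# -- drug table I/O -------------------------------------------------------

def read_drug_table(path: str | Path) -> dict[str, str]:
    """Read ``drug_id,smiles`` CSV, or a .smi file (SMILES [id] per line)."""
    path = Path(path)
    drugs: dict[str, str] = {}
    if path.suffix == ".smi":
        for k, line in enumerate(path.read_text().splitlines()):
            parts = line.split()
            if not parts:
                continue
            drug_id = parts[1] if len(parts) > 1 else f"drug_{k}"
            drugs[drug_id] = parts[0]
        return drugs
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            drugs[row["drug_id"]] = row["smiles"]
    return drugs


def write_drug_table(drugs: dict[str, str], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["drug_id", "smiles"])
        for drug_id, smiles in drugs.items():
            writer.writerow([drug_id, smiles])
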