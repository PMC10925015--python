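"""Self-contained synthetic inputs for the full pipeline.

The generators emulate the three real input tables — a drug table, four
genes × cell-lines omics matrices, and a drug/cell response table — with a
known planted rule, so that training, evaluation, missing-value imputation
and gene attribution can all be exercised and verified offline:

    ln IC50(d, c) = alpha * exp[planted_gene, c] + beta * z(d) + eps

where ``z(d)`` is the drug's heavy-atom count scaled by 1/10 and
``eps ~ Normal(0, noise_sd)``.  The drug pool is a fixed list of 64 valid
drug-like SMILES; omics entries follow simple declared distributions with a
2% missing rate to exercise mean imputation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .errors import PoolExhaustedError
from .records import ResponseRecord

# 64 drug-like molecules: common approved drugs, fragments and heterocycles.
SMILES_POOL: tuple[str, ...] = (
    "CC(=O)Oc1ccccc1C(=O)O",                     # aspirin
    "CC(C)Cc1ccc(C(C)C(=O)O)cc1",                # ibuprofen
    "CC(=O)Nc1ccc(O)cc1",                        # paracetamol
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",                # caffeine
    "CN1CCC[C@H]1c1cccnc1",                      # nicotine
    "OC(=O)c1ccccc1O",                           # salicylic acid
    "Clc1ccccc1Cl",                              # dichlorobenzene
    "c1ccc2ccccc2c1",                            # naphthalene
    "c1ccc2[nH]ccc2c1",                          # indole
    "O=C(O)c1ccncc1",                            # isonicotinic acid
    "NC(=O)c1ccncc1",                            # isonicotinamide
    "Nc1ccc(S(N)(=O)=O)cc1",                     # sulfanilamide
    "OCC(O)CO",                                  # glycerol
    "CC(=O)OCC[N+](C)(C)C",                      # acetylcholine
    "NCCc1ccc(O)c(O)c1",                         # dopamine
    "NC(Cc1ccc(O)cc1)C(=O)O",                    # tyrosine
    "NC(Cc1c[nH]c2ccccc12)C(=O)O",               # tryptophan
    "CC(N)Cc1ccccc1",                            # amphetamine
    "CNC(C)Cc1ccccc1",                           # methamphetamine
    "COc1cc2c(cc1OC)CCN2",                       # dimethoxy-indoline scaffold
    "O=c1cc[nH]c(=O)[nH]1",                      # uracil
    "Cc1c[nH]c(=O)[nH]c1=O",                     # thymine
    "Nc1ccn(C2CC(O)C(CO)O2)c(=O)n1",             # cytidine-like nucleoside
    "OCC1OC(O)C(O)C(O)C1O",                      # glucose
    "CC(=O)NC1C(O)OC(CO)C(O)C1O",                # N-acetylglucosamine
    "OC(=O)CC(O)(CC(=O)O)C(=O)O",                # citric acid
    "OC(=O)C=CC(=O)O",                           # fumaric acid
    "CC(O)C(=O)O",                               # lactic acid
    "C1CCNCC1",                                  # piperidine
    "C1CNCCN1",                                  # piperazine
    "C1COCCN1",                                  # morpholine
    "c1ccsc1",                                   # thiophene
    "c1ccoc1",                                   # furan
    "c1cc[nH]c1",                                # pyrrole
    "c1ccncc1",                                  # pyridine
    "c1cnc2[nH]ccc2c1",                          # azaindole
    "c1ccc(-c2ccccc2)cc1",                       # biphenyl
    "O=C(Nc1ccccc1)c1ccccc1",                    # benzanilide
    "O=S(=O)(c1ccccc1)c1ccccc1",                 # diphenyl sulfone
    "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1",            # atenolol
    "CC(C)NCC(O)COc1cccc2ccccc12",               # propranolol
    "CN(C)CCCN1c2ccccc2Sc2ccccc21",              # promazine
    "Clc1ccc2c(c1)C(c1ccccc1)=NCC2",             # benzazepine scaffold
    "O=C1CC(c2ccccc2)Oc2ccccc21",                # flavanone
    "O=c1cc(-c2ccccc2)oc2ccccc12",               # flavone
    "COc1ccc(CCN)cc1",                           # methoxyphenethylamine
    "CCN(CC)CCNC(=O)c1ccc(N)cc1",                # procainamide
    "CCOC(=O)c1ccc(N)cc1",                       # benzocaine
    "CN1CCN(CCCN2c3ccccc3Sc3ccc(Cl)cc32)CC1",    # prochlorperazine
    "OC(c1ccccc1)(c1ccccc1)C1CCNCC1",            # azacyclonol
    "O=C(O)c1cc(O)c(O)c(O)c1",                   # gallic acid
    "COc1cc(C=CC(=O)O)ccc1O",                    # ferulic acid
    "CC1=CC(=O)CC(C)(C)C1",                      # isophorone
    "CC12CCC3c4ccc(O)cc4CCC3C1CCC2O",            # estradiol
    "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",             # salbutamol
    "NS(=O)(=O)c1cc2c(cc1Cl)NCNS2(=O)=O",        # hydrochlorothiazide
    "CN(C)C(=N)NC(=N)N",                         # metformin
    "NCCCC(N)C(=O)O",                            # ornithine
    "NC(=O)NC1NC(=O)NC1=O",                      # allantoin
    "Oc1ccc(Cl)cc1Cc1cc(Cl)ccc1O",               # dichlorophene
    "CC(C)(C)c1ccc(O)cc1",                       # tert-butylphenol
    "CCCCCCCCC(=O)O",                            # nonanoic acid
    "CCOc1ccc(NC(C)=O)cc1",                      # phenacetin
    "CSCCC(N)C(=O)O",                            # methionine
)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic dataset."""
    n_drugs: int = 20
    n_cells: int = 50
    n_genes: int = 100
    planted_gene_index: int = 0
    alpha: float = 1.0           # planted-gene effect on ln IC50
    beta: float = 0.5            # drug-structure (heavy-atom) effect
    noise_sd: float = 0.1
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.planted_gene_index >= self.n_genes:
            raise ValueError("planted_gene_index out of range")


def make_drug_set(n_drugs: int, seed: int = 0) -> dict[str, str]:
    """Sample ``n_drugs`` distinct SMILES from the built-in pool."""
    if not 1 <= n_drugs <= len(SMILES_POOL):
        raise PoolExhaustedError(
            f"pool holds {len(SMILES_POOL)} molecules, {n_drugs} requested")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(SMILES_POOL), size=n_drugs, replace=False)
    return {f"D{i:03d}": SMILES_POOL[j] for i, j in enumerate(sorted(idx))}


def make_omics(n_cells: int, n_genes: int, seed: int = 0,
               missing_rate: float = 0.02) -> dict[str, pd.DataFrame]:
    """Four raw genes × cell-lines matrices with ~2% missing entries."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(n_genes)]
    cells = [f"c{i:03d}" for i in range(n_cells)]
    layers = {
        "exp": rng.normal(0.0, 1.0, size=(n_genes, n_cells)),
        "mut": rng.poisson(0.3, size=(n_genes, n_cells)).astype(float),
        "meth": rng.uniform(0.0, 1.0, size=(n_genes, n_cells)),
        "copy": rng.normal(2.0, 0.5, size=(n_genes, n_cells)),
    }
    out = {}
    for name, mat in layers.items():
        mask = rng.random(mat.shape) < missing_rate
        mat = mat.copy()
        mat[mask] = np.nan
        out[name] = pd.DataFrame(mat, index=genes, columns=cells)
    return out


def drug_structure_covariate(smiles: str) -> float:
    """Scaled heavy-atom count: the planted structural effect z(d)."""
    mol = Chem.MolFromSmiles(smiles)
    return mol.GetNumHeavyAtoms() / 10.0


def make_responses(
    drug_table: dict[str, str], omics: dict[str, pd.DataFrame],
    spec: FixtureSpec,
) -> tuple[list[ResponseRecord], dict]:
    """Responses from the planted linear rule, plus the ground-truth record."""
    rng = np.random.default_rng(spec.seed + 1)
    exp = omics["exp"]
    planted_gene = exp.index[spec.planted_gene_index]
    # the rule reads the raw (pre-normalization) expression, NaNs as 0
    exp_row = np.nan_to_num(exp.loc[planted_gene].to_numpy(dtype=float))
    records = []
    for drug_id, smiles in drug_table.items():
        z = drug_structure_covariate(smiles)
        for j, cell in enumerate(exp.columns):
            ln_ic50 = (spec.alpha * exp_row[j] + spec.beta * z
                       + rng.normal(0.0, spec.noise_sd))
            records.append(ResponseRecord(drug_id=drug_id, cell_line_id=cell,
                                          ln_ic50=float(ln_ic50)))
    truth = {"planted_gene": planted_gene, **asdict(spec)}
    return records, truth


def make_missing_mask(n_drugs: int, n_cells: int, missing_fraction: float,
                      seed: int = 0) -> np.ndarray:
    """Boolean (n_drugs, n_cells) grid with an exact masked count.

    Exactly ``round(missing_fraction * n_drugs * n_cells)`` entries are True,
    chosen uniformly without replacement.
    """
    total = n_drugs * n_cells
    n_masked = round(missing_fraction * total)
    rng = np.random.default_rng(seed)
    flat = np.zeros(total, dtype=bool)
    flat[rng.choice(total, size=n_masked, replace=False)] = True
    return flat.reshape(n_drugs, n_cells)


def make_dataset(spec: FixtureSpec):
    """Convenience: drug table, raw omics, responses and truth in one call."""
    drugs = make_drug_set(spec.n_drugs, seed=spec.seed)
    omics = make_omics(spec.n_cells, spec.n_genes, seed=spec.seed + 2)
    records, truth = make_responses(drugs, omics, spec)
    if spec.missing_fraction > 0:
        mask = make_missing_mask(spec.n_drugs, spec.n_cells,
                                 spec.missing_fraction, seed=spec.seed + 3)
        drug_ids = list(drugs)
        cell_ids = list(omics["exp"].columns)
        pos = {(d, c): (i, j) for i, d in enumerate(drug_ids)
               for j, c in enumerate(cell_ids)}
        records = [r for r in records
                   if not mask[pos[(r.drug_id, r.cell_line_id)]]]
    return drugs, omics, records, truth


def write_fixtures(spec: FixtureSpec, out_dir: str | Path) -> None:
    """Write drugs.csv, omics/{exp,mut,meth,copy}.csv, responses.csv, truth.json."""
    from .drug_graph import write_drug_table
    from .records import write_response_table

    out_dir = Path(out_dir)
    (out_dir / "omics").mkdir(parents=True, exist_ok=True)
    drugs, omics, records, truth = make_dataset(spec)
    write_drug_table(drugs, out_dir / "drugs.csv")
    for name, df in omics.items():
        df.to_csv(out_dir / "omics" / f"{name}.csv")
    write_response_table(records, out_dir / "responses.csv")
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2))
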