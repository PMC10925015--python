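"""Response records (drug, cell line, ln IC50, split) and their table I/O."""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from pathlib import Path

from .errors import DataError

TRAIN, VALID, TEST = "TRAIN", "VALID", "TEST"
SPLITS = (TRAIN, VALID, TEST)


@dataclass(frozen=True)
class ResponseRecord:
    """One drug–cell-line interaction with its natural-log IC50."""
    drug_id: str
    cell_line_id: str
    ln_ic50: float
    split: str = TRAIN
    tcga_type: str | None = None
    parent_drug_id: str | None = None  # set for augmentation-created records

    def __post_init__(self):
        if not math.isfinite(self.ln_ic50):
            raise DataError(f"non-finite ln_ic50 for ({self.drug_id}, "
                            f"{self.cell_line_id})")
        if self.split not in SPLITS:
            raise DataError(f"unknown split label {self.split!r}")

    @property
    def parent(self) -> str:
        """Identity used for per-drug grouping: the parent for virtual drugs."""
        return self.parent_drug_id or self.drug_id

    def with_split(self, split: str) -> "ResponseRecord":
        return replace(self, split=split)


def read_response_table(path: str | Path) -> list[ResponseRecord]:
    """Read a CSV with columns drug_id, cell_line_id, ln_ic50 [, split, tcga_type]."""
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(ResponseRecord(
                drug_id=row["drug_id"],
                cell_line_id=row["cell_line_id"],
                ln_ic50=float(row["ln_ic50"]),
                split=row.get("split", TRAIN) or TRAIN,
                tcga_type=row.get("tcga_type") or None,
                parent_drug_id=row.get("parent_drug_id") or None,
            ))
    return records


def write_response_table(records: list[ResponseRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["drug_id", "cell_line_id", "ln_ic50", "split",
                         "tcga_type", "parent_drug_id"])
        for r in records:
            writer.writerow([r.drug_id, r.cell_line_id, repr(r.ln_ic50),
                             r.split, r.tcga_type or "", r.parent_drug_id or ""])
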