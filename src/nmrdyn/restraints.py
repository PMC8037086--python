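"""NOE distance-restraint bookkeeping.

Restraints are classified purely by residue separation |i−j|:
intra-residual (0), sequential (1), medium range (2–4) and long range
(>4) — the categories NMR structure-statistics tables report.  Readers
cover a simple tabular CSV and a permissive text format that extracts
(i, j) pairs from XPLOR-style ``assign`` statements or CYANA-style rows;
ambiguous OR-groups are counted once via their first residue pair.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES = ("intra", "sequential", "medium", "long")

_RESID_RE = re.compile(r"resid(?:ue)?\s+(\d+)", re.IGNORECASE)


def classify_restraint(residue_i: int, residue_j: int) -> str:
    """Category from |i−j|: 0 → intra, 1 → sequential, 2–4 → medium, >4 → long."""
    sep = abs(int(residue_i) - int(residue_j))
    if sep == 0:
        return "intra"
    if sep == 1:
        return "sequential"
    if sep <= 4:
        return "medium"
    return "long"


@dataclass(frozen=True)
class RestraintRecord:
    residue_i: int
    residue_j: int
    atom_i: str = ""
    atom_j: str = ""
    bound: float | None = None
    category: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "category", classify_restraint(self.residue_i, self.residue_j))


def summarize_restraints(records: list[RestraintRecord]) -> dict[str, int]:
    """Counts per category plus the total; the categories partition the total."""
    counts = {c: 0 for c in CATEGORIES}
    for rec in records:
        counts[rec.category] += 1
    counts["total"] = len(records)
    return counts


def read_restraints_table(path: str | Path) -> list[RestraintRecord]:
    """Read a tabular restraint list (residue_i, atom_i, residue_j, atom_j[, upper_bound])."""
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        bound = float(getattr(row, "upper_bound")) if hasattr(row, "upper_bound") else None
        records.append(
            RestraintRecord(
                residue_i=int(row.residue_i),
                residue_j=int(row.residue_j),
                atom_i=str(getattr(row, "atom_i", "")),
                atom_j=str(getattr(row, "atom_j", "")),
                bound=bound,
            )
        )
    return records


def write_restraint_summary(records: list[RestraintRecord], path: str | Path) -> pd.DataFrame:
    counts = summarize_restraints(records)
    df = pd.DataFrame(
        {"category": CATEGORIES + ("total",), "count": [counts[c] for c in CATEGORIES] + [counts["total"]]}
    )
    df.to_csv(path, index=False)
    return df


def _parse_assign_statement(statement: str) -> RestraintRecord | None:
    resids = _RESID_RE.findall(statement)
    if len(resids) < 2:
        return None
    if len(resids) > 2:
        logger.info("ambiguous restraint counted once via first pair: %r", statement[:60])
    return RestraintRecord(residue_i=int(resids[0]), residue_j=int(resids[1]))


def read_restraints_mr(path: str | Path) -> list[RestraintRecord]:
    """Permissive reader for .mr restraint text.

    XPLOR dialect: every ``assign`` statement (possibly spanning lines)
    contributes one restraint from its first two ``resid`` numbers, so
    OR-group ambiguous restraints are counted once.  CYANA dialect: rows
    of ``i resname atom j resname atom upper``.  Unparseable lines are
    skipped.
    """
    text = Path(path).read_text()
    records: list[RestraintRecord] = []
    lower = text.lower()
    if "assign" in lower:
        chunks = re.split(r"(?i)\bassign\b", text)[1:]
        for chunk in chunks:
            rec = _parse_assign_statement(chunk)
            if rec is not None:
                records.append(rec)
        return records
    for line in text.splitlines():
        parts = line.split()
        if len(parts) < 7 or line.lstrip().startswith(("#", "!")):
            continue
        try:
            i, j = int(parts[0]), int(parts[3])
            bound = float(parts[6])
        except ValueError:
            continue
        records.append(
            RestraintRecord(residue_i=i, residue_j=j, atom_i=parts[2], atom_j=parts[5], bound=bound)
        )
    return records


__all__ = [
    "CATEGORIES",
    "RestraintRecord",
    "classify_restraint",
    "summarize_restraints",
    "read_restraints_table",
    "read_restraints_mr",
    "write_restraint_summary",
]
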