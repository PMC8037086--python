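"""Assigned 2D ¹H-¹⁵N peak lists and the Sparky text dialect.

A peak list holds one row per assigned amide: an assignment label (e.g.
``T28N-H``), the ¹⁵N and ¹H positions in ppm (Sparky column order: w1 =
¹⁵N, w2 = ¹H) and an optional peak height.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

_ASSIGNMENT_RE = re.compile(r"^([A-Za-z]{0,3})(\d+)")


def residue_number(assignment: str) -> int:
    """Residue number parsed from an assignment label like ``T28N-H``."""
    m = _ASSIGNMENT_RE.match(assignment)
    if not m:
        raise ValueError(f"cannot parse residue number from assignment {assignment!r}")
    return int(m.group(2))


@dataclass
class PeakList:
    """Assigned 2D resonances; wraps a DataFrame with columns
    ``assignment, residue, w_N, w_H, height``."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"assignment", "w_N", "w_H"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"peak list lacks columns {sorted(missing)}")
        if "residue" not in self.data.columns:
            self.data = self.data.assign(
                residue=[residue_number(a) for a in self.data["assignment"]]
            )
        if "height" not in self.data.columns:
            self.data = self.data.assign(height=np.nan)
        dup = self.data["assignment"].duplicated()
        if dup.any():
            raise ValueError(
                f"duplicate assignments: {sorted(self.data['assignment'][dup].unique())}"
            )
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def copy(self) -> "PeakList":
        return PeakList(self.data.copy())

    @classmethod
    def from_records(cls, records) -> "PeakList":
        """Build from an iterable of (assignment, w_N, w_H[, height]) tuples."""
        rows = []
        for rec in records:
            assignment, w_n, w_h = rec[0], rec[1], rec[2]
            height = rec[3] if len(rec) > 3 else np.nan
            rows.append({"assignment": assignment, "w_N": w_n, "w_H": w_h, "height": height})
        return cls(pd.DataFrame(rows))


def read_sparky(path: str | Path) -> PeakList:
    """Read a Sparky-style peak list.

    Whitespace-separated columns: assignment, w1 (¹⁵N ppm), w2 (¹H ppm)
    and an optional height.  Blank lines and header lines starting with
    ``Assignment`` are skipped.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("Assignment"):
            continue
        parts = stripped.split()
        if len(parts) < 3:
            raise ValueError(f"malformed peak-list line: {line!r}")
        height = float(parts[3]) if len(parts) > 3 else np.nan
        rows.append(
            {
                "assignment": parts[0],
                "w_N": float(parts[1]),
                "w_H": float(parts[2]),
                "height": height,
            }
        )
    return PeakList(pd.DataFrame(rows))


def write_sparky(peaks: PeakList, path: str | Path) -> None:
    """Write a Sparky-style peak list (assignment, w1=¹⁵N, w2=¹H, height)."""
    lines = [f"{'Assignment':>12} {'w1':>9} {'w2':>9} {'Height':>13}"]
    for row in peaks.data.itertuples(index=False):
        height = "" if pd.isna(row.height) else f"{row.height:13.3f}"
        lines.append(f"{row.assignment:>12} {row.w_N:9.3f} {row.w_H:9.3f} {height}")
    Path(path).write_text("\n".join(lines) + "\n")


__all__ = ["PeakList", "read_sparky", "write_sparky", "residue_number"]
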