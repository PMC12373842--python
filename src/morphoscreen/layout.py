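"""Microtiter-plate geometry and well naming.

A 384-well plate has 16 rows (A–P) and 24 columns (1–24). Wells are named
by row letter + column number ("B07"); names are accepted with or without
zero padding and stored normalized (zero-padded, e.g. ``B07``).
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping, Tuple

ROLES = ("dmso", "positive", "compound", "empty")

_ROW_LETTERS = string.ascii_uppercase


def well_name(row: int, col: int) -> str:
    """Name for 0-based row index and 1-based column number."""
    if row < 0 or row >= len(_ROW_LETTERS):
        raise ValueError(f"row index out of range: {row}")
    if col < 1:
        raise ValueError(f"column must be 1-based positive: {col}")
    return f"{_ROW_LETTERS[row]}{col:02d}"


def parse_well(name: str) -> Tuple[int, int]:
    """Parse "B07" or "B7" into (0-based row index, 1-based column)."""
    name = name.strip().upper()
    if len(name) < 2 or name[0] not in _ROW_LETTERS:
        raise ValueError(f"malformed well name: {name!r}")
    try:
        col = int(name[1:])
    except ValueError as exc:
        raise ValueError(f"malformed well name: {name!r}") from exc
    if col < 1:
        raise ValueError(f"malformed well name: {name!r}")
    return _ROW_LETTERS.index(name[0]), col


def normalize_well(name: str) -> str:
    row, col = parse_well(name)
    return well_name(row, col)


@dataclass(frozen=True)
class PlateLayout:
    """Assignment of plate positions to roles.

    ``control_wells`` maps well names to "dmso" or "positive"; every other
    position is available for a compound. The default screen layout places
    14 DMSO and 14 positive-control replicates on each 384-well plate.
    """

    n_rows: int = 16
    n_cols: int = 24
    control_wells: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_rows > 26 or self.n_cols < 1:
            raise ValueError("invalid plate dimensions")
        seen: Dict[str, str] = {}
        for name, role in self.control_wells.items():
            norm = normalize_well(name)
            row, col = parse_well(norm)
            if row >= self.n_rows or col > self.n_cols:
                raise ValueError(f"control well {norm} outside plate")
            if norm in seen:
                raise ValueError(f"well {norm} assigned twice")
            if role not in ("dmso", "positive"):
                raise ValueError(f"control role must be dmso/positive: {role}")
            seen[norm] = role
        object.__setattr__(self, "control_wells", seen)

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def compound_capacity(self) -> int:
        return self.n_wells - len(self.control_wells)

    def role_of(self, well: str) -> str:
        return self.control_wells.get(normalize_well(well), "compound")

    def iter_wells(self) -> Iterator[str]:
        """All wells in row-major (reading) order."""
        for row, col in itertools.product(range(self.n_rows), range(1, self.n_cols + 1)):
            yield well_name(row, col)

    def count_role(self, role: str) -> int:
        return sum(1 for r in self.control_wells.values() if r == role)


def default_384_layout(n_controls_per_role: int = 14) -> PlateLayout:
    """Screen layout: DMSO replicates down column 2, positive controls down
    column 23 (rows A.. as needed), 14 of each by default."""
    controls: Dict[str, str] = {}
    for i in range(n_controls_per_role):
        controls[well_name(i, 2)] = "dmso"
        controls[well_name(i, 23)] = "positive"
    return PlateLayout(16, 24, controls)
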