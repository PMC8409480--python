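"""Microtiter-plate geometry and per-well assignments.

Wells are addressed two ways: 0-based ``(row, col)`` coordinates with row A
at the top-left origin, and conventional labels such as ``"A1"``.  Distances
between wells are Euclidean in well-pitch units (row pitch and column pitch
treated as equal), which is the geometry used by the contamination
distance-of-migration profile.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import pandas as pd

__all__ = [
    "Well",
    "WellAssignment",
    "PlateLayout",
    "well_from_label",
    "label_from_well",
    "well_distance",
    "rotate_layout",
    "read_layout",
    "write_layout",
]

_LABEL_RE = re.compile(r"^([A-Pa-p])(\d{1,2})$")

#: Allowed plate sizes: (n_rows, n_cols)
PLATE_GEOMETRIES = {(8, 12), (16, 24)}

ROLES = {"sample", "negative_control", "positive_control", "empty"}


@dataclass(frozen=True)
class Well:
    """A single well position on a rectangular plate."""

    row: int
    col: int
    n_rows: int = 8
    n_cols: int = 12

    def __post_init__(self) -> None:
        if not (0 <= self.row < self.n_rows):
            raise ValueError(f"row {self.row} outside plate with {self.n_rows} rows")
        if not (0 <= self.col < self.n_cols):
            raise ValueError(f"col {self.col} outside plate with {self.n_cols} columns")

    @property
    def label(self) -> str:
        return label_from_well(self)


def well_from_label(label: str, n_rows: int = 8, n_cols: int = 12) -> Well:
    """Parse a label like ``"A1"`` into a :class:`Well`.

    Row letters run A.. from the top, column numbers 1.. from the left.
    Raises ``ValueError`` for malformed or out-of-bounds labels.
    """
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise ValueError(f"malformed well label: {label!r}")
    row = ord(m.group(1).upper()) - ord("A")
    col = int(m.group(2)) - 1
    if row >= n_rows or col >= n_cols or col < 0:
        raise ValueError(
            f"well label {label!r} outside a {n_rows}x{n_cols} plate"
        )
    return Well(row=row, col=col, n_rows=n_rows, n_cols=n_cols)


def label_from_well(well: Well) -> str:
    """Inverse of :func:`well_from_label`: ``Well(0, 0) -> "A1"``."""
    return f"{chr(ord('A') + well.row)}{well.col + 1}"


def well_distance(a: Well, b: Well, rounded: bool = False) -> float:
    """Euclidean distance between two wells in well-pitch units.

    With ``rounded=True`` the distance is rounded to the nearest integer,
    halves away from zero (so 0.5 -> 1), matching how migration distances
    are binned in the contamination profile.
    """
    if (a.n_rows, a.n_cols) != (b.n_rows, b.n_cols):
        raise ValueError("wells belong to plates of different geometry")
    d = math.hypot(a.row - b.row, a.col - b.col)
    if rounded:
        return float(math.floor(d + 0.5))
    return d


@dataclass(frozen=True)
class WellAssignment:
    """What was put in a well: sample identity, MID pair, tracer, spike-in."""

    sample_id: str
    fwd_mid_id: str
    rev_mid_id: str
    expected_coligo_id: str = ""
    isd_amount: float = 0.0
    role: str = "sample"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown well role {self.role!r}; expected one of {sorted(ROLES)}")
        if self.isd_amount < 0:
            raise ValueError("isd_amount must be nonnegative")


@dataclass
class PlateLayout:
    """A plate with per-well assignments.

    ``assignments`` maps well labels ("A1") to :class:`WellAssignment`.
    Each (forward MID, reverse MID) pair must be unique across the layout:
    the dual index is the sample identity, so a repeated pairing would make
    two wells indistinguishable after sequencing.
    """

    n_rows: int = 8
    n_cols: int = 12
    assignments: dict[str, WellAssignment] = field(default_factory=dict)
    isd_unit: str = "pg/ul"

    def __post_init__(self) -> None:
        if (self.n_rows, self.n_cols) not in PLATE_GEOMETRIES:
            raise ValueError(
                f"unsupported plate geometry {self.n_rows}x{self.n_cols}; "
                f"expected one of {sorted(PLATE_GEOMETRIES)}"
            )
        seen_pairs: dict[tuple[str, str], str] = {}
        for label, a in self.assignments.items():
            well_from_label(label, self.n_rows, self.n_cols)  # bounds check
            pair = (a.fwd_mid_id, a.rev_mid_id)
            if pair in seen_pairs:
                raise ValueError(
                    f"duplicate MID pairing {pair} in wells {seen_pairs[pair]} and {label}"
                )
            seen_pairs[pair] = label

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    def wells(self) -> Iterator[Well]:
        """All wells of the plate in row-major order (A1, A2, ... H12)."""
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                yield Well(r, c, self.n_rows, self.n_cols)

    def well(self, label: str) -> Well:
        return well_from_label(label, self.n_rows, self.n_cols)

    def mid_pair_to_sample(self) -> dict[tuple[str, str], str]:
        return {
            (a.fwd_mid_id, a.rev_mid_id): a.sample_id
            for a in self.assignments.values()
        }

    def sample_to_well(self) -> dict[str, str]:
        return {a.sample_id: label for label, a in self.assignments.items()}

    def coligo_home_wells(self) -> dict[str, str]:
        """Map each expected coligo id to the well it was added to."""
        homes: dict[str, str] = {}
        for label, a in self.assignments.items():
            if a.expected_coligo_id:
                homes[a.expected_coligo_id] = label
        return homes


def rotate_layout(layout: PlateLayout) -> PlateLayout:
    """Return the layout as it would read after a 180-degree plate rotation.

    Well (r, c) maps to (n_rows-1-r, n_cols-1-c); applying twice is the
    identity.  Used to check whether a plate was inadvertently rotated
    before the tracer oligos were read out.
    """
    rotated: dict[str, WellAssignment] = {}
    for label, a in layout.assignments.items():
        w = layout.well(label)
        new = Well(layout.n_rows - 1 - w.row, layout.n_cols - 1 - w.col,
                   layout.n_rows, layout.n_cols)
        rotated[new.label] = a
    return replace(layout, assignments=rotated)


_LAYOUT_COLUMNS = [
    "well", "sample_id", "fwd_mid_id", "rev_mid_id",
    "expected_coligo_id", "isd_amount", "role",
]


def read_layout(path, n_rows: int = 8, n_cols: int = 12) -> PlateLayout:
    """Read a sample sheet (TSV/CSV by extension) into a :class:`PlateLayout`."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = set(_LAYOUT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet {path} missing columns: {sorted(missing)}")
    assignments = {}
    for _, row in df.iterrows():
        assignments[row["well"]] = WellAssignment(
            sample_id=row["sample_id"],
            fwd_mid_id=row["fwd_mid_id"],
            rev_mid_id=row["rev_mid_id"],
            expected_coligo_id=row["expected_coligo_id"],
            isd_amount=float(row["isd_amount"]) if row["isd_amount"] else 0.0,
            role=row["role"] or "sample",
        )
    return PlateLayout(n_rows=n_rows, n_cols=n_cols, assignments=assignments)


def write_layout(layout: PlateLayout, path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    rows = []
    for label, a in layout.assignments.items():
        rows.append({
            "well": label, "sample_id": a.sample_id,
            "fwd_mid_id": a.fwd_mid_id, "rev_mid_id": a.rev_mid_id,
            "expected_coligo_id": a.expected_coligo_id,
            "isd_amount": a.isd_amount, "role": a.role,
        })
    pd.DataFrame(rows, columns=_LAYOUT_COLUMNS).to_csv(path, sep=sep, index=False)
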