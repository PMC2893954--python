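"""384-well plate data model: addresses, control layouts, readout tables.

The screen is run in 384-well plates (rows A–P, columns 1–24). Each plate
carries a fixed control layout: four wells transfected with an esiRNA against
Rad51 (positive control, strong suppression of homologous recombination) and
twelve wells with esiRNA against renilla luciferase (Rluc, non-targeting
negative control). The per-well readout is the percentage of GFP-positive
cells measured by flow cytometry, on a 0–100 scale.

User-facing well addresses are 1-based letter+number strings ("C3"); internal
indices are 0-based (row 0–15, column 0–23).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import AddressError, FormatError

ROW_LETTERS = string.ascii_uppercase[:16]  # A..P
N_ROWS = 16
N_COLS = 24
WELLS_PER_PLATE = N_ROWS * N_COLS

# Roles a well can play on a screening plate.
SAMPLE = "sample"
POSITIVE_CONTROL = "positive_control"
NEGATIVE_CONTROL = "negative_control"
EMPTY = "empty"
ROLES = (SAMPLE, POSITIVE_CONTROL, NEGATIVE_CONTROL, EMPTY)

#: Rad51 esiRNA wells on every screening plate.
POSITIVE_CONTROL_ADDRESSES = ("C3", "C21", "M5", "M18")
#: Rluc esiRNA wells on every screening plate.
NEGATIVE_CONTROL_ADDRESSES = (
    "C4", "D3", "D4", "C22", "D21", "D22",
    "M6", "N5", "N6", "M19", "N18", "N19",
)


@dataclass(frozen=True, order=True)
class WellAddress:
    """A single well, stored 0-based; rendered as e.g. ``"C3"``."""

    row: int
    col: int

    def __post_init__(self) -> None:
        if not (0 <= self.row < N_ROWS and 0 <= self.col < N_COLS):
            raise AddressError(
                f"well indices out of range for a 384 plate: row={self.row} col={self.col}"
            )

    @property
    def label(self) -> str:
        return f"{ROW_LETTERS[self.row]}{self.col + 1}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def parse_well_address(text: str) -> WellAddress:
    """Parse a letter+number address like ``"C3"`` into 0-based indices.

    Rejects rows beyond P and columns beyond 24.
    """
    if not isinstance(text, str) or len(text) < 2:
        raise AddressError(f"malformed well address: {text!r}")
    letter, digits = text[0].upper(), text[1:]
    if letter not in ROW_LETTERS:
        raise AddressError(f"row {letter!r} outside A–P in address {text!r}")
    if not digits.isdigit():
        raise AddressError(f"malformed well address: {text!r}")
    col = int(digits)
    if not 1 <= col <= N_COLS:
        raise AddressError(f"column {col} outside 1–24 in address {text!r}")
    return WellAddress(ROW_LETTERS.index(letter), col - 1)


def all_addresses() -> list[WellAddress]:
    """All 384 addresses in row-major order (A1, A2, …, P24)."""
    return [WellAddress(r, c) for r in range(N_ROWS) for c in range(N_COLS)]


@dataclass
class PlateLayout:
    """Role and esiRNA assignment for every well of one plate."""

    plate_id: str
    roles: dict[WellAddress, str]
    esirna: dict[WellAddress, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.roles) != WELLS_PER_PLATE:
            raise FormatError(
                f"plate {self.plate_id}: layout must cover all {WELLS_PER_PLATE} wells, "
                f"got {len(self.roles)}"
            )
        bad = {r for r in self.roles.values() if r not in ROLES}
        if bad:
            raise FormatError(f"plate {self.plate_id}: unknown roles {sorted(bad)}")

    def wells_with_role(self, role: str) -> list[WellAddress]:
        return sorted(w for w, r in self.roles.items() if r == role)

    @property
    def sample_wells(self) -> list[WellAddress]:
        return self.wells_with_role(SAMPLE)


def default_control_layout(plate_id: str = "plate") -> PlateLayout:
    """The screen's standard layout: 4 Rad51 wells, 12 Rluc wells, 368 samples."""
    roles = {w: SAMPLE for w in all_addresses()}
    for a in POSITIVE_CONTROL_ADDRESSES:
        roles[parse_well_address(a)] = POSITIVE_CONTROL
    for a in NEGATIVE_CONTROL_ADDRESSES:
        roles[parse_well_address(a)] = NEGATIVE_CONTROL
    return PlateLayout(plate_id=plate_id, roles=roles)


@dataclass
class PlateReadout:
    """Measured percent GFP-positive cells for (a subset of) one plate's wells."""

    layout: PlateLayout
    values: dict[WellAddress, float]
    replicate_id: int = 1
    extra: dict[str, dict[WellAddress, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for well, value in self.values.items():
            if well not in self.layout.roles:
                raise FormatError(
                    f"plate {self.layout.plate_id}: value for unknown well {well.label}"
                )
            v = float(value)
            if not (v == v) or not 0.0 <= v <= 100.0:  # NaN or out of range
                raise FormatError(
                    f"plate {self.layout.plate_id} well {well.label}: "
                    f"value {value!r} outside [0, 100]"
                )

    @property
    def plate_id(self) -> str:
        return self.layout.plate_id

    def values_with_role(self, role: str) -> list[float]:
        return [self.values[w] for w in sorted(self.values) if self.layout.roles[w] == role]


# ---------------------------------------------------------------------------
# Library map: esiRNA → gene and silencing-trigger index
# ---------------------------------------------------------------------------

@dataclass
class LibraryMap:
    """esiRNA id → (gene id, trigger index).

    A gene is targeted by up to two independent, non-overlapping esiRNAs
    ("silencing triggers" 1 and 2); the map enforces at most one esiRNA per
    (gene, trigger).
    """

    entries: dict[str, tuple[str, int]]

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for esirna, (gene, trigger) in self.entries.items():
            if trigger not in (1, 2):
                raise FormatError(f"esiRNA {esirna}: trigger index must be 1 or 2")
            key = (gene, trigger)
            if key in seen:
                raise FormatError(
                    f"gene {gene}: more than one esiRNA for trigger {trigger}"
                )
            seen.add(key)

    def gene_of(self, esirna: str) -> str:
        return self.entries[esirna][0]

    def trigger_of(self, esirna: str) -> int:
        return self.entries[esirna][1]

    def triggers_for_gene(self, gene: str) -> dict[int, str]:
        return {t: e for e, (g, t) in self.entries.items() if g == gene}

    def genes(self) -> list[str]:
        return sorted({g for g, _ in self.entries.values()})


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("plate_id", "replicate_id", "well", "value")


def read_readout_table(path: str | Path) -> list[PlateReadout]:
    """Read per-well readouts from CSV (plate_id, replicate_id, well, value).

    Optional ``role`` and ``esirna_id`` columns rebuild the plate layout; when
    absent, the default control layout is assumed. Any other columns are
    preserved per well under :attr:`PlateReadout.extra`.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    dup = df.duplicated(subset=["plate_id", "replicate_id", "well"])
    if dup.any():
        row = int(df.index[dup][0])
        raise FormatError(f"{path}: duplicate (plate, replicate, well) at row {row + 2}")
    bad = ~df["value"].astype(float).between(0.0, 100.0)
    if bad.any():
        row = int(df.index[bad][0])
        raise FormatError(
            f"{path}: value {df['value'].iloc[row]!r} outside [0,100] at row {row + 2}"
        )

    extra_cols = [c for c in df.columns if c not in _REQUIRED_COLUMNS + ("role", "esirna_id")]
    readouts: list[PlateReadout] = []
    for (plate_id, replicate_id), group in df.groupby(["plate_id", "replicate_id"], sort=True):
        layout = default_control_layout(str(plate_id))
        values: dict[WellAddress, float] = {}
        extra: dict[str, dict[WellAddress, str]] = {c: {} for c in extra_cols}
        for _, rec in group.iterrows():
            w = parse_well_address(str(rec["well"]))
            values[w] = float(rec["value"])
            if "role" in df.columns and isinstance(rec["role"], str):
                layout.roles[w] = rec["role"]
            if "esirna_id" in df.columns and isinstance(rec["esirna_id"], str):
                layout.esirna[w] = rec["esirna_id"]
            for c in extra_cols:
                extra[c][w] = rec[c]
        readouts.append(
            PlateReadout(layout=layout, values=values, replicate_id=int(replicate_id),
                         extra={c: m for c, m in extra.items() if m})
        )
    return readouts


def write_readout_table(readouts: Iterable[PlateReadout], path: str | Path) -> None:
    """Write readouts to CSV; lossless round-trip with :func:`read_readout_table`."""
    rows = []
    for ro in readouts:
        for w in sorted(ro.values):
            row = {
                "plate_id": ro.plate_id,
                "replicate_id": ro.replicate_id,
                "well": w.label,
                "value": ro.values[w],
                "role": ro.layout.roles[w],
                "esirna_id": ro.layout.esirna.get(w),
            }
            for c, m in ro.extra.items():
                row[c] = m.get(w)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_library_map(path: str | Path) -> LibraryMap:
    """Read a TSV with columns esirna_id, gene_id, trigger_index."""
    df = pd.read_csv(path, sep="\t")
    for col in ("esirna_id", "gene_id", "trigger_index"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    entries = {
        str(r.esirna_id): (str(r.gene_id), int(r.trigger_index))
        for r in df.itertuples()
    }
    if len(entries) != len(df):
        raise FormatError(f"{path}: duplicate esirna_id entries")
    return LibraryMap(entries)


def write_library_map(library: LibraryMap, path: str | Path) -> None:
    rows = [
        {"esirna_id": e, "gene_id": g, "trigger_index": t}
        for e, (g, t) in sorted(library.entries.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
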