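"""Active-site functional regions of the phosphohexomutase paralogs.

Four regions are conserved across the whole enzyme superfamily:

i.   the phosphoserine loop carrying the catalytic serine (TASH core),
ii.  the metal-binding loop (three aspartates: DGDGDR / DPDADR variants),
iii. the sugar-binding loop (GEESF in PGM1/5, FAFEE in PGM2/2L1, YFEAN in PGM3),
iv.  the phosphate-binding loop (conserved arginines / SGT motif).

A region is defined as a closed span of reference-alignment columns; member
residues of each protein are recovered through the alignment, so the same
definition serves motif profiling, extraction and variant classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .msa import GAP, Msa, PositionMap
from .records import ProteinRecord


class RegionLabel(str, Enum):
    PHOSPHOSERINE = "phosphoserine"
    METAL_BINDING = "metal_binding"
    SUGAR_BINDING = "sugar_binding"
    PO4_BINDING = "po4_binding"
    OTHER_KEY = "other_key"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class FunctionalRegion:
    """A functional region as a 0-based half-open reference column span."""

    label: RegionLabel
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        if self.col_stop <= self.col_start or self.col_start < 0:
            raise ValueError(f"empty or invalid column span for {self.label}")

    @property
    def columns(self) -> range:
        return range(self.col_start, self.col_stop)

    @property
    def width(self) -> int:
        return self.col_stop - self.col_start

    def native_interval(self, pm: PositionMap, protein: str) -> tuple[int, int] | None:
        """Smallest native interval of ``protein`` covering the region."""
        positions = []
        for col in self.columns:
            pos = _position_in_column(pm, protein, col)
            if pos is not None:
                positions.append(pos)
        if not positions:
            return None
        return min(positions), max(positions)

    def contains(self, pm: PositionMap, protein: str, native_pos: int) -> bool:
        col = pm.column_of(protein, native_pos)
        return col is not None and self.col_start <= col < self.col_stop


def _position_in_column(pm: PositionMap, protein: str, col: int) -> int | None:
    # PositionMap stores columns privately; walk via its internal table.
    group = pm._columns[col]  # noqa: SLF001 - intra-package access
    return group.get(protein)


def extract_region(
    record: ProteinRecord,
    region: FunctionalRegion,
    pm: PositionMap,
) -> tuple[str, list[int]]:
    """Residues of ``record`` within a region, gaps omitted.

    Returns the substring and the parallel list of native positions.
    Raises ``ValueError`` when the protein has no residue in any region
    column.
    """
    if record.id not in pm.proteins:
        raise KeyError(f"{record.id} not present in position map")
    positions = []
    for col in region.columns:
        pos = _position_in_column(pm, record.id, col)
        if pos is not None:
            positions.append(pos)
    if not positions:
        raise ValueError(
            f"region {region.label} entirely unmapped for {record.id}"
        )
    residues = "".join(record.residue_at(p) for p in positions)
    return residues, positions


def region_columns_in_subalignment(
    region: FunctionalRegion,
    reference_pm: PositionMap,
    reference_row_id: str,
    sub_msa: Msa,
    sub_row_id: str | None = None,
) -> list[tuple[int, int]]:
    """Locate a reference region inside a per-subgroup sub-alignment.

    The sub-alignment must contain the reference protein (same residues) as
    one of its rows; region columns are carried over via that protein's
    native positions.

    Returns ``(ordinal, column)`` pairs where ``ordinal`` indexes the region's
    reference columns (0-based) and ``column`` is the sub-alignment column.
    """
    sub_row_id = sub_row_id or reference_row_id
    row = sub_msa.row(sub_row_id)
    # native position -> sub-alignment column for the shared sequence
    pos_to_col: dict[int, int] = {}
    count = 0
    for col, c in enumerate(row.gapped):
        if c != GAP:
            count += 1
            pos_to_col[row.native_position(count)] = col
    cols = []
    for ordinal, col in enumerate(region.columns):
        pos = _position_in_column(reference_pm, reference_row_id, col)
        if pos is not None and pos in pos_to_col:
            cols.append((ordinal, pos_to_col[pos]))
    return cols
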