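"""Multiple sequence alignments and cross-paralog position mapping.

The central object for variant transfer is the :class:`PositionMap`: each
alignment column defines a correspondence group of (protein, native position)
pairs.  Rows aligned in permutation-adjusted coordinates (PGM3) carry a
:class:`~pgm_paralogs.permutation.CoordinateTranslator` and are always
reported in native numbering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .permutation import CoordinateTranslator, PermutationSpec, circular_permute
from .records import ProteinRecord, _parse_header

GAP = "-"

#: Sentinel returned for positions that fall in a gap column of the target.
UNMAPPED = None


@dataclass(frozen=True)
class MsaRow:
    """One aligned sequence.

    ``gapped`` ungaps to the record's residues, or to the permutation-adjusted
    residues when ``translator`` is present (``adjusted`` coordinate mode).
    """

    record: ProteinRecord
    gapped: str
    translator: CoordinateTranslator | None = None

    @property
    def adjusted(self) -> bool:
        return self.translator is not None

    def native_position(self, seq_index: int) -> int:
        """Map a 1-based index into the ungapped row to native numbering."""
        if self.translator is None:
            return seq_index
        return self.translator.to_native(seq_index)


class Msa:
    """An alignment over the protein alphabet plus ``-``."""

    def __init__(self, rows: Iterable[MsaRow]):
        self.rows: list[MsaRow] = list(rows)
        if not self.rows:
            raise ValueError("alignment must have at least one row")
        ncols = {len(r.gapped) for r in self.rows}
        if len(ncols) != 1:
            raise ValueError(f"rows have differing lengths: {sorted(ncols)}")
        self.ncols = ncols.pop()
        for row in self.rows:
            ungapped = row.gapped.replace(GAP, "")
            if row.translator is None:
                expected = row.record.residues
            else:
                expected = circular_permute(row.record, row.translator.spec)[0].residues
            if ungapped != expected:
                raise ValueError(
                    f"row {row.record.id}: gapped sequence does not reproduce "
                    f"the record's residues"
                    + (" (adjusted coordinates)" if row.translator else "")
                )
        self._index = {r.record.id: i for i, r in enumerate(self.rows)}
        if len(self._index) != len(self.rows):
            raise ValueError("duplicate row ids")

    def __len__(self) -> int:
        return len(self.rows)

    def row(self, key: int | str) -> MsaRow:
        if isinstance(key, str):
            return self.rows[self._index[key]]
        return self.rows[key]

    def ids(self) -> list[str]:
        return [r.record.id for r in self.rows]

    @classmethod
    def from_gapped(
        cls,
        sequences: Mapping[str, str],
        records: Mapping[str, ProteinRecord] | None = None,
        permutations: Mapping[str, PermutationSpec] | None = None,
    ) -> "Msa":
        """Build an alignment from gapped strings.

        ``permutations`` marks rows whose gapped sequence is laid out in
        permutation-adjusted coordinates; their native records are recovered
        by undoing the segment swap.
        """
        permutations = permutations or {}
        rows = []
        for rid, gapped in sequences.items():
            ungapped = gapped.replace(GAP, "")
            spec = permutations.get(rid)
            translator = None
            if spec is not None:
                # gapped row is adjusted; recover the native sequence
                tmp = ProteinRecord(id=rid, residues=ungapped)
                native_res = circular_permute(tmp, _adjusted_spec(spec))[0].residues
                translator = CoordinateTranslator(spec, len(ungapped))
            else:
                native_res = ungapped
            if records and rid in records:
                record = records[rid]
            else:
                record = ProteinRecord(id=rid, residues=native_res)
            rows.append(MsaRow(record=record, gapped=gapped, translator=translator))
        return cls(rows)

    @classmethod
    def read(
        cls,
        path: str | Path,
        permutations: Mapping[str, PermutationSpec] | None = None,
    ) -> "Msa":
        """Read an aligned FASTA file.

        Rows whose id appears in ``permutations`` (or whose header carries an
        ``adjusted`` token) are interpreted in adjusted coordinates.
        """
        from .records import Paralog

        permutations = permutations or {}
        sequences: dict[str, str] = {}
        records: dict[str, ProteinRecord] = {}
        meta: dict[str, tuple[Paralog, str]] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            rid, paralog, organism = _parse_header(rec.description)
            sequences[rid] = str(rec.seq).upper()
            meta[rid] = (paralog, organism)
        if not sequences:
            raise ValueError(f"no aligned records found in {path}")
        msa = cls.from_gapped(sequences, permutations=permutations)
        # attach paralog/organism metadata parsed from the headers
        rows = []
        for row in msa.rows:
            paralog, organism = meta[row.record.id]
            record = ProteinRecord(
                id=row.record.id,
                residues=row.record.residues,
                paralog=paralog,
                organism=organism,
            )
            rows.append(MsaRow(record=record, gapped=row.gapped, translator=row.translator))
        return cls(rows)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for row in self.rows:
                tokens = [row.record.id]
                if row.record.paralog.value != "OTHER":
                    tokens.append(row.record.paralog.value)
                if row.adjusted:
                    tokens.append("adjusted")
                fh.write(">" + "|".join(tokens) + "\n")
                for i in range(0, self.ncols, 60):
                    fh.write(row.gapped[i : i + 60] + "\n")


def _adjusted_spec(spec: PermutationSpec) -> PermutationSpec:
    """Spec that undoes ``spec`` when applied to the adjusted sequence."""
    (a0, a1), (b0, b1) = spec.segment_a, spec.segment_b
    len_a, len_b = a1 - a0 + 1, b1 - b0 + 1
    return PermutationSpec(
        segment_a=(a0, a0 + len_b - 1), segment_b=(a0 + len_b, b1)
    )


# ---------------------------------------------------------------------------
# identities
# ---------------------------------------------------------------------------

def pairwise_identity(msa: Msa, i: int | str, j: int | str) -> float:
    """Percent identity between two rows.

    The denominator is the number of columns where at least one of the two
    rows is non-gap (dual-gap columns are excluded); matching columns require
    identical non-gap residues.
    """
    a, b = msa.row(i).gapped, msa.row(j).gapped
    counted = matches = 0
    for ca, cb in zip(a, b):
        if ca == GAP and cb == GAP:
            continue
        counted += 1
        if ca == cb:
            matches += 1
    if counted == 0:
        warnings.warn("pairwise identity over empty overlap; defined as 0")
        return 0.0
    return 100.0 * matches / counted


@dataclass
class IdentityResult:
    """Square identity matrix (percent) and companion 1 - identity distances."""

    identity: pd.DataFrame
    distance: pd.DataFrame


def identity_matrix(msa: Msa) -> IdentityResult:
    """All-against-all percent identities with a 1 - id/100 distance half."""
    if len(msa) < 2:
        raise ValueError("need at least two rows")
    ids = msa.ids()
    n = len(ids)
    m = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pairwise_identity(msa, i, j)
    identity = pd.DataFrame(m, index=ids, columns=ids)
    return IdentityResult(identity=identity, distance=1.0 - identity / 100.0)


# ---------------------------------------------------------------------------
# position mapping
# ---------------------------------------------------------------------------

class PositionMap:
    """Alignment-column correspondence between proteins in native coordinates.

    Strict mapping: a protein gapped in a column is simply absent from that
    column's group (no nearest-residue rescue).
    """

    def __init__(self, columns: list[dict[str, int]], proteins: list[str]):
        self._columns = columns
        self._proteins = set(proteins)
        self._by_protein: dict[str, dict[int, int]] = {p: {} for p in proteins}
        for col_idx, group in enumerate(columns):
            for protein, pos in group.items():
                if pos in self._by_protein[protein]:
                    raise ValueError(
                        f"{protein} position {pos} appears in two columns"
                    )
                self._by_protein[protein][pos] = col_idx

    @property
    def proteins(self) -> set[str]:
        return set(self._proteins)

    def column_of(self, protein: str, native_pos: int) -> int | None:
        """0-based alignment column holding this residue, if any."""
        if protein not in self._proteins:
            raise KeyError(f"unknown protein {protein!r}")
        return self._by_protein[protein].get(native_pos)

    def group(self, protein: str, native_pos: int) -> dict[str, int]:
        """The full correspondence group containing (protein, position)."""
        col = self.column_of(protein, native_pos)
        if col is None:
            return {}
        return dict(self._columns[col])

    def map_position(
        self, from_protein: str, native_pos: int, to_protein: str
    ) -> int | None:
        """Transfer a native position across paralogs; ``None`` if unmapped."""
        if to_protein not in self._proteins:
            raise KeyError(f"unknown protein {to_protein!r}")
        group = self.group(from_protein, native_pos)
        return group.get(to_protein, UNMAPPED)


def build_position_map(msa: Msa) -> PositionMap:
    """Column-group position map over all rows, reported in native numbering."""
    columns: list[dict[str, int]] = []
    counters = {row.record.id: 0 for row in msa.rows}
    for col in range(msa.ncols):
        group: dict[str, int] = {}
        for row in msa.rows:
            c = row.gapped[col]
            if c == GAP:
                continue
            counters[row.record.id] += 1
            group[row.record.id] = row.native_position(counters[row.record.id])
        columns.append(group)
    return PositionMap(columns, [r.record.id for r in msa.rows])


def map_position(
    pm: PositionMap, from_protein: str, native_pos: int, to_protein: str
) -> int | None:
    """Functional form of :meth:`PositionMap.map_position`."""
    return pm.map_position(from_protein, native_pos, to_protein)
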