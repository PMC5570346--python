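"""Protein sequence records for the phosphohexomutase paralog family.

A :class:`ProteinRecord` holds one paralog sequence in its native 1-based
numbering (UniProt-style).  Sequences are upper-case strings over the 20
canonical amino acids plus ``X`` for unknown residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class Paralog(str, Enum):
    PGM1 = "PGM1"
    PGM2 = "PGM2"
    PGM2L1 = "PGM2L1"
    PGM3 = "PGM3"
    PGM5 = "PGM5"
    OTHER = "OTHER"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical residues plus X.
ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Human paralogs in the conventional reporting order.
HUMAN_PARALOGS = ("PGM1", "PGM2", "PGM2L1", "PGM3", "PGM5")

#: UniProtKB accessions of the five human paralogs (major transcripts).
UNIPROT_ACCESSIONS = {
    "PGM1": "P36871",
    "PGM2": "Q96G03",
    "PGM2L1": "Q6PCE3",
    "PGM3": "O95394",
    "PGM5": "Q15124",
}

#: Native sequence lengths of the human major transcripts.
NATIVE_LENGTHS = {
    "PGM1": 562, "PGM2": 612, "PGM2L1": 622, "PGM3": 542, "PGM5": 567,
}


@dataclass(frozen=True)
class ProteinRecord:
    """One paralog sequence with native 1-based numbering.

    ``residues[i-1]`` is the residue at native position ``i``; the sequence
    length equals the last native position.
    """

    id: str
    residues: str
    paralog: Paralog = Paralog.OTHER
    organism: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def residue_at(self, position: int) -> str:
        """Residue at a 1-based native position."""
        if not 1 <= position <= len(self.residues):
            raise IndexError(
                f"position {position} outside 1..{len(self.residues)} "
                f"for {self.id}"
            )
        return self.residues[position - 1]


def _parse_header(description: str) -> tuple[str, Paralog, str]:
    """Parse ``id|PARALOG|organism`` style FASTA headers (pieces optional)."""
    parts = description.split()[0].split("|")
    rid = parts[0]
    paralog = Paralog.OTHER
    organism = ""
    for token in parts[1:]:
        try:
            paralog = Paralog(token)
        except ValueError:
            if token != "adjusted":
                organism = token
    return rid, paralog, organism


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read plain (ungapped) FASTA into :class:`ProteinRecord` objects."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rid, paralog, organism = _parse_header(rec.description)
        records.append(
            ProteinRecord(
                id=rid,
                residues=str(rec.seq).upper().replace("-", ""),
                paralog=paralog,
                organism=organism,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(
            Seq(r.residues),
            id="|".join(p for p in (r.id, r.paralog.value, r.organism) if p),
            description="",
        )
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")
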