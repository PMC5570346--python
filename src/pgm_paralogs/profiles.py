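"""Per-subgroup position frequency profiles of the active-site regions.

Each enzyme sub-group (PGM1, PGM2, PGM2L1, PGM3, PGM5) has its own multiple
sequence alignment of diverse orthologs.  For every functional region we
compute a position frequency matrix (the data behind a sequence logo), flag
strictly conserved columns, and use the profiles as a log-odds classifier for
assigning novel sequences to a sub-group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .msa import GAP, Msa, PositionMap
from .records import ProteinRecord
from .regions import FunctionalRegion, RegionLabel, region_columns_in_subalignment

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass
class RegionProfile:
    """Frequency matrix (20 x width) for one region of one sub-group."""

    label: RegionLabel
    frequencies: pd.DataFrame      # index: amino acids, columns: 0..width-1
    strict: list[bool]             # per column: single residue at freq 1 (pre-pseudocount)
    consensus: str
    column_ordinals: list[int] = field(default_factory=list)  # region-column index per profile column

    @property
    def width(self) -> int:
        return self.frequencies.shape[1]


@dataclass
class SubgroupProfile:
    """All region profiles of one enzyme sub-group."""

    subgroup: str
    regions: dict[RegionLabel, RegionProfile]
    pseudocount: float
    n_sequences: int

    def region(self, label: RegionLabel) -> RegionProfile:
        return self.regions[label]


@dataclass(frozen=True)
class MotifConsensus:
    subgroup: str
    region: RegionLabel
    consensus: str
    strict: tuple[bool, ...]


def _column_frequencies(
    residues: Sequence[str], pseudocount: float
) -> tuple[np.ndarray, bool]:
    counts = np.zeros(20)
    for aa in residues:
        if aa in _AA_INDEX:
            counts[_AA_INDEX[aa]] += 1
    total = counts.sum()
    strict = bool(total > 0 and np.max(counts) == total)
    freqs = (counts + pseudocount) / (total + 20 * pseudocount)
    return freqs, strict


def build_profiles(
    sub_alignments: Mapping[str, Msa],
    regions: Sequence[FunctionalRegion],
    reference_pm: PositionMap,
    reference_ids: Mapping[str, str],
    pseudocount: float = 0.5,
) -> list[SubgroupProfile]:
    """Position frequency matrices per sub-group and region.

    ``reference_ids`` names, for each sub-group, the row shared with the
    reference alignment through which region columns are located.  Column
    frequencies are normalised with ``pseudocount`` added per residue; the
    strict-conservation flag reflects the raw (pre-pseudocount) counts.
    """
    out = []
    for subgroup, sub_msa in sub_alignments.items():
        if len(sub_msa) < 2:
            raise ValueError(f"sub-alignment {subgroup}: need >= 2 sequences")
        region_profiles: dict[RegionLabel, RegionProfile] = {}
        for region in regions:
            located = region_columns_in_subalignment(
                region, reference_pm, reference_ids[subgroup], sub_msa
            )
            if not located:
                raise ValueError(
                    f"region {region.label} has no columns in the "
                    f"{subgroup} sub-alignment"
                )
            ordinals = [o for o, _ in located]
            cols = [c for _, c in located]
            mat = np.zeros((20, len(cols)))
            strict: list[bool] = []
            consensus = []
            all_gap = True
            for k, col in enumerate(cols):
                residues = [row.gapped[col] for row in sub_msa.rows]
                if any(r != GAP for r in residues):
                    all_gap = False
                freqs, is_strict = _column_frequencies(residues, pseudocount)
                mat[:, k] = freqs
                strict.append(is_strict)
                consensus.append(AMINO_ACIDS[int(np.argmax(freqs))])
            if all_gap:
                raise ValueError(
                    f"region {region.label} is all-gap in the {subgroup} "
                    "sub-alignment"
                )
            region_profiles[region.label] = RegionProfile(
                label=region.label,
                frequencies=pd.DataFrame(
                    mat, index=list(AMINO_ACIDS), columns=range(len(cols))
                ),
                strict=strict,
                consensus="".join(consensus),
                column_ordinals=ordinals,
            )
        out.append(
            SubgroupProfile(
                subgroup=subgroup,
                regions=region_profiles,
                pseudocount=pseudocount,
                n_sequences=len(sub_msa),
            )
        )
    return out


def motif_consensus(profile: SubgroupProfile, label: RegionLabel) -> MotifConsensus:
    rp = profile.region(label)
    return MotifConsensus(
        subgroup=profile.subgroup,
        region=label,
        consensus=rp.consensus,
        strict=tuple(rp.strict),
    )


# ---------------------------------------------------------------------------
# sub-group classification
# ---------------------------------------------------------------------------

def _make_aligner(open_gap: float = 10.0, extend_gap: float = 0.5) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -open_gap
    aligner.extend_gap_score = -extend_gap
    return aligner


def _align_query_to_reference(
    query: ProteinRecord, reference_msa: Msa
) -> tuple[str, dict[int, str], set[int]]:
    """Best reference row, column -> query-residue map, and occupied columns."""
    aligner = _make_aligner()
    best = None
    qseq = query.residues.replace("X", "A")  # X scores poorly everywhere
    for row in reference_msa.rows:
        rseq = row.gapped.replace(GAP, "")
        try:
            aln = aligner.align(rseq, qseq)[0]
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or aln.score > best[0]:
            best = (aln.score, row, aln)
    if best is None:
        raise ValueError("query could not be aligned to any reference row")
    _, row, aln = best

    # index (0-based) within the ungapped reference row -> query residue
    ref_index_to_query: dict[int, str] = {}
    ref_blocks, query_blocks = aln.aligned
    for (rs, re), (qs, qe) in zip(ref_blocks, query_blocks):
        for off in range(re - rs):
            ref_index_to_query[rs + off] = query.residues[qs + off]

    # reference alignment column -> query residue
    col_to_query: dict[int, str] = {}
    occupied: set[int] = set()
    idx = 0
    for col, c in enumerate(row.gapped):
        if c == GAP:
            continue
        occupied.add(col)
        if idx in ref_index_to_query:
            col_to_query[col] = ref_index_to_query[idx]
        idx += 1
    return row.record.id, col_to_query, occupied


def classify_subgroup(
    query: ProteinRecord,
    profiles: Sequence[SubgroupProfile],
    reference_msa: Msa,
    reference_pm: PositionMap,
    regions: Sequence[FunctionalRegion],
    reference_ids: Mapping[str, str],
    background: np.ndarray | None = None,
    margin: float = 2.0,
    min_coverage: float = 0.8,
) -> tuple[str | None, dict[str, float]]:
    """Assign a query sequence to an enzyme sub-group by region log-odds.

    The query is globally aligned (affine gaps, BLOSUM62) to each reference
    row; the best-scoring row's column map is inherited.  Each sub-group is
    scored as ``sum over region columns of log(freq(residue)/background)``.
    Returns ``(subgroup, scores)``; subgroup is ``None`` (unclassified) when
    region coverage falls below ``min_coverage`` or the best margin is below
    ``margin`` nats.
    """
    if background is None:
        background = np.full(20, 1.0 / 20.0)
    ref_row_id, col_to_query, occupied = _align_query_to_reference(
        query, reference_msa
    )

    # coverage is judged over the region columns the chosen reference row
    # actually occupies (a structurally absent column is not a failure)
    total_cols = 0
    covered = 0
    region_queries: list[tuple[FunctionalRegion, list[tuple[int, str]]]] = []
    for region in regions:
        pairs = []
        for k, col in enumerate(region.columns):
            if col in occupied:
                total_cols += 1
            aa = col_to_query.get(col)
            if aa is not None and aa in _AA_INDEX:
                covered += 1
                pairs.append((k, aa))
        region_queries.append((region, pairs))
    if total_cols == 0 or covered / total_cols < min_coverage:
        warnings.warn(
            f"query {query.id}: only {covered}/{total_cols} region columns "
            "aligned; unclassified"
        )
        return None, {}

    scores: dict[str, float] = {}
    for profile in profiles:
        score = 0.0
        for region, pairs in region_queries:
            rp = profile.regions.get(region.label)
            if rp is None:
                continue
            ordinal_to_col = {o: k for k, o in enumerate(rp.column_ordinals)}
            for k, aa in pairs:
                pk = ordinal_to_col.get(k)
                if pk is None:
                    continue
                f = rp.frequencies.iloc[_AA_INDEX[aa], pk]
                score += float(np.log(max(f, 1e-12) / background[_AA_INDEX[aa]]))
        scores[profile.subgroup] = score

    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) > 1 and ranked[0][1] - ranked[1][1] < margin:
        return None, scores
    return ranked[0][0], scores
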