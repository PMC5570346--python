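"""Bundled synthetic reference fixtures for the five human paralogs.

No real sequence data is redistributed; every fixture is *synthetic*,
constructed deterministically at run time (the text copies shipped under
``pgm_paralogs/data/`` are byte-identical exports of these generators).
The reference alignment is a
stand-in for a curated alignment of the five human proteins: the sequences
have the real native lengths (562/612/622/542/567), PGM3 is laid out in
permutation-adjusted coordinates (native 54-114 swapped with 115-169), the
four active-site motifs sit at the catalogued native positions, and every
cross-paralog correspondence in the curated variant table is anchored into a
shared alignment column.  Residues outside these constraints are simulated
under the JTT model on the family's sister-pair topology, so identities and
trees built from the fixture behave like the real family qualitatively.

The curated variant table transcribes the known patient variants of PGM1 and
PGM3 and the population (ExAC-derived) variants selected by the
knowledge-based screen, with their frequency classes; the expert
physicochemical-significance call is carried as an explicit flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from . import jtt
from .expression import ExpressionMatrix, Modality
from .msa import Msa, MsaRow, PositionMap, build_position_map
from .permutation import PGM3_SPEC, CoordinateTranslator, circular_permute
from .phylo import read_newick
from .records import NATIVE_LENGTHS, Paralog, ProteinRecord, UNIPROT_ACCESSIONS
from .regions import FunctionalRegion, RegionLabel
from .synth import evolve_on_tree
from .variants import (
    DiseaseCatalog,
    FrequencyClass,
    MissenseVariant,
    Provenance,
)

#: Seed fixing every synthetic fixture (all fixtures are pure functions of it).
FIXTURE_SEED = 20170824

#: Backbone used to fill unconstrained fixture residues (sister pairs
#: (PGM1,PGM5) and (PGM2,PGM2L1); PGM3 most distant).
_FIXTURE_TREE = "((PGM1:0.35,PGM5:0.35):0.5,(PGM2:0.35,PGM2L1:0.35):0.5,PGM3:1.3);"

PARALOGS = ("PGM1", "PGM2", "PGM2L1", "PGM3", "PGM5")

# ---------------------------------------------------------------------------
# anchored layout of the reference alignment
#
# Each event pins aligned-coordinate positions (PGM3 in adjusted numbering)
# of the participating proteins into one shared column.  Residues between a
# protein's consecutive anchors pack against the right anchor (gaps open
# just after the left anchor).  Events tagged with a region label define the
# four functional-region column spans.
# ---------------------------------------------------------------------------


def _build_events() -> list[tuple[dict[str, int], str | None]]:
    ev: list[tuple[dict[str, int], str | None]] = []
    ev.append(({"PGM1": 38, "PGM3": 41}, None))
    # region i: phosphoserine loop (TASHN core + sub-group tail)
    for k in range(5):
        ev.append((
            {"PGM1": 115 + k, "PGM2": 160 + k, "PGM2L1": 173 + k,
             "PGM3": 117 + k, "PGM5": 118 + k},
            "phosphoserine",
        ))
    ev.append(({"PGM2": 165, "PGM2L1": 178}, "phosphoserine"))
    ev.append(({"PGM2": 166, "PGM2L1": 179}, "phosphoserine"))
    ev.append((
        {"PGM1": 120, "PGM2": 167, "PGM2L1": 180, "PGM3": 122, "PGM5": 123},
        "phosphoserine",
    ))
    ev.append(({"PGM1": 121, "PGM2": 168, "PGM3": 123, "PGM5": 124},
               "phosphoserine"))
    ev.append(({"PGM1": 122, "PGM2": 169, "PGM3": 124, "PGM5": 125},
               "phosphoserine"))
    ev.append((
        {"PGM1": 139, "PGM2": 185, "PGM2L1": 198, "PGM3": 138, "PGM5": 142},
        None,
    ))
    ev.append((
        {"PGM1": 261, "PGM2": 290, "PGM2L1": 291, "PGM3": 246, "PGM5": 264},
        None,
    ))
    # region ii: metal-binding loop
    for k in range(6):
        ev.append((
            {"PGM1": 288 + k, "PGM2": 322 + k, "PGM2L1": 332 + k,
             "PGM3": 273 + k, "PGM5": 293 + k},
            "metal_binding",
        ))
    ev.append(({"PGM1": 305}, None))       # domain 2/3 boundary column
    ev.append(({"PGM3": 297}, None))       # keeps PGM3 297 inside domain 3
    # region iii: sugar-binding loop
    sugar = [
        {"PGM1": 373, "PGM2": 423, "PGM2L1": 431, "PGM5": 376},
        {"PGM1": 374, "PGM2": 424, "PGM2L1": 432, "PGM5": 377},
        {"PGM1": 375, "PGM2": 425, "PGM2L1": 433, "PGM3": 368, "PGM5": 378},
        {"PGM1": 376, "PGM2": 426, "PGM2L1": 434, "PGM3": 369, "PGM5": 379},
        {"PGM1": 377, "PGM2": 427, "PGM2L1": 435, "PGM3": 370, "PGM5": 380},
        {"PGM1": 378, "PGM2L1": 436, "PGM3": 371, "PGM5": 381},
        {"PGM1": 379, "PGM2L1": 437, "PGM3": 372, "PGM5": 382},
        {"PGM1": 380, "PGM2": 428, "PGM2L1": 438, "PGM5": 383},
        {"PGM1": 381, "PGM5": 384},
        {"PGM1": 382, "PGM5": 385},
        {"PGM1": 383, "PGM5": 386},
    ]
    for e in sugar:
        ev.append((e, "sugar_binding"))
    ev.append(({"PGM1": 422, "PGM5": 427}, None))    # domain 4 boundary
    ev.append(({"PGM2L1": 520, "PGM3": 451}, None))
    # region iv: phosphate-binding loop
    for k in range(6):
        ev.append((
            {"PGM1": 503 + k, "PGM2": 558 + k, "PGM2L1": 568 + k,
             "PGM3": 496 + k, "PGM5": 508 + k},
            "po4_binding",
        ))
    for k, p5 in enumerate(range(514, 520)):
        ev.append(({"PGM1": 509 + k, "PGM5": p5}, "po4_binding"))
    ev.append(({"PGM1": 515, "PGM3": 505, "PGM5": 520}, "po4_binding"))
    ev.append(({"PGM1": 516}, "po4_binding"))
    return ev


def _layout() -> tuple[dict[str, dict[int, int]], dict[str, tuple[int, int]], int]:
    """Compute per-protein anchor->column maps and region column spans.

    Returns (anchors[protein][aligned_pos] = 1-based column,
    region span per label as 1-based closed interval, total columns).
    """
    events = _build_events()
    anchors: dict[str, dict[int, int]] = {p: {} for p in PARALOGS}
    region_cols: dict[str, list[int]] = {}
    prev_pos: dict[str, int] = {}
    prev_col: dict[str, int] = {}
    col = 0
    for event, region in events:
        c = col + 1
        for protein, pos in event.items():
            if protein in prev_pos:
                if pos <= prev_pos[protein]:
                    raise ValueError(f"non-monotone anchor {protein}:{pos}")
                c = max(c, prev_col[protein] + (pos - prev_pos[protein]))
            else:
                c = max(c, pos)  # leading residues must fit left of the anchor
        for protein, pos in event.items():
            anchors[protein][pos] = c
            prev_pos[protein], prev_col[protein] = pos, c
        if region is not None:
            region_cols.setdefault(region, []).append(c)
        col = c
    lengths = _aligned_lengths()
    ncols = max(
        prev_col[p] + (lengths[p] - prev_pos[p]) for p in PARALOGS
    )
    spans = {r: (min(cs), max(cs)) for r, cs in region_cols.items()}
    return anchors, spans, ncols


def _aligned_lengths() -> dict[str, int]:
    return dict(NATIVE_LENGTHS)  # the permutation preserves length


def _column_map(protein: str, anchors: dict[int, int], length: int) -> list[int]:
    """1-based column of every aligned position 1..length."""
    pairs = sorted(anchors.items())
    cols = [0] * (length + 1)
    first_pos, first_col = pairs[0]
    for pos in range(1, first_pos + 1):
        cols[pos] = first_col - (first_pos - pos)
    for (p0, c0), (p1, c1) in zip(pairs, pairs[1:]):
        for pos in range(p0 + 1, p1 + 1):
            cols[pos] = c1 - (p1 - pos)
    last_pos, last_col = pairs[-1]
    for pos in range(last_pos + 1, length + 1):
        cols[pos] = last_col + (pos - last_pos)
    if cols[1] < 1:
        raise ValueError(f"{protein}: layout pushes residues before column 1")
    for a, b in zip(cols[1:], cols[2:]):
        if b <= a:
            raise ValueError(f"{protein}: layout is not strictly increasing")
    return cols


# ---------------------------------------------------------------------------
# pinned residues (aligned coordinates; PGM3 pins below are native and are
# converted through the permutation translator)
# ---------------------------------------------------------------------------

_PINS_NATIVE: dict[str, dict[int, str]] = {
    "PGM1": {
        19: "T", 38: "N", 41: "Q", 62: "D",
        115: "T", 116: "A", 117: "S", 118: "H", 119: "N", 120: "P",
        121: "G", 122: "G", 139: "A", 230: "G", 261: "H", 263: "D",
        288: "D", 289: "G", 290: "D", 291: "G", 292: "D", 293: "R",
        330: "G", 336: "P", 337: "T",
        375: "G", 376: "E", 377: "E", 378: "S", 379: "F", 380: "G",
        388: "E", 422: "R",
        503: "R", 504: "G", 505: "S", 506: "G", 507: "T", 508: "G",
        509: "K", 510: "V", 511: "G", 512: "S", 513: "K", 514: "A",
        515: "R", 516: "L",
    },
    "PGM2": {
        160: "T", 161: "A", 162: "S", 163: "H", 164: "N", 165: "S",
        166: "H", 167: "G", 168: "G", 169: "A",
        322: "D", 323: "P", 324: "D", 325: "A", 326: "D", 327: "R",
        423: "F", 424: "A", 425: "F", 426: "E", 427: "E", 428: "G",
        558: "R", 559: "S", 560: "G", 561: "T", 562: "P", 563: "E",
    },
    "PGM2L1": {
        173: "T", 174: "A", 175: "S", 176: "H", 177: "N", 178: "R",
        179: "K", 180: "E", 291: "Q",
        332: "D", 333: "P", 334: "D", 335: "A", 336: "D", 337: "R",
        431: "F", 432: "A", 433: "F", 434: "E", 435: "E", 436: "S",
        437: "I", 520: "C",
        568: "R", 569: "S", 570: "G", 571: "G", 572: "T", 573: "E",
        574: "P", 575: "K",
    },
    "PGM3": {
        41: "R", 62: "T", 63: "A", 64: "S", 65: "H", 66: "N", 67: "P",
        68: "A", 69: "G", 83: "L", 239: "D", 246: "N",
        273: "D", 274: "G", 275: "D", 276: "A", 277: "D", 278: "R",
        297: "D", 368: "Y", 369: "F", 370: "E", 371: "A", 372: "N",
        379: "F", 451: "Q",
        496: "R", 497: "S", 498: "G", 499: "T", 500: "A", 501: "E",
        502: "D", 503: "A", 504: "K", 505: "R",
    },
    "PGM5": {
        118: "T", 119: "A", 120: "S", 121: "H", 122: "N", 123: "P",
        124: "G", 125: "G",
        293: "D", 294: "G", 295: "D", 296: "G", 297: "D", 298: "R",
        378: "G", 379: "E", 380: "E", 381: "S", 382: "F", 383: "S",
        386: "T", 427: "R",
        508: "R", 509: "G", 510: "S", 511: "G", 512: "T", 513: "S",
        514: "G", 515: "A", 516: "R", 517: "V", 518: "G", 519: "I",
        520: "R",
    },
}


def _aligned_pins() -> dict[str, dict[int, str]]:
    """Pins in aligned coordinates (PGM3 native pins -> adjusted)."""
    translator = CoordinateTranslator(PGM3_SPEC, NATIVE_LENGTHS["PGM3"])
    out: dict[str, dict[int, str]] = {}
    for protein, pins in _PINS_NATIVE.items():
        if protein == "PGM3":
            out[protein] = {
                translator.to_adjusted(pos): aa for pos, aa in pins.items()
            }
        else:
            out[protein] = dict(pins)
    return out


@dataclass
class ReferenceBundle:
    """Everything needed to run the analysis on the bundled fixtures."""

    msa: Msa
    position_map: PositionMap
    regions: list[FunctionalRegion]
    variants: list[MissenseVariant]
    catalog: DiseaseCatalog
    sub_alignments: dict[str, Msa]
    expression_protein: ExpressionMatrix
    expression_rna: ExpressionMatrix

    @property
    def reference_ids(self) -> dict[str, str]:
        return {p: p for p in PARALOGS}


@lru_cache(maxsize=1)
def reference_alignment() -> Msa:
    """The synthetic five-paralog reference alignment (PGM3 adjusted)."""
    anchors, _, ncols = _layout()
    lengths = _aligned_lengths()
    pins = _aligned_pins()

    rng = np.random.default_rng(FIXTURE_SEED)
    master = evolve_on_tree(read_newick(_FIXTURE_TREE), ncols, rng)

    rows = []
    for protein in PARALOGS:
        length = lengths[protein]
        cols = _column_map(protein, anchors[protein], length)
        aligned_seq = [
            jtt.AA_ORDER[master[protein][cols[pos] - 1]]
            for pos in range(1, length + 1)
        ]
        for pos, aa in pins[protein].items():
            aligned_seq[pos - 1] = aa
        gapped = ["-"] * ncols
        for pos in range(1, length + 1):
            gapped[cols[pos] - 1] = aligned_seq[pos - 1]
        gapped = "".join(gapped)

        translator = None
        if protein == "PGM3":
            adjusted = "".join(aligned_seq)
            tmp = ProteinRecord(id=protein, residues=adjusted)
            from .msa import _adjusted_spec

            native = circular_permute(tmp, _adjusted_spec(PGM3_SPEC))[0].residues
            translator = CoordinateTranslator(PGM3_SPEC, length)
        else:
            native = "".join(aligned_seq)
        record = ProteinRecord(
            id=protein,
            residues=native,
            paralog=Paralog(protein),
            organism=UNIPROT_ACCESSIONS[protein],
        )
        rows.append(MsaRow(record=record, gapped=gapped, translator=translator))
    return Msa(rows)


@lru_cache(maxsize=1)
def functional_regions() -> tuple[FunctionalRegion, ...]:
    """The four active-site regions as reference column spans (0-based)."""
    _, spans, _ = _layout()
    order = ["phosphoserine", "metal_binding", "sugar_binding", "po4_binding"]
    return tuple(
        FunctionalRegion(
            label=RegionLabel(name),
            col_start=spans[name][0] - 1,
            col_stop=spans[name][1],
        )
        for name in order
    )


# ---------------------------------------------------------------------------
# curated variant table (patient catalog + selected population variants)
# ---------------------------------------------------------------------------

_S = FrequencyClass.SINGLETON
_LO = FrequencyClass.BELOW_1E4          # marked * in the source table
_MID = FrequencyClass.BETWEEN_1E4_1E3   # marked ^ in the source table

_PATIENT: list[tuple[str, int, str, str]] = [
    ("PGM1", 19, "T", "A"), ("PGM1", 41, "Q", "R"), ("PGM1", 62, "D", "H"),
    ("PGM1", 115, "T", "A"), ("PGM1", 121, "G", "R"), ("PGM1", 230, "G", "E"),
    ("PGM1", 263, "D", "G"), ("PGM1", 263, "D", "Y"), ("PGM1", 291, "G", "R"),
    ("PGM1", 330, "G", "R"), ("PGM1", 336, "P", "R"), ("PGM1", 337, "T", "M"),
    ("PGM1", 377, "E", "K"), ("PGM1", 388, "E", "K"), ("PGM1", 422, "R", "W"),
    ("PGM1", 503, "R", "Q"), ("PGM1", 508, "G", "R"), ("PGM1", 515, "R", "L"),
    ("PGM1", 515, "R", "Q"), ("PGM1", 516, "L", "P"),
    ("PGM3", 41, "R", "L"), ("PGM3", 83, "L", "S"), ("PGM3", 239, "D", "H"),
    ("PGM3", 246, "N", "S"), ("PGM3", 297, "D", "E"), ("PGM3", 379, "F", "L"),
    ("PGM3", 451, "Q", "R"), ("PGM3", 502, "D", "Y"),
]

_POPULATION: list[tuple[str, int, str, str, FrequencyClass]] = [
    # PGM1
    ("PGM1", 38, "N", "Y", _S), ("PGM1", 41, "Q", "E", _S),
    ("PGM1", 41, "Q", "H", _S), ("PGM1", 121, "G", "W", _S),
    ("PGM1", 139, "A", "T", _S), ("PGM1", 261, "H", "D", _S),
    ("PGM1", 288, "D", "G", _S), ("PGM1", 330, "G", "S", _LO),
    ("PGM1", 375, "G", "V", _LO), ("PGM1", 380, "G", "R", _LO),
    ("PGM1", 422, "R", "Q", _S), ("PGM1", 505, "S", "R", _S),
    ("PGM1", 506, "G", "S", _S), ("PGM1", 511, "G", "R", _LO),
    ("PGM1", 515, "R", "W", _LO),
    # PGM2
    ("PGM2", 165, "S", "P", _S), ("PGM2", 166, "H", "D", _S),
    ("PGM2", 322, "D", "N", _LO), ("PGM2", 322, "D", "E", _S),
    ("PGM2", 323, "P", "L", _MID), ("PGM2", 324, "D", "H", _S),
    ("PGM2", 324, "D", "G", _S), ("PGM2", 428, "G", "E", _S),
    ("PGM2", 558, "R", "C", _LO), ("PGM2", 558, "R", "H", _MID),
    ("PGM2", 563, "E", "V", _S),
    # PGM2L1
    ("PGM2L1", 178, "R", "C", _LO), ("PGM2L1", 291, "Q", "K", _S),
    ("PGM2L1", 332, "D", "V", _S), ("PGM2L1", 334, "D", "E", _LO),
    ("PGM2L1", 431, "F", "L", _S), ("PGM2L1", 432, "A", "E", _S),
    ("PGM2L1", 433, "F", "S", _S), ("PGM2L1", 435, "E", "G", _S),
    ("PGM2L1", 437, "I", "T", _LO), ("PGM2L1", 520, "C", "Y", _S),
    ("PGM2L1", 571, "G", "R", _LO),
    # PGM3
    ("PGM3", 41, "R", "H", _LO), ("PGM3", 63, "A", "V", _S),
    ("PGM3", 369, "F", "I", _S), ("PGM3", 372, "N", "Y", _S),
    ("PGM3", 496, "R", "W", _LO), ("PGM3", 501, "E", "Q", _S),
    ("PGM3", 501, "E", "G", _S), ("PGM3", 505, "R", "Q", _S),
    # PGM5
    ("PGM5", 295, "D", "V", _LO), ("PGM5", 383, "S", "R", _S),
    ("PGM5", 386, "T", "I", _S), ("PGM5", 427, "R", "C", _S),
    ("PGM5", 427, "R", "H", _LO), ("PGM5", 508, "R", "W", _LO),
    ("PGM5", 508, "R", "Q", _LO), ("PGM5", 513, "S", "R", _MID),
    ("PGM5", 516, "R", "W", _LO),
]


@lru_cache(maxsize=1)
def table_variants() -> tuple[MissenseVariant, ...]:
    """The curated variant fixture (patient + retained population variants).

    The expert physicochemical call is taken as given (flag True for every
    entry; the published screen includes substitutions whose Grantham score
    is below any reasonable uniform threshold).
    """
    out = [
        MissenseVariant(
            protein=p, position=pos, ref=ref, alt=alt,
            frequency=FrequencyClass.SINGLETON,
            provenance=Provenance.PATIENT, physchem_override=True,
        )
        for p, pos, ref, alt in _PATIENT
    ]
    out.extend(
        MissenseVariant(
            protein=p, position=pos, ref=ref, alt=alt, frequency=freq,
            provenance=Provenance.POPULATION, physchem_override=True,
        )
        for p, pos, ref, alt, freq in _POPULATION
    )
    return tuple(out)


def disease_catalog() -> DiseaseCatalog:
    return DiseaseCatalog.from_variants(table_variants())


# ---------------------------------------------------------------------------
# per-subgroup sub-alignments (synthetic ortholog families)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def sub_alignments(n_members: int = 10, divergence: float = 0.4) -> dict[str, Msa]:
    """Synthetic ortholog families per sub-group.

    Each family holds the human fixture sequence plus relatives mutated
    under JTT at the pinned-free positions, in the same gapped layout; motif
    (pinned) columns are invariant, so within-subgroup strict conservation
    mirrors the real sub-alignments.
    """
    ref = reference_alignment()
    pins = _aligned_pins()
    model = jtt.default_model()
    rng = np.random.default_rng(FIXTURE_SEED + 1)
    p_t = model.transition_matrix(divergence)
    cum = np.cumsum(p_t, axis=1)

    out: dict[str, Msa] = {}
    for protein in PARALOGS:
        row = ref.row(protein)
        adjusted_seq = row.gapped.replace("-", "")
        pinned = set(pins[protein])
        sequences: dict[str, str] = {protein: row.gapped}
        perms = {}
        if row.translator is not None:
            perms[protein] = row.translator.spec
        states = jtt.encode(adjusted_seq)
        for k in range(1, n_members):
            u = rng.random(len(states))
            new_states = (u[:, None] > cum[states]).sum(axis=1)
            seq = list(jtt.decode(new_states))
            for pos in pinned:
                seq[pos - 1] = adjusted_seq[pos - 1]
            rid = f"{protein}_rel{k}"
            gapped = []
            it = iter("".join(seq))
            for c in row.gapped:
                gapped.append("-" if c == "-" else next(it))
            sequences[rid] = "".join(gapped)
            if row.translator is not None:
                perms[rid] = row.translator.spec
        out[protein] = Msa.from_gapped(sequences, permutations=perms)
    return out


# ---------------------------------------------------------------------------
# expression fixture (emulating the published tissue panel)
# ---------------------------------------------------------------------------

_TISSUES = (
    "adipocyte", "adrenal gland", "appendix", "bladder", "breast", "colon",
    "duodenum", "esophagus", "gall bladder", "heart", "ileum epithelia",
    "kidney", "liver", "lung", "lymph node", "ovary", "pancreas", "placenta",
    "prefrontal cortex", "prostate", "rectum", "retina", "salivary gland",
    "skin", "spleen", "stomach", "testis", "thyroid", "tonsil", "uterus",
)

# fold-change multipliers over the lognormal baseline (tissue -> factor)
_PROTEIN_SIGNATURES: dict[str, dict[str, float]] = {
    "PGM1": {"liver": 12.0, "adipocyte": 8.0, "kidney": 3.0, "lung": 3.0},
    "PGM2": {"lymph node": 10.0, "retina": 8.0, "spleen": 7.0},
    "PGM2L1": {"prefrontal cortex": 15.0},
    "PGM3": {"salivary gland": 5.0, "ileum epithelia": 4.5, "skin": 4.0},
    "PGM5": {"prostate": 12.0, "bladder": 10.0, "uterus": 9.0,
             "pancreas": 4.0, "spleen": 4.0, "rectum": 4.0, "stomach": 4.0},
}

_RNA_SIGNATURES: dict[str, dict[str, float]] = {
    "PGM1": {"liver": 10.0, "kidney": 8.0, "lung": 8.0},
    "PGM2": {"tonsil": 9.0, "skin": 8.0, "lymph node": 7.0},
    "PGM2L1": {"prefrontal cortex": 14.0},
    "PGM3": {"testis": 8.0, "salivary gland": 7.0, "thyroid": 6.0,
             "placenta": 6.0},
    "PGM5": {"esophagus": 60.0, "spleen": 6.0, "gall bladder": 5.0,
             "adrenal gland": 5.0},
}

# a few cells marked missing to exercise the mask (never signature cells)
_MISSING = {
    Modality.PROTEIN_IBAQ: [("retina", "PGM2L1"), ("breast", "PGM3")],
    Modality.RNA_FPKM: [("appendix", "PGM1"), ("heart", "PGM2L1")],
}


def _expression_fixture(modality: Modality) -> ExpressionMatrix:
    signatures = (
        _PROTEIN_SIGNATURES if modality is Modality.PROTEIN_IBAQ
        else _RNA_SIGNATURES
    )
    offset = 3 if modality is Modality.PROTEIN_IBAQ else 4
    rng = np.random.default_rng(FIXTURE_SEED + offset)
    base = 6.0 if modality is Modality.PROTEIN_IBAQ else 3.0
    values = np.exp(base + 0.4 * rng.standard_normal((len(_TISSUES), len(PARALOGS))))
    df = pd.DataFrame(values, index=list(_TISSUES), columns=list(PARALOGS))
    for paralog, factors in signatures.items():
        for tissue, factor in factors.items():
            df.loc[tissue, paralog] *= factor
    if modality is Modality.PROTEIN_IBAQ:
        df["PGM2L1"] /= 4.0                      # markedly low outside brain
        df.loc["prefrontal cortex", "PGM2L1"] *= 4.0
    for tissue, paralog in _MISSING[modality]:
        df.loc[tissue, paralog] = np.nan
    return ExpressionMatrix(data=df.round(3), modality=modality)


@lru_cache(maxsize=1)
def expression_fixtures() -> tuple[ExpressionMatrix, ExpressionMatrix]:
    return (
        _expression_fixture(Modality.PROTEIN_IBAQ),
        _expression_fixture(Modality.RNA_FPKM),
    )


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def reference_bundle() -> ReferenceBundle:
    msa = reference_alignment()
    protein, rna = expression_fixtures()
    return ReferenceBundle(
        msa=msa,
        position_map=build_position_map(msa),
        regions=list(functional_regions()),
        variants=list(table_variants()),
        catalog=disease_catalog(),
        sub_alignments=sub_alignments(),
        expression_protein=protein,
        expression_rna=rna,
    )


def write_bundle(directory: str | Path) -> dict[str, Path]:
    """Export the fixture bundle as plain-text files for CLI use."""
    from .variants import write_variant_table

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bundle = reference_bundle()
    paths: dict[str, Path] = {}

    p = directory / "reference_alignment.synthetic.afa"
    bundle.msa.write(p)
    paths["alignment"] = p

    p = directory / "curated_variants.tsv"
    write_variant_table(bundle.variants, p)
    paths["variants"] = p

    p = directory / "regions.tsv"
    pd.DataFrame(
        [
            {"label": r.label.value, "col_start": r.col_start,
             "col_stop": r.col_stop}
            for r in bundle.regions
        ]
    ).to_csv(p, sep="\t", index=False)
    paths["regions"] = p

    for protein, sub in bundle.sub_alignments.items():
        sp = directory / f"subalignment_{protein}.synthetic.afa"
        sub.write(sp)
        paths[f"subalignment_{protein}"] = sp

    p = directory / "expression_protein.synthetic.tsv"
    bundle.expression_protein.write_tsv(p)
    paths["expression_protein"] = p
    p = directory / "expression_rna.synthetic.tsv"
    bundle.expression_rna.write_tsv(p)
    paths["expression_rna"] = p

    p = directory / "permutation.tsv"
    pd.DataFrame(
        [{
            "protein": "PGM3",
            "segment_a_start": PGM3_SPEC.segment_a[0],
            "segment_a_end": PGM3_SPEC.segment_a[1],
            "segment_b_start": PGM3_SPEC.segment_b[0],
            "segment_b_end": PGM3_SPEC.segment_b[1],
        }]
    ).to_csv(p, sep="\t", index=False)
    paths["permutation"] = p
    return paths
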