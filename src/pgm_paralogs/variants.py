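"""Knowledge-based transfer and classification of missense variants.

PGM1 and PGM3 deficiencies are inherited diseases with a catalog of
confirmed patient missense positions.  The classification implemented here
screens population (ExAC-style) variants of all five paralogs:

* ``confirmed_disease``      - the variant itself is a patient variant;
* ``at_disease_position``    - a population variant at a position where the
  same protein already has a patient variant (tabulated in parentheses in
  the source catalog; not counted as a new corresponding variant);
* ``corresponds_to_disease`` - category 1: the position maps, through the
  permutation-aware reference alignment, onto a patient position of another
  paralog (or of PGM1/PGM3) that is not already a patient position of the
  variant's own protein;
* ``functional_region``      - category 2: the position falls inside one of
  the key active-site regions;
* ``unclassified``           - everything else.

Categories 1 and 2 additionally require a significant physicochemical change
(Grantham distance, or an explicit expert flag) and population rarity.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .grantham import grantham_distance
from .msa import PositionMap
from .regions import FunctionalRegion

DEFAULT_TAU = 60.0
DEFAULT_MAX_FREQ = 1e-3

_AA3 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V",
}


class FrequencyClass(str, Enum):
    """Coarse population frequency bins used by the variant catalog."""

    SINGLETON = "singleton"
    BELOW_1E4 = "lt_1e-4"
    BETWEEN_1E4_1E3 = "between_1e-4_and_1e-3"
    ABOVE_1E3 = "ge_1e-3"


class Provenance(str, Enum):
    PATIENT = "patient_confirmed"
    POPULATION = "population"


class Category(str, Enum):
    CONFIRMED = "confirmed_disease"
    AT_DISEASE_POSITION = "at_disease_position"
    CORRESPONDS = "corresponds_to_disease"
    FUNCTIONAL_REGION = "functional_region"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class MissenseVariant:
    """A single residue substitution with population context."""

    protein: str
    position: int
    ref: str
    alt: str
    frequency: FrequencyClass | float = FrequencyClass.SINGLETON
    provenance: Provenance = Provenance.POPULATION
    physchem_override: bool | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.label}: ref and alt identical")
        if self.position < 1:
            raise ValueError(f"{self.label}: position must be >= 1")

    @property
    def label(self) -> str:
        return f"{self.protein}:{self.ref}{self.position}{self.alt}"


def parse_protein_change(text: str) -> tuple[str, int, str]:
    """Parse an HGVS-style protein consequence such as ``p.Arg503Gln``."""
    m = re.fullmatch(r"p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})", text.strip())
    if not m:
        raise ValueError(f"cannot parse protein change {text!r}")
    ref3, pos, alt3 = m.groups()
    try:
        return _AA3[ref3], int(pos), _AA3[alt3]
    except KeyError as exc:
        raise ValueError(f"unknown residue code in {text!r}") from exc


def _parse_frequency(token: str) -> FrequencyClass | float:
    token = token.strip()
    try:
        return FrequencyClass(token)
    except ValueError:
        pass
    try:
        return float(token)
    except ValueError as exc:
        raise ValueError(f"unrecognised frequency {token!r}") from exc


def read_variant_table(path: str | Path) -> list[MissenseVariant]:
    """Read a tab-separated variant table.

    Expected header: ``protein position ref alt frequency provenance`` with
    an optional ``physchem`` column (1/0 expert flag) and optional
    ``change`` column carrying ``p.Arg503Gln``-style strings instead of
    position/ref/alt.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    variants = []
    for _, row in df.iterrows():
        if "change" in df.columns and isinstance(row.get("change"), str):
            ref, pos, alt = parse_protein_change(row["change"])
        else:
            ref, pos, alt = row["ref"], int(row["position"]), row["alt"]
        override = None
        if "physchem" in df.columns and not pd.isna(row["physchem"]):
            override = bool(int(row["physchem"]))
        variants.append(
            MissenseVariant(
                protein=row["protein"],
                position=pos,
                ref=ref,
                alt=alt,
                frequency=_parse_frequency(row.get("frequency", "singleton")),
                provenance=Provenance(row.get("provenance", "population")),
                physchem_override=override,
            )
        )
    return variants


def write_variant_table(variants: Iterable[MissenseVariant], path: str | Path) -> None:
    rows = []
    for v in variants:
        freq = v.frequency.value if isinstance(v.frequency, FrequencyClass) else v.frequency
        rows.append(
            {
                "protein": v.protein,
                "position": v.position,
                "ref": v.ref,
                "alt": v.alt,
                "frequency": freq,
                "provenance": v.provenance.value,
                "physchem": "" if v.physchem_override is None else int(v.physchem_override),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


class DiseaseCatalog:
    """Confirmed patient missense positions per protein."""

    def __init__(self, entries: Mapping[str, Mapping[int, set[str]]]):
        self._entries = {
            protein: {pos: set(alts) for pos, alts in positions.items()}
            for protein, positions in entries.items()
        }

    @classmethod
    def from_variants(cls, variants: Iterable[MissenseVariant]) -> "DiseaseCatalog":
        entries: dict[str, dict[int, set[str]]] = {}
        for v in variants:
            if v.provenance is not Provenance.PATIENT:
                continue
            entries.setdefault(v.protein, {}).setdefault(v.position, set()).add(v.alt)
        return cls(entries)

    @property
    def proteins(self) -> list[str]:
        return sorted(self._entries)

    def positions(self, protein: str) -> set[int]:
        return set(self._entries.get(protein, {}))

    def n_positions(self, protein: str | None = None) -> int:
        if protein is not None:
            return len(self._entries.get(protein, {}))
        return sum(len(p) for p in self._entries.values())

    def contains(self, protein: str, position: int) -> bool:
        return position in self._entries.get(protein, {})

    def alts(self, protein: str, position: int) -> set[str]:
        return set(self._entries.get(protein, {}).get(position, set()))


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def physchem_change(
    ref: str, alt: str, tau: float = DEFAULT_TAU
) -> tuple[float, bool]:
    """Grantham score of a substitution and its significance at threshold tau."""
    if ref == alt:
        return 0.0, False
    score = grantham_distance(ref, alt)
    return score, score >= tau


def frequency_filter(
    variant: MissenseVariant,
    max_freq: float = DEFAULT_MAX_FREQ,
    missing: str = "pass",
) -> bool:
    """True when the variant is rare enough to be a disease candidate.

    Class-based frequencies pass unless the class is at/above the threshold
    class; numeric frequencies are compared directly. Singletons always pass.
    """
    f = variant.frequency
    if f is None:
        if missing == "pass":
            warnings.warn(f"{variant.label}: no frequency; passing filter")
            return True
        return False
    if isinstance(f, FrequencyClass):
        if f is FrequencyClass.ABOVE_1E3:
            return max_freq > 1e-3
        if f is FrequencyClass.BETWEEN_1E4_1E3:
            return max_freq >= 1e-3
        if f is FrequencyClass.BELOW_1E4:
            return max_freq >= 1e-4
        return True  # singleton
    return float(f) < max_freq


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

#: PGM1 structural domain boundaries (native residues, closed intervals).
PGM1_DOMAINS = {1: (1, 191), 2: (192, 304), 3: (305, 421), 4: (422, 562)}


@dataclass(frozen=True)
class VariantClassification:
    variant: MissenseVariant
    category: Category
    physchem_score: float
    physchem_significant: bool
    rare: bool
    mapped_anchor: tuple[str, int] | None
    domain: int | None
    discarded: bool = False


def _domain_columns(pm: PositionMap, reference_protein: str = "PGM1") -> list[int] | None:
    """Alignment columns of the PGM1 domain 2/3/4 start positions.

    Returns ``None`` when the reference protein (or a boundary residue) is
    absent from the alignment, in which case domains are not assigned.
    """
    if reference_protein not in pm.proteins:
        return None
    cols = []
    for d in (2, 3, 4):
        start = PGM1_DOMAINS[d][0]
        col = pm.column_of(reference_protein, start)
        if col is None:
            return None
        cols.append(col)
    return cols


_UNSET = object()


def assign_domain(
    pm: PositionMap, protein: str, position: int, boundary_cols=_UNSET
) -> int | None:
    """Structural domain (1-4) via PGM1 boundaries transferred by column.

    ``None`` when the alignment does not carry the PGM1 domain boundaries.
    """
    if boundary_cols is _UNSET:
        boundary_cols = _domain_columns(pm)
    if boundary_cols is None:
        return None
    if protein == "PGM1":
        for d, (lo, hi) in PGM1_DOMAINS.items():
            if lo <= position <= hi:
                return d
        return None
    col = pm.column_of(protein, position)
    if col is None:
        return None
    domain = 1
    for d, bcol in zip((2, 3, 4), boundary_cols):
        if col >= bcol:
            domain = d
    return domain


def classify_variant(
    variant: MissenseVariant,
    catalog: DiseaseCatalog,
    pm: PositionMap,
    regions: Sequence[FunctionalRegion],
    tau: float = DEFAULT_TAU,
    max_freq: float = DEFAULT_MAX_FREQ,
    _boundary_cols=_UNSET,
) -> VariantClassification:
    """Classify one variant (see module docstring for the category logic)."""
    if variant.protein not in pm.proteins:
        raise KeyError(f"unknown protein {variant.protein!r}")

    score, significant = physchem_change(variant.ref, variant.alt, tau)
    if variant.physchem_override is not None:
        significant = variant.physchem_override
    rare = frequency_filter(variant, max_freq)
    domain = assign_domain(pm, variant.protein, variant.position, _boundary_cols)

    if variant.provenance is Provenance.PATIENT:
        return VariantClassification(
            variant, Category.CONFIRMED, score, significant, rare, None, domain
        )

    # positions of confirmed disease variants sharing the alignment column
    group = pm.group(variant.protein, variant.position)
    anchors = [
        (protein, pos)
        for protein, pos in sorted(group.items())
        if catalog.contains(protein, pos)
    ]
    own_disease = catalog.contains(variant.protein, variant.position)

    if significant and rare:
        if own_disease:
            return VariantClassification(
                variant,
                Category.AT_DISEASE_POSITION,
                score,
                significant,
                rare,
                (variant.protein, variant.position),
                domain,
            )
        if anchors:
            cross = [a for a in anchors if a[0] != variant.protein]
            return VariantClassification(
                variant,
                Category.CORRESPONDS,
                score,
                significant,
                rare,
                cross[0] if cross else anchors[0],
                domain,
            )
        if any(r.contains(pm, variant.protein, variant.position) for r in regions):
            return VariantClassification(
                variant,
                Category.FUNCTIONAL_REGION,
                score,
                significant,
                rare,
                None,
                domain,
            )
    return VariantClassification(
        variant, Category.UNCLASSIFIED, score, significant, rare, None, domain
    )


def classify_all(
    variants: Iterable[MissenseVariant],
    catalog: DiseaseCatalog,
    pm: PositionMap,
    regions: Sequence[FunctionalRegion],
    tau: float = DEFAULT_TAU,
    max_freq: float = DEFAULT_MAX_FREQ,
) -> list[VariantClassification]:
    boundary_cols = _domain_columns(pm)
    return [
        classify_variant(
            v, catalog, pm, regions, tau, max_freq, _boundary_cols=boundary_cols
        )
        for v in variants
    ]


# ---------------------------------------------------------------------------
# summary (the printed-table shape and counts)
# ---------------------------------------------------------------------------

PARALOG_ORDER = ("PGM1", "PGM2", "PGM2L1", "PGM3", "PGM5")


@dataclass
class Summary:
    grid: pd.DataFrame
    counts: dict[str, int]
    classifications: list[VariantClassification]

    def to_markdown(self) -> str:
        lines = [self.grid.to_markdown(), "", "Counts:"]
        for k, v in self.counts.items():
            lines.append(f"- {k}: {v}")
        return "\n".join(lines)


def summarize(
    classifications: Sequence[VariantClassification],
    catalog: DiseaseCatalog | None = None,
) -> Summary:
    """Tabulate classifications into the domain x protein grid plus counts.

    Count definitions follow the source study:

    * ``category1_variants`` - population variants corresponding to a disease
      position at a residue position not itself already a patient position of
      the same protein (``corresponds_to_disease``);
    * ``category2_variants``/``category2_positions`` - active-site-region
      variants and the distinct positions hosting them;
    * ``new_variants_pgm1_pgm3`` - categories 1+2 restricted to PGM1/PGM3;
    * ``new_variants_other_paralogs`` - category 1 restricted to
      PGM2/PGM2L1/PGM5 (the study's conclusion grouping counts only these);
    * ``predicted_variants_total`` - every retained population variant
      (categories 1 + 2 + same-position).
    """
    if catalog is None:
        catalog = DiseaseCatalog.from_variants(
            [c.variant for c in classifications]
        )

    active = [c for c in classifications if not c.discarded]
    cat1 = [c for c in active if c.category is Category.CORRESPONDS]
    cat2 = [c for c in active if c.category is Category.FUNCTIONAL_REGION]
    same_pos = [c for c in active if c.category is Category.AT_DISEASE_POSITION]

    counts = {
        "disease_positions_PGM1": catalog.n_positions("PGM1"),
        "disease_positions_PGM3": catalog.n_positions("PGM3"),
        "disease_positions_total": catalog.n_positions(),
        "category1_variants": len(cat1),
        "category2_variants": len(cat2),
        "category2_positions": len(
            {(c.variant.protein, c.variant.position) for c in cat2}
        ),
        "at_disease_position_variants": len(same_pos),
        "new_variants_pgm1_pgm3": sum(
            1 for c in cat1 + cat2 if c.variant.protein in ("PGM1", "PGM3")
        ),
        "new_variants_other_paralogs": sum(
            1 for c in cat1 if c.variant.protein not in ("PGM1", "PGM3")
        ),
        "predicted_variants_total": len(cat1) + len(cat2) + len(same_pos),
    }

    # catalog-shaped grid: domain x (protein, patient/functional sub-section)
    rows = []
    for domain in (1, 2, 3, 4):
        for section, cats in (
            ("patient/corresponding", (Category.CONFIRMED, Category.CORRESPONDS,
                                       Category.AT_DISEASE_POSITION)),
            ("functional_region", (Category.FUNCTIONAL_REGION,)),
        ):
            row = {"domain": domain, "section": section}
            for protein in PARALOG_ORDER:
                labels = [
                    f"{c.variant.ref}{c.variant.position}{c.variant.alt}"
                    for c in active
                    if c.domain == domain
                    and c.variant.protein == protein
                    and c.category in cats
                ]
                row[protein] = ", ".join(sorted(set(labels), key=_pos_key))
            rows.append(row)
    grid = pd.DataFrame(rows).set_index(["domain", "section"])
    return Summary(grid=grid, counts=counts, classifications=list(classifications))


def _pos_key(label: str) -> tuple[int, str]:
    m = re.search(r"\d+", label)
    return (int(m.group()) if m else 0, label)


def polyphen_hook(
    classifications: Sequence[VariantClassification],
    external_scores: Mapping[tuple[str, int, str, str], float] | None = None,
    benign_cutoff: float = 0.446,
) -> list[VariantClassification]:
    """Apply externally supplied deleteriousness scores (no network calls).

    Variants whose score falls below ``benign_cutoff`` are marked discarded;
    with no score table the classifications pass through unchanged.
    """
    if not external_scores:
        return list(classifications)
    out = []
    for c in classifications:
        v = c.variant
        key = (v.protein, v.position, v.ref, v.alt)
        score = external_scores.get(key)
        if score is not None and score < benign_cutoff:
            out.append(replace(c, discarded=True))
        else:
            out.append(c)
    return out
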