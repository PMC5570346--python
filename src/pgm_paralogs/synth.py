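"""Seeded generators of paralog families, variant tables and expression data.

Every stage of the analysis can be exercised without downloads: families are
simulated under the JTT substitution model on a known tree, with sub-group
motif constraints overwritten after evolution (a deliberate simplification
of purifying selection), one taxon optionally circularly permuted; variant
tables are planted against a synthetic disease catalog; expression matrices
carry one elevated signature tissue per paralog under lognormal noise.

All generators are pure functions of an explicit seed (no global RNG state).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import jtt
from .expression import ExpressionMatrix, Modality
from .grantham import AMINO_ACIDS, grantham_distance
from .msa import Msa
from .permutation import PermutationSpec, circular_permute
from .phylo import PhyloTree, TreeNode, read_newick
from .records import ProteinRecord
from .regions import FunctionalRegion, RegionLabel
from .variants import (
    DiseaseCatalog,
    FrequencyClass,
    MissenseVariant,
    Provenance,
)

#: Default five-paralog backbone with the sister pairs seen in the family.
DEFAULT_TREE = (
    "((PGM1:0.15,PGM5:0.15):0.25,(PGM2:0.15,PGM2L1:0.15):0.25,PGM3:0.55);"
)

#: Sub-group motif constraints (true-alignment coordinates, 1-based closed).
DEFAULT_MOTIFS: dict[RegionLabel, tuple[int, int, dict[str, str]]] = {
    RegionLabel.PHOSPHOSERINE: (151, 158, {
        "PGM1": "TASHNPGG", "PGM2": "TASHNSHG", "PGM2L1": "TASHNRKE",
        "PGM3": "TASHNPAG", "PGM5": "TASHNPGA",
    }),
    RegionLabel.METAL_BINDING: (201, 206, {
        "PGM1": "DGDGDR", "PGM2": "DPDADR", "PGM2L1": "DPDADR",
        "PGM3": "DGDADR", "PGM5": "DGDGDR",
    }),
    RegionLabel.SUGAR_BINDING: (251, 255, {
        "PGM1": "GEESF", "PGM2": "FAFEE", "PGM2L1": "FAFEE",
        "PGM3": "YFEAN", "PGM5": "GEESF",
    }),
    RegionLabel.PO4_BINDING: (301, 312, {
        "PGM1": "RGSGTGKVGSKR", "PGM2": "RSGTPELGAKSK",
        "PGM2L1": "RSGGTEPKLGSK", "PGM3": "RSGTAEDAKRGA",
        "PGM5": "RGSGTSGARVGR",
    }),
}

DEFAULT_PERMUTATION = PermutationSpec(segment_a=(41, 80), segment_b=(81, 120))


@dataclass
class VariantPlan:
    n_disease: int = 6          # synthetic patient positions in PGM1
    n_cat1: int = 8             # planted corresponding variants (other paralogs)
    n_cat2: int = 8             # planted functional-region variants
    n_decoy: int = 10           # variants matching neither criterion
    frequency_weights: tuple[float, float, float] = (0.6, 0.3, 0.1)


@dataclass
class ExpressionPlan:
    tissues: tuple[str, ...] = (
        "liver", "prefrontal cortex", "esophagus", "prostate", "spleen",
        "kidney", "lung", "pancreas", "stomach", "thyroid", "testis", "skin",
    )
    signature: Mapping[str, str] = field(default_factory=lambda: {
        "PGM1": "liver", "PGM2": "spleen", "PGM2L1": "prefrontal cortex",
        "PGM3": "testis", "PGM5": "esophagus",
    })
    base_log_mean: float = 5.0
    sigma: float = 0.5
    fold_change: float = 8.0


@dataclass
class SimulationConfig:
    seed: int = 0
    tree: str = DEFAULT_TREE
    sequence_length: int = 400
    motifs: Mapping[RegionLabel, tuple[int, int, dict[str, str]]] = field(
        default_factory=lambda: dict(DEFAULT_MOTIFS)
    )
    permuted_taxon: str | None = "PGM3"
    permutation: PermutationSpec = DEFAULT_PERMUTATION
    members_per_subgroup: int = 1
    within_subgroup_divergence: float = 0.25
    variant_plan: VariantPlan = field(default_factory=VariantPlan)
    expression_plan: ExpressionPlan = field(default_factory=ExpressionPlan)

    def __post_init__(self) -> None:
        for label, (start, stop, motifs) in self.motifs.items():
            if not 1 <= start <= stop <= self.sequence_length:
                raise ValueError(f"motif span {label} outside sequence")
            for sg, motif in motifs.items():
                if len(motif) != stop - start + 1:
                    raise ValueError(
                        f"motif {label}/{sg} length != span width"
                    )


@dataclass
class GroundTruth:
    tree: PhyloTree
    subgroup_of: dict[str, str]            # taxon -> subgroup
    permuted_taxa: dict[str, PermutationSpec]
    motifs: Mapping[RegionLabel, tuple[int, int, dict[str, str]]]
    path_lengths: pd.DataFrame


@dataclass
class FamilySim:
    records: list[ProteinRecord]           # native sequences (FASTA-ready)
    alignment: Msa                         # true (ungapped) alignment
    truth: GroundTruth


def _expand_tree(tree: PhyloTree, members: int, divergence: float) -> tuple[PhyloTree, dict[str, str]]:
    """Replace each leaf by a star of ``members`` leaves (sub-families)."""
    subgroup_of: dict[str, str] = {}

    def expand(node: TreeNode) -> TreeNode:
        if node.is_leaf:
            if members <= 1:
                subgroup_of[node.name] = node.name
                return node
            children = []
            for k in range(1, members + 1):
                name = f"{node.name}_{k}"
                subgroup_of[name] = node.name
                children.append(TreeNode(name=name, length=divergence))
            return TreeNode(name=None, length=node.length, children=children)
        return TreeNode(name=node.name, length=node.length,
                        children=[expand(c) for c in node.children])

    return PhyloTree(root=expand(tree.root)), subgroup_of


def evolve_on_tree(
    tree: PhyloTree, length: int, rng: np.random.Generator,
    model: jtt.JttModel | None = None,
) -> dict[str, np.ndarray]:
    """Simulate JTT state sequences for every leaf of a tree."""
    model = model or jtt.default_model()
    root_states = rng.choice(20, size=length, p=model.pi)
    out: dict[str, np.ndarray] = {}

    def descend(node: TreeNode, states: np.ndarray) -> None:
        for child in node.children:
            if child.length < 0:
                raise ValueError("branch length < 0")
            p = model.transition_matrix(child.length)
            # cumulative inverse sampling per site, vectorised over states
            cum = np.cumsum(p, axis=1)
            u = rng.random(length)
            new = (u[:, None] > cum[states]).sum(axis=1)
            descend(child, new)
        if node.is_leaf:
            out[node.name] = states

    descend(tree.root, root_states)
    return out


def _path_lengths(tree: PhyloTree) -> pd.DataFrame:
    names = tree.leaf_names()
    dist = {n: {} for n in names}

    def collect(node: TreeNode, depth: float, acc: list) -> list:
        if node.is_leaf:
            return [(node.name, depth)]
        below = []
        groups = []
        for c in node.children:
            g = collect(c, depth + c.length, acc)
            groups.append(g)
            below.extend(g)
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for n1, d1 in groups[a]:
                    for n2, d2 in groups[b]:
                        d = d1 + d2 - 2 * depth
                        dist[n1][n2] = dist[n2][n1] = d
        return below

    collect(tree.root, 0.0, [])
    df = pd.DataFrame(0.0, index=names, columns=names)
    for a in names:
        for b in names:
            if a != b:
                df.loc[a, b] = dist[a][b]
    return df


def simulate_family(cfg: SimulationConfig) -> FamilySim:
    """Simulate a paralog family with known tree, motifs and permutation."""
    rng = np.random.default_rng(cfg.seed)
    backbone = read_newick(cfg.tree)
    tree, subgroup_of = _expand_tree(
        backbone, cfg.members_per_subgroup, cfg.within_subgroup_divergence
    )
    leaf_states = evolve_on_tree(tree, cfg.sequence_length, rng)

    # overwrite motif columns per subgroup (constraint, not selection)
    aligned: dict[str, str] = {}
    for taxon in tree.leaf_names():
        seq = list(jtt.decode(leaf_states[taxon]))
        sg = subgroup_of[taxon]
        for start, stop, motifs in cfg.motifs.values():
            motif = motifs.get(sg)
            if motif:
                seq[start - 1 : stop] = list(motif)
        aligned[taxon] = "".join(seq)

    permuted: dict[str, PermutationSpec] = {}
    records = []
    for taxon in tree.leaf_names():
        seq = aligned[taxon]
        if cfg.permuted_taxon is not None and (
            taxon == cfg.permuted_taxon
            or subgroup_of[taxon] == cfg.permuted_taxon
        ):
            # the aligned layout is the *adjusted* form; recover the native
            # sequence so that re-adjusting with the spec reproduces it
            spec = cfg.permutation
            tmp = ProteinRecord(id=taxon, residues=seq)
            from .msa import _adjusted_spec

            native = circular_permute(tmp, _adjusted_spec(spec))[0].residues
            permuted[taxon] = spec
            records.append(ProteinRecord(id=taxon, residues=native))
        else:
            records.append(ProteinRecord(id=taxon, residues=seq))

    msa = Msa.from_gapped(aligned, permutations=permuted)
    truth = GroundTruth(
        tree=tree,
        subgroup_of=subgroup_of,
        permuted_taxa=permuted,
        motifs=cfg.motifs,
        path_lengths=_path_lengths(tree),
    )
    return FamilySim(records=records, alignment=msa, truth=truth)


def functional_regions_from_motifs(
    cfg: SimulationConfig,
) -> list[FunctionalRegion]:
    """Region definitions (0-based column spans) for the simulated alignment."""
    return [
        FunctionalRegion(label=label, col_start=start - 1, col_stop=stop)
        for label, (start, stop, _) in cfg.motifs.items()
    ]


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

_FREQ_CLASSES = (
    FrequencyClass.SINGLETON,
    FrequencyClass.BELOW_1E4,
    FrequencyClass.BETWEEN_1E4_1E3,
)


def _distant_alt(ref: str, rng: np.random.Generator, min_grantham: float = 100.0) -> str:
    candidates = [a for a in AMINO_ACIDS if a != ref and grantham_distance(ref, a) >= min_grantham]
    if not candidates:
        candidates = [a for a in AMINO_ACIDS if a != ref]
    return candidates[int(rng.integers(len(candidates)))]


@dataclass
class VariantTruth:
    variants: list[MissenseVariant]
    labels: dict[str, str]                 # variant label -> true category
    catalog: DiseaseCatalog


def simulate_variants(cfg: SimulationConfig, family: FamilySim) -> VariantTruth:
    """Plant category-1/category-2/decoy variants against a synthetic catalog.

    Positions are alignment columns translated to each taxon's native
    numbering (the permuted taxon exercises coordinate translation); refs
    always match the native sequence.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    plan = cfg.variant_plan
    taxa = family.alignment.ids()
    anchor_taxon = next(t for t in taxa if family.truth.subgroup_of[t] == "PGM1")
    others = [t for t in taxa if t != anchor_taxon]

    motif_cols = set()
    for start, stop, _ in cfg.motifs.values():
        motif_cols.update(range(start, stop + 1))
    free_cols = [c for c in range(1, cfg.sequence_length + 1) if c not in motif_cols]

    need = plan.n_disease + plan.n_decoy
    if need > len(free_cols) or plan.n_cat2 > len(motif_cols):
        raise ValueError("variant plan exceeds available positions")
    chosen = rng.choice(len(free_cols), size=need, replace=False)
    picks = [free_cols[i] for i in chosen]
    disease_cols = picks[: plan.n_disease]
    decoy_cols = picks[plan.n_disease :]

    def native_pos(taxon: str, column: int) -> int:
        row = family.alignment.row(taxon)
        return row.native_position(column)

    def residue(taxon: str, column: int) -> str:
        return family.alignment.row(taxon).gapped[column - 1]

    def draw_freq() -> FrequencyClass:
        idx = rng.choice(3, p=np.asarray(plan.frequency_weights))
        return _FREQ_CLASSES[int(idx)]

    variants: list[MissenseVariant] = []
    labels: dict[str, str] = {}

    # synthetic patient catalog on the PGM1 anchor
    for col in disease_cols:
        ref = residue(anchor_taxon, col)
        v = MissenseVariant(
            protein=anchor_taxon,
            position=native_pos(anchor_taxon, col),
            ref=ref,
            alt=_distant_alt(ref, rng),
            frequency=FrequencyClass.SINGLETON,
            provenance=Provenance.PATIENT,
        )
        variants.append(v)
        labels[v.label] = "confirmed_disease"

    # category 1: corresponding positions in the other paralogs
    for k in range(plan.n_cat1):
        taxon = others[int(rng.integers(len(others)))]
        col = disease_cols[int(rng.integers(len(disease_cols)))]
        ref = residue(taxon, col)
        v = MissenseVariant(
            protein=taxon,
            position=native_pos(taxon, col),
            ref=ref,
            alt=_distant_alt(ref, rng),
            frequency=draw_freq(),
        )
        if v.label in labels:
            continue
        variants.append(v)
        labels[v.label] = "corresponds_to_disease"

    # category 2: inside motif regions (disease columns are all outside them)
    motif_pool = sorted(motif_cols)
    cat2_sites = rng.choice(len(motif_pool), size=plan.n_cat2, replace=False)
    for idx in cat2_sites:
        col = motif_pool[int(idx)]
        taxon = taxa[int(rng.integers(len(taxa)))]
        ref = residue(taxon, col)
        v = MissenseVariant(
            protein=taxon,
            position=native_pos(taxon, col),
            ref=ref,
            alt=_distant_alt(ref, rng),
            frequency=draw_freq(),
        )
        if v.label in labels:
            continue
        variants.append(v)
        labels[v.label] = "functional_region"

    # decoys: outside regions and catalog columns
    for col in decoy_cols:
        taxon = taxa[int(rng.integers(len(taxa)))]
        ref = residue(taxon, col)
        v = MissenseVariant(
            protein=taxon,
            position=native_pos(taxon, col),
            ref=ref,
            alt=_distant_alt(ref, rng),
            frequency=draw_freq(),
        )
        if v.label in labels:
            continue
        variants.append(v)
        labels[v.label] = "unclassified"

    catalog = DiseaseCatalog.from_variants(variants)
    return VariantTruth(variants=variants, labels=labels, catalog=catalog)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTruth:
    protein: ExpressionMatrix
    rna: ExpressionMatrix
    signature: dict[str, str]


def simulate_expression(cfg: SimulationConfig) -> ExpressionTruth:
    """Lognormal expression with one elevated signature tissue per paralog."""
    plan = cfg.expression_plan
    if plan.sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(cfg.seed + 2)
    paralogs = ("PGM1", "PGM2", "PGM2L1", "PGM3", "PGM5")
    matrices = {}
    for modality in (Modality.PROTEIN_IBAQ, Modality.RNA_FPKM):
        values = np.exp(
            plan.base_log_mean
            + plan.sigma * rng.standard_normal((len(plan.tissues), len(paralogs)))
        )
        df = pd.DataFrame(values, index=list(plan.tissues), columns=list(paralogs))
        for paralog, tissue in plan.signature.items():
            if tissue in df.index:
                df.loc[tissue, paralog] *= plan.fold_change
        matrices[modality] = ExpressionMatrix(data=df, modality=modality)
    return ExpressionTruth(
        protein=matrices[Modality.PROTEIN_IBAQ],
        rna=matrices[Modality.RNA_FPKM],
        signature=dict(plan.signature),
    )
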