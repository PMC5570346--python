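"""End-to-end analysis run over the bundled fixtures or user inputs."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, fixtures
from .permutation import PGM3_SPEC
from .expression import heatmap_matrix, log_transform, row_zscore, top_tissues
from .msa import Msa, build_position_map, identity_matrix
from .phylo import (
    complete_deletion,
    neighbor_joining,
    protein_distance,
    write_distance_matrix,
    write_newick,
)
from .profiles import build_profiles, motif_consensus
from .variants import (
    DEFAULT_MAX_FREQ,
    DEFAULT_TAU,
    classify_all,
    summarize,
)


class StageError(RuntimeError):
    """Pipeline failure tagged with the stage name and an exit code."""

    STAGE_CODES = {
        "inputs": 2, "alignment": 3, "profiles": 4, "phylogeny": 5,
        "variants": 6, "expression": 7, "report": 8,
    }

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.exit_code = self.STAGE_CODES.get(stage, 1)


@dataclass
class RunConfig:
    out_dir: Path = Path("pgm_run")
    seed: int = 0
    tau: float = DEFAULT_TAU
    max_freq: float = DEFAULT_MAX_FREQ
    pseudocount: float = 0.5
    margin: float = 2.0
    distance_model: str = "p_distance"
    cluster_rows: bool = True
    stages: tuple[str, ...] = (
        "alignment", "profiles", "phylogeny", "variants", "expression"
    )
    # optional user inputs; bundled fixtures are used when None
    alignment_path: Path | None = None
    variants_path: Path | None = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def read_reference_alignment(path: Path) -> Msa:
    """Read an aligned FASTA, treating a PGM3 row as permutation-adjusted."""
    from Bio import SeqIO

    ids = [rec.id.split("|")[0] for rec in SeqIO.parse(str(path), "fasta")]
    perms = {"PGM3": PGM3_SPEC} if "PGM3" in ids else None
    return Msa.read(path, permutations=perms)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the staged analysis; returns the summary manifest dictionary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = fixtures.reference_bundle()
    written: list[Path] = []
    summary: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": {
            "tau": cfg.tau, "max_freq": cfg.max_freq,
            "pseudocount": cfg.pseudocount, "margin": cfg.margin,
        },
    }

    try:
        if cfg.alignment_path is not None:
            msa = read_reference_alignment(cfg.alignment_path)
        else:
            msa = bundle.msa
        pm = build_position_map(msa)
    except Exception as exc:
        raise StageError("inputs", str(exc)) from exc

    if "alignment" in cfg.stages:
        try:
            idm = identity_matrix(msa)
            p = out / "identity_matrix.tsv"
            idm.identity.to_csv(p, sep="\t")
            written.append(p)
            p = out / "identity_distance.tsv"
            idm.distance.to_csv(p, sep="\t")
            written.append(p)
            vals = idm.identity.to_numpy()
            summary["identity"] = {
                "mean_offdiag": float(
                    vals[~np.eye(len(vals), dtype=bool)].mean()
                ),
            }
        except Exception as exc:
            raise StageError("alignment", str(exc)) from exc

    if "profiles" in cfg.stages:
        try:
            profiles = build_profiles(
                bundle.sub_alignments, bundle.regions, pm,
                bundle.reference_ids, pseudocount=cfg.pseudocount,
            )
            rows = []
            for prof in profiles:
                for label, rp in prof.regions.items():
                    rows.append({
                        "subgroup": prof.subgroup,
                        "region": label.value,
                        "consensus": rp.consensus,
                        "strict_columns": sum(rp.strict),
                    })
                    p = out / f"pfm_{prof.subgroup}_{label.value}.tsv"
                    rp.frequencies.to_csv(p, sep="\t")
                    written.append(p)
            p = out / "motif_consensus.tsv"
            pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
            written.append(p)
            summary["profiles"] = {
                "subgroups": [prof.subgroup for prof in profiles]
            }
        except Exception as exc:
            raise StageError("profiles", str(exc)) from exc

    if "phylogeny" in cfg.stages:
        try:
            fa = complete_deletion(msa)
            dm = protein_distance(fa, cfg.distance_model)
            p = out / "distances.tsv"
            write_distance_matrix(dm, p)
            written.append(p)
            tree = neighbor_joining(dm)
            newick = write_newick(tree)
            p = out / "tree.nwk"
            p.write_text(newick + "\n")
            written.append(p)
            summary["phylogeny"] = {
                "retained_columns": fa.ncols,
                "model": cfg.distance_model,
                "newick": newick,
            }
        except Exception as exc:
            raise StageError("phylogeny", str(exc)) from exc

    if "variants" in cfg.stages:
        try:
            if cfg.variants_path is not None:
                from .variants import read_variant_table

                variants = read_variant_table(cfg.variants_path)
            else:
                variants = bundle.variants
            cls = classify_all(
                variants, bundle.catalog, pm, bundle.regions,
                tau=cfg.tau, max_freq=cfg.max_freq,
            )
            rep = summarize(cls, bundle.catalog)
            rows = [
                {
                    "variant": c.variant.label,
                    "category": c.category.value,
                    "grantham": c.physchem_score,
                    "significant": c.physchem_significant,
                    "rare": c.rare,
                    "anchor": (
                        f"{c.mapped_anchor[0]}:{c.mapped_anchor[1]}"
                        if c.mapped_anchor else ""
                    ),
                    "domain": c.domain,
                }
                for c in cls
            ]
            p = out / "classifications.tsv"
            pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
            written.append(p)
            p = out / "variant_grid.md"
            p.write_text(rep.to_markdown() + "\n")
            written.append(p)
            summary["variants"] = rep.counts
        except Exception as exc:
            raise StageError("variants", str(exc)) from exc

    if "expression" in cfg.stages:
        try:
            prot = bundle.expression_protein.drop_empty_tissues()
            rna = bundle.expression_rna.drop_empty_tissues()
            logp = log_transform(prot)
            zr = row_zscore(rna)
            hm_p, order_p = heatmap_matrix(logp, cluster_rows=cfg.cluster_rows)
            hm_r, _ = heatmap_matrix(zr, cluster_rows=cfg.cluster_rows)
            p = out / "heatmap_protein_log10.tsv"
            hm_p.to_csv(p, sep="\t")
            written.append(p)
            p = out / "heatmap_rna_zscore.tsv"
            hm_r.to_csv(p, sep="\t")
            written.append(p)
            summary["expression"] = {
                "top_protein_tissue": {
                    paralog: top_tissues(logp, paralog, 1)[0]
                    for paralog in prot.paralogs
                },
                "top_rna_tissue": {
                    paralog: top_tissues(zr, paralog, 1)[0]
                    for paralog in rna.paralogs
                },
                "row_order_protein": order_p,
            }
        except Exception as exc:
            raise StageError("expression", str(exc)) from exc

    try:
        summary["outputs"] = {
            str(p.relative_to(out)): _sha256(p) for p in written
        }
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
    except Exception as exc:
        raise StageError("report", str(exc)) from exc
    return summary
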