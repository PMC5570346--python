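"""Tissue-expression normalisation and summaries.

Protein abundance (iBAQ) and RNA (FPKM) matrices over ~30 human tissues are
log-transformed or row Z-scored (the RNA convention: each tissue row scaled
to mean 0 / sd 1 across the five paralogs) and summarised as ranked tissue
lists and deterministically ordered heat-map matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist


class Modality(str, Enum):
    PROTEIN_IBAQ = "protein_iBAQ"
    RNA_FPKM = "rna_fpkm"


class Transform(str, Enum):
    LOG10 = "log10"
    ROW_ZSCORE = "row_zscore"


@dataclass
class ExpressionMatrix:
    """Tissue x paralog expression values; NaN marks missing measurements."""

    data: pd.DataFrame               # index: tissues, columns: paralogs
    modality: Modality

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float)
        if np.nanmin(values, initial=0.0) < 0:
            raise ValueError("expression values must be non-negative")

    @property
    def tissues(self) -> list[str]:
        return list(self.data.index)

    @property
    def paralogs(self) -> list[str]:
        return list(self.data.columns)

    @classmethod
    def read_tsv(cls, path: str | Path, modality: Modality) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(data=df.astype(float), modality=modality)

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t")

    def drop_empty_tissues(self) -> "ExpressionMatrix":
        """Drop tissues with no measurement for any paralog."""
        keep = self.data.notna().any(axis=1) & (self.data.fillna(0).sum(axis=1) > 0)
        return ExpressionMatrix(data=self.data.loc[keep], modality=self.modality)


@dataclass
class NormalizedMatrix:
    data: pd.DataFrame
    transform: Transform
    modality: Modality
    row_means: pd.Series | None = None
    row_sds: pd.Series | None = None
    constant_rows: list[str] | None = None


def log_transform(m: ExpressionMatrix) -> NormalizedMatrix:
    """log10 of positive entries; zeros become missing (with a warning)."""
    values = m.data.to_numpy(dtype=float).copy()
    zeros = values == 0
    if zeros.any():
        warnings.warn(
            f"{int(zeros.sum())} zero entries treated as missing under log10"
        )
        values[zeros] = np.nan
    out = np.full_like(values, np.nan)
    mask = ~np.isnan(values)
    out[mask] = np.log10(values[mask])
    return NormalizedMatrix(
        data=pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
        transform=Transform.LOG10,
        modality=m.modality,
    )


def row_zscore(m: ExpressionMatrix) -> NormalizedMatrix:
    """Per-row Z-scores with sample sd (n-1) over non-missing entries.

    Constant rows become all-zero (flagged); rows with fewer than two
    non-missing entries are emitted as missing with a warning.
    """
    df = m.data.astype(float)
    out = pd.DataFrame(np.nan, index=df.index, columns=df.columns)
    means, sds, constant = {}, {}, []
    for tissue, row in df.iterrows():
        vals = row.dropna()
        if len(vals) < 2:
            warnings.warn(f"row {tissue!r}: fewer than 2 values; left missing")
            continue
        mu, sd = float(vals.mean()), float(vals.std(ddof=1))
        means[tissue], sds[tissue] = mu, sd
        if sd == 0:
            constant.append(tissue)
            out.loc[tissue, vals.index] = 0.0
        else:
            out.loc[tissue, vals.index] = (vals - mu) / sd
    return NormalizedMatrix(
        data=out,
        transform=Transform.ROW_ZSCORE,
        modality=m.modality,
        row_means=pd.Series(means),
        row_sds=pd.Series(sds),
        constant_rows=constant,
    )


def top_tissues(
    nm: NormalizedMatrix | ExpressionMatrix, paralog: str, k: int | None = None
) -> list[str]:
    """Tissues ranked by descending value for one paralog (ties by label)."""
    data = nm.data if isinstance(nm, (NormalizedMatrix, ExpressionMatrix)) else nm
    if paralog not in data.columns:
        raise KeyError(f"unknown paralog {paralog!r}")
    col = data[paralog].dropna()
    if col.empty:
        warnings.warn(f"no values for {paralog}; empty ranking")
        return []
    ranked = sorted(col.items(), key=lambda kv: (-kv[1], kv[0]))
    names = [t for t, _ in ranked]
    return names if k is None else names[:k]


def heatmap_matrix(
    nm: NormalizedMatrix, cluster_rows: bool = True
) -> tuple[pd.DataFrame, list[str]]:
    """Row-ordered matrix for heat-map export.

    With ``cluster_rows`` the tissues are ordered by average-linkage
    hierarchical clustering on Euclidean distances (missing entries filled
    with the row mean of zero under Z-scoring); leaf order is made
    deterministic by recursively placing the subtree containing the smallest
    tissue label first.
    """
    if not cluster_rows or len(nm.data) < 3:
        return nm.data.copy(), list(nm.data.index)
    filled = nm.data.fillna(0.0).to_numpy(dtype=float)
    z = linkage(pdist(filled, metric="euclidean"), method="average")
    n = len(nm.data)
    labels = list(nm.data.index)

    # deterministic leaf ordering: subtree with the smallest label first
    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        left, right = int(z[node - n, 0]), int(z[node - n, 1])
        l1, l2 = leaves(left), leaves(right)
        if min(labels[i] for i in l2) < min(labels[i] for i in l1):
            l1, l2 = l2, l1
        return l1 + l2

    order = leaves(2 * n - 2)
    ordered_labels = [labels[i] for i in order]
    return nm.data.loc[ordered_labels], ordered_labels
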