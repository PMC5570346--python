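"""Distance-based phylogenetics and likelihood scoring under the JTT model.

Implements the classical pipeline used for the paralog family: complete
gap deletion, pairwise protein distances (p-distance, Poisson-corrected, or
maximum-likelihood pairwise times under JTT), Saitou-Nei neighbor joining,
and Felsenstein-pruning log-likelihood of a fixed tree.  Heuristic maximum
likelihood topology search is deliberately out of scope: trees are built by
NJ and scored as given.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import jtt
from .msa import Msa

_CANONICAL = set(jtt.AA_ORDER)


# ---------------------------------------------------------------------------
# tree structure + newick IO
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of a rooted representation of an (unrooted) tree."""

    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def copy(self) -> "TreeNode":
        return TreeNode(
            name=self.name,
            length=self.length,
            children=[c.copy() for c in self.children],
        )


@dataclass
class PhyloTree:
    """Unrooted tree held as a trifurcating (or deeper) rooted structure."""

    root: TreeNode
    log_likelihood: float | None = None

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def copy(self) -> "PhyloTree":
        return PhyloTree(root=self.root.copy(), log_likelihood=self.log_likelihood)


class NewickParseError(ValueError):
    pass


def write_newick(tree: PhyloTree) -> str:
    """Serialise with branch lengths at 10 significant digits."""

    def fmt(node: TreeNode, top: bool) -> str:
        if node.is_leaf:
            body = node.name or ""
        else:
            body = "(" + ",".join(fmt(c, False) for c in node.children) + ")"
            if node.name:
                body += node.name
        if top:
            return body
        return f"{body}:{node.length:.10g}"

    return fmt(tree.root, True) + ";"


def read_newick(text: str) -> PhyloTree:
    """Parse a newick string via scikit-bio, reporting the error position."""
    import skbio

    try:
        sk = skbio.TreeNode.read(io.StringIO(text.strip()), format="newick")
    except Exception as exc:
        raise NewickParseError(f"malformed newick near position 0: {exc}") from exc

    def convert(node) -> TreeNode:
        return TreeNode(
            name=node.name,
            length=float(node.length) if node.length is not None else 0.0,
            children=[convert(c) for c in node.children],
        )

    return PhyloTree(root=convert(sk))


# ---------------------------------------------------------------------------
# alignment filtering
# ---------------------------------------------------------------------------

@dataclass
class FilteredAlignment:
    """Complete-deletion view of an alignment (no gaps/ambiguity retained)."""

    ids: list[str]
    columns: list[int]          # retained source column indices (0-based)
    matrix: np.ndarray          # (n_rows, n_retained) JTT state indices

    @property
    def ncols(self) -> int:
        return len(self.columns)


def complete_deletion(msa: Msa) -> FilteredAlignment:
    """Drop every column containing a gap or non-canonical residue."""
    ids = msa.ids()
    rows = [r.gapped for r in msa.rows]
    retained = []
    states = []
    for col in range(msa.ncols):
        column = [row[col] for row in rows]
        if all(c in _CANONICAL for c in column):
            retained.append(col)
            states.append([jtt.AA_ORDER.index(c) for c in column])
    if not retained:
        raise ValueError(
            "complete deletion removed every column; consider pairwise deletion"
        )
    return FilteredAlignment(
        ids=ids,
        columns=retained,
        matrix=np.array(states, dtype=int).T,
    )


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12, equal_nan=True):
            raise ValueError("distance matrix not symmetric")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DistanceMatrix":
        return cls(labels=list(df.index), values=df.to_numpy(dtype=float))


def _jtt_pair_distance(si: np.ndarray, sj: np.ndarray, model: jtt.JttModel) -> float:
    """ML evolutionary time for one sequence pair under JTT."""
    pairs, counts = np.unique(si * 20 + sj, return_counts=True)
    ii, jj = pairs // 20, pairs % 20
    log_pi = np.log(model.pi)

    def neg_loglik(t: float) -> float:
        p = model.transition_matrix(t)
        probs = np.clip(p[ii, jj], 1e-300, None)
        return -float(np.sum(counts * (log_pi[ii] + np.log(probs))))

    if np.all(ii == jj):
        return 0.0
    res = minimize_scalar(neg_loglik, bounds=(1e-8, 50.0), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


def protein_distance(fa: FilteredAlignment, model: str = "p_distance") -> DistanceMatrix:
    """Pairwise distances over the gap-free alignment.

    Models: ``p_distance`` (mismatch fraction), ``poisson``
    (``-ln(1 - p)``), ``jtt_ml_pair`` (ML pairwise time under JTT).
    """
    n = len(fa.ids)
    if n < 2 or fa.ncols < 1:
        raise ValueError("need >= 2 sequences and >= 1 column")
    d = np.zeros((n, n))
    jm = jtt.default_model() if model == "jtt_ml_pair" else None
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = fa.matrix[i], fa.matrix[j]
            if model == "jtt_ml_pair":
                dij = _jtt_pair_distance(si, sj, jm)
            else:
                p = float(np.mean(si != sj))
                if model == "p_distance":
                    dij = p
                elif model == "poisson":
                    if p >= 1.0:
                        warnings.warn("p = 1: Poisson distance is infinite")
                        dij = np.inf
                    else:
                        dij = -np.log(1.0 - p)
                else:
                    raise ValueError(f"unknown distance model {model!r}")
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(labels=list(fa.ids), values=d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Deterministic: Q-matrix ties are broken by the lexicographically smallest
    (i, j) label-index pair.  Negative branch lengths are clamped to zero with
    the deficit moved to the sibling branch.  The result is unrooted
    (trifurcating root).
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dm.labels]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest Q; ties -> smallest (i, j)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                key = (q[a, b], a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sibling
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode(
            children=[
                TreeNode(name=nodes[i].name, length=li, children=nodes[i].children),
                TreeNode(name=nodes[j].name, length=lj, children=nodes[j].children),
            ]
        )
        # distances from the new node
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        k = len(nodes)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[k, : k] = new_row[: k]
        d[: k, k] = new_row[: k]
        d[k, k] = 0.0
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [k]

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    children = []
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        node = nodes[idx]
        children.append(TreeNode(name=node.name, length=max(ln, 0.0),
                                 children=node.children))
    return PhyloTree(root=TreeNode(children=children))


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def tree_loglik(
    tree: PhyloTree,
    fa: FilteredAlignment,
    model: jtt.JttModel | None = None,
) -> float:
    """Felsenstein-pruning log-likelihood of a fixed tree under JTT.

    Branch lengths are taken as given; equilibrium frequencies weight the
    root.  Because the model is reversible the value is invariant to the
    rooting of the (unrooted) tree.
    """
    model = model or jtt.default_model()
    leaf_index = {name: idx for idx, name in enumerate(fa.ids)}
    tree_leaves = tree.leaf_names()
    if sorted(tree_leaves) != sorted(fa.ids):
        raise ValueError(
            f"tree leaves {sorted(tree_leaves)} != alignment rows {sorted(fa.ids)}"
        )
    ncols = fa.ncols

    def partial(node: TreeNode) -> np.ndarray:
        """(ncols, 20) conditional likelihoods below ``node``."""
        if node.is_leaf:
            lik = np.zeros((ncols, 20))
            states = fa.matrix[leaf_index[node.name]]
            lik[np.arange(ncols), states] = 1.0
            return lik
        lik = np.ones((ncols, 20))
        for child in node.children:
            p = model.transition_matrix(child.length)
            lik *= partial(child) @ p.T
        return lik

    root_lik = partial(tree.root)
    site = root_lik @ model.pi
    if np.any(site <= 0):
        return -np.inf
    return float(np.sum(np.log(site)))


# ---------------------------------------------------------------------------
# PHYLIP-style square distance IO
# ---------------------------------------------------------------------------

def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(dm.labels)}\n")
        for label, row in zip(dm.labels, dm.values):
            fh.write(label + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


def read_distance_matrix(path) -> DistanceMatrix:
    with open(path) as fh:
        n = int(fh.readline().strip())
        labels, rows = [], []
        for _ in range(n):
            parts = fh.readline().split()
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return DistanceMatrix(labels=labels, values=np.array(rows))
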