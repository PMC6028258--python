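"""p-distance matrices and neighbor-joining trees between individuals.

The genetic distance between two individuals is the p-distance: the
proportion of mismatching genotype calls among sites where both have
data (haploid genotype comparison, appropriate for male X and Y).  Trees
are built with the Saitou-Nei neighbor-joining algorithm; on an additive
distance matrix NJ recovers the generating tree and branch lengths
exactly.  Negative branch lengths are clamped to zero, and ties in the
join criterion break on the lowest (row, column) index so results are
reproducible regardless of floating-point quirks.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(np.diag(m)[~np.isnan(np.diag(m))], 0.0):
            raise ValueError("diagonal must be zero")
        self.matrix = m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


@dataclass
class TreeNode:
    """A node of an (unrooted, represented rooted) phylogenetic tree."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    annotation: dict = field(default_factory=dict)

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        return [leaf for child, _ in self.children for leaf in child.leaves()]

    def leaf_labels(self) -> list[str]:
        return [l.label for l in self.leaves()]

    def to_newick(self, include_annotations: bool = False) -> str:
        return self._newick(include_annotations) + ";"

    def _newick(self, ann: bool) -> str:
        comment = ""
        if ann and self.annotation:
            inner = ",".join(f"{k}={v}" for k, v in sorted(self.annotation.items()))
            comment = f"[&{inner}]"
        if not self.children:
            return f"{self.label}{comment}"
        parts = ",".join(f"{c._newick(ann)}:{l:.10g}" for c, l in self.children)
        return f"({parts}){self.label or ''}{comment}"

    def leaf_path_lengths(self) -> pd.DataFrame:
        """Pairwise patristic distances between leaves (additivity check)."""
        dists: dict[str, dict[str, float]] = {}

        def walk(node: TreeNode) -> dict[str, float]:
            if not node.children:
                return {node.label: 0.0}
            below: list[dict[str, float]] = []
            for child, length in node.children:
                sub = walk(child)
                below.append({k: v + length for k, v in sub.items()})
            for i in range(len(below)):
                for j in range(i + 1, len(below)):
                    for a, da in below[i].items():
                        for b, db in below[j].items():
                            dists.setdefault(a, {})[b] = da + db
                            dists.setdefault(b, {})[a] = da + db
            return {k: v for d in below for k, v in d.items()}

        walk(self)
        labels = self.leaf_labels()
        out = pd.DataFrame(0.0, index=labels, columns=labels)
        for a, row in dists.items():
            for b, d in row.items():
                out.loc[a, b] = d
        return out


def p_distance(genotypes: pd.DataFrame) -> DistanceMatrix:
    """Pairwise p-distances from a (individuals x sites) genotype table.

    Genotypes may be any comparable values (allele characters, 0/1 codes);
    NaN marks missing data.  Each pairwise distance uses only the sites
    non-missing in both individuals; a pair sharing no sites gets NaN.
    """
    if len(genotypes) < 2:
        raise ValueError("need at least two individuals")
    ids = list(genotypes.index)
    vals = genotypes.to_numpy(dtype=object)
    missing = pd.isna(genotypes).to_numpy()
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~missing[i] & ~missing[j]
            if not shared.any():
                mat[i, j] = mat[j, i] = np.nan
                continue
            diff = np.sum(vals[i, shared] != vals[j, shared])
            mat[i, j] = mat[j, i] = diff / shared.sum()
    return DistanceMatrix(ids, mat)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining on a finite distance matrix.

    Iteratively joins the pair (i, j) minimizing
    Q(i, j) = (r - 2) d(i, j) - R_i - R_j   (R_i = row sum, r = active taxa),
    with branch lengths l_i = d(i,j)/2 + (R_i - R_j) / (2(r - 2)) and
    l_j = d(i,j) - l_i, negative lengths clamped to zero.  Returns the
    final three-branch internal node (the conventional representation of
    the unrooted NJ tree).
    """
    d = dm.matrix.copy()
    if np.isnan(d).any():
        raise ValueError("distance matrix contains missing entries")
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(label=i) for i in dm.ids]

    while len(nodes) > 3:
        r = len(nodes)
        rowsum = d.sum(axis=1)
        q = (r - 2) * d - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (row, column) index among minima, for determinism
        best = np.inf
        bi = bj = -1
        for i in range(r):
            for j in range(i + 1, r):
                if q[i, j] < best - 1e-12:
                    best, bi, bj = q[i, j], i, j
        li = d[bi, bj] / 2 + (rowsum[bi] - rowsum[bj]) / (2 * (r - 2))
        lj = d[bi, bj] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode(children=[(nodes[bi], li), (nodes[bj], lj)])

        new_d = np.zeros((r - 1, r - 1))
        keep = [k for k in range(r) if k not in (bi, bj)]
        for a, ka in enumerate(keep):
            for b, kb in enumerate(keep):
                new_d[a, b] = d[ka, kb]
        for a, ka in enumerate(keep):
            dk = (d[bi, ka] + d[bj, ka] - d[bi, bj]) / 2
            new_d[a, r - 2] = new_d[r - 2, a] = max(dk, 0.0)
        nodes = [nodes[k] for k in keep] + [parent]
        d = new_d

    # three remaining nodes: solve the three-point formulas exactly
    la = (d[0, 1] + d[0, 2] - d[1, 2]) / 2
    lb = (d[0, 1] + d[1, 2] - d[0, 2]) / 2
    lc = (d[0, 2] + d[1, 2] - d[0, 1]) / 2
    root = TreeNode(children=[(nodes[0], max(la, 0.0)),
                              (nodes[1], max(lb, 0.0)),
                              (nodes[2], max(lc, 0.0))])
    return root


def annotate_leaves(
    tree: TreeNode,
    table: pd.DataFrame,
    id_column: str = "individual",
) -> pd.DataFrame:
    """Attach per-individual values (copy numbers, labels) to tree leaves.

    ``table`` holds one row per individual; every other column becomes a
    leaf annotation.  Ids absent from the tree draw a warning and are
    skipped; un-annotated leaves are left untouched.  Returns the side-car
    table (one row per annotated leaf) that accompanies the Newick export.
    """
    leaves = {l.label: l for l in tree.leaves()}
    rows = []
    for _, row in table.iterrows():
        ind = row[id_column]
        if ind not in leaves:
            warnings.warn(f"annotation id {ind!r} is not a leaf of the tree")
            continue
        ann = {k: row[k] for k in table.columns if k != id_column}
        leaves[ind].annotation.update(ann)
        rows.append({id_column: ind, **ann})
    return pd.DataFrame(rows)


def write_tree(tree: TreeNode, path: str | os.PathLike, annotations: pd.DataFrame | None = None) -> None:
    """Write Newick (with [&k=v] comments when annotated) plus side-car TSV."""
    with open(path, "w") as fh:
        fh.write(tree.to_newick(include_annotations=True) + "\n")
    if annotations is not None and len(annotations):
        annotations.to_csv(str(path) + ".annotations.tsv", sep="\t", index=False)
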