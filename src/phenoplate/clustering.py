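"""Centred-Pearson distances, from-scratch UPGMA agglomeration, and
Cluster 3.0 / TreeView (CDT + GTR) and Newick export.

The agglomeration is average linkage in the size-weighted (UPGMA
proper, Sokal–Michener) form: the most similar pair of profiles is
merged first, and the distance from a merged cluster to any other node
is the member-count-weighted mean of its children's distances.  The
scan is phrased over distances d = 1 − r (minimum distance ≡ maximum
similarity), which is algebraically identical to scanning a similarity
matrix for its highest value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .scoring import LogRatioMatrix

_SYM_TOL = 1e-12


@dataclass
class DistanceMatrix:
    """Symmetric centred-Pearson distance matrix over strain profiles.

    Entries are d(i, j) = 1 − r(i, j) ∈ [0, 2]; the diagonal is zero.
    ``zero_variance`` lists rows with flat profiles, whose correlation
    with anything is undefined and is treated as 0 (distance 1).
    """

    ids: list[str]
    values: np.ndarray
    zero_variance: set = field(default_factory=set)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValidationError(
                f"DistanceMatrix: shape {v.shape} does not match {n} ids"
            )
        if not np.allclose(v, v.T, rtol=0, atol=_SYM_TOL):
            raise ValidationError("DistanceMatrix: not symmetric")
        if np.any(np.abs(np.diag(v)) > _SYM_TOL):
            raise ValidationError("DistanceMatrix: nonzero diagonal")
        if np.any(v < -_SYM_TOL) or np.any(v > 2 + 1e-9):
            raise ValidationError("DistanceMatrix: entries outside [0, 2]")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)


def _pairwise_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r of two vectors; 0 when either has zero variance."""
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(np.sum(xc * xc)))
    sy = float(np.sqrt(np.sum(yc * yc)))
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float(np.dot(xc, yc) / (sx * sy))


def centred_pearson_distance(matrix) -> DistanceMatrix:
    """1 − Pearson correlation between strain profiles, pairwise-complete.

    ``matrix`` may be a :class:`~phenoplate.scoring.LogRatioMatrix`, a
    DataFrame (rows = strains) or a plain 2-D array.  Missing cells are
    handled by correlating over the columns both rows share (minimum
    2); a row with fewer than 2 usable columns is an error.  Rows with
    zero variance are flagged and placed at distance 1 from everything
    (correlation treated as 0).
    """
    if isinstance(matrix, LogRatioMatrix):
        df = matrix.values
    elif isinstance(matrix, pd.DataFrame):
        df = matrix
    else:
        arr = np.asarray(matrix, dtype=float)
        df = pd.DataFrame(arr, index=[str(i) for i in range(arr.shape[0])])
    if df.shape[0] < 2:
        raise ValidationError("centred_pearson_distance: need at least 2 rows")
    ids = [str(i) for i in df.index]
    data = df.to_numpy(dtype=float)
    present = np.isfinite(data)
    usable_counts = present.sum(axis=1)
    for i, c in enumerate(usable_counts):
        if c < 2:
            raise ValidationError(
                f"centred_pearson_distance: row {ids[i]!r} has {c} usable "
                "columns (need >= 2)"
            )
    zero_var = set()
    for i in range(len(ids)):
        vals = data[i, present[i]]
        if np.ptp(vals) == 0:
            zero_var.add(ids[i])

    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = present[i] & present[j]
            if shared.sum() < 2:
                raise ValidationError(
                    f"centred_pearson_distance: rows {ids[i]!r} and {ids[j]!r} "
                    f"share {int(shared.sum())} columns (need >= 2)"
                )
            r = _pairwise_pearson(data[i, shared], data[j, shared])
            d[i, j] = d[j, i] = min(max(1.0 - r, 0.0), 2.0)
    return DistanceMatrix(ids=ids, values=d, zero_variance=zero_var)


@dataclass
class Merge:
    """One agglomeration step.  Node numbering: leaves are 0..n−1 in
    input order; the cluster formed by merge k (0-based) is node n+k."""

    left: int
    right: int
    height: float
    count: int


@dataclass
class Dendrogram:
    """UPGMA merge tree over strains."""

    leaf_ids: list[str]
    merges: list[Merge]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def root(self) -> int:
        return self.n_leaves + len(self.merges) - 1

    def validate(self) -> None:
        n = self.n_leaves
        if len(self.merges) != n - 1:
            raise ValidationError(
                f"Dendrogram: {len(self.merges)} merges for {n} leaves"
            )
        heights = [m.height for m in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValidationError("Dendrogram: merge heights decrease")
        used = set()
        for m in self.merges:
            for child in (m.left, m.right):
                if child in used:
                    raise ValidationError(f"Dendrogram: node {child} used twice")
                used.add(child)


def upgma(dist: DistanceMatrix) -> Dendrogram:
    """Size-weighted average-linkage agglomeration of a distance matrix.

    At each step the pair of active nodes at minimum distance (the most
    similar pair) is merged at that distance; the new cluster's distance
    to any other node k is (nᵢ·d(k,i) + nⱼ·d(k,j)) / (nᵢ + nⱼ).  Ties
    break to the pair whose (older, younger) creation indices are
    smallest, and the older node becomes the left child, which makes the
    tree deterministic for any input.
    """
    n = dist.n
    if n < 2:
        raise ValidationError("upgma: need at least 2 items")
    # distances between active nodes, keyed by creation index
    d = {
        (i, j): dist.values[i, j] for i in range(n) for j in range(i + 1, n)
    }
    size = {i: 1 for i in range(n)}
    active = list(range(n))
    merges: list[Merge] = []
    next_node = n
    while len(active) > 1:
        best = None
        best_d = np.inf
        for a_pos, i in enumerate(active):
            for j in active[a_pos + 1 :]:
                dij = d[(i, j)]
                if dij < best_d:
                    best_d = dij
                    best = (i, j)
        i, j = best  # i older than j by construction of `active`
        new_size = size[i] + size[j]
        for k in active:
            if k in (i, j):
                continue
            dk = (size[i] * d[_key(k, i)] + size[j] * d[_key(k, j)]) / new_size
            d[_key(k, next_node)] = dk
        merges.append(Merge(left=i, right=j, height=best_d, count=new_size))
        size[next_node] = new_size
        active = [k for k in active if k not in (i, j)] + [next_node]
        next_node += 1
    dend = Dendrogram(leaf_ids=list(dist.ids), merges=merges)
    dend.validate()
    return dend


def _key(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a < b else (b, a)


def leaf_order(dend: Dendrogram) -> list[str]:
    """Leaf ids in depth-first order, left child first."""
    n = dend.n_leaves
    order: list[str] = []
    stack = [dend.root]
    while stack:
        node = stack.pop()
        if node < n:
            order.append(dend.leaf_ids[node])
        else:
            m = dend.merges[node - n]
            stack.append(m.right)  # popped after left
            stack.append(m.left)
    return order


def cut(dend: Dendrogram, k: int) -> dict[str, int]:
    """Cut the tree into ``k`` flat clusters by undoing the last k−1 merges.

    Returns a mapping from leaf id to a cluster label in 0..k−1, with
    labels assigned in order of each cluster's first leaf.
    """
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ValidationError(f"cut: k={k} outside 1..{n}")
    parent = list(range(n + len(dend.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for idx, m in enumerate(dend.merges[: n - k]):
        node = n + idx
        parent[find(m.left)] = node
        parent[find(m.right)] = node

    labels: dict[str, int] = {}
    root_label: dict[int, int] = {}
    for leaf in range(n):
        r = find(leaf)
        if r not in root_label:
            root_label[r] = len(root_label)
        labels[dend.leaf_ids[leaf]] = root_label[r]
    return labels


def cophenetic_matrix(dend: Dendrogram) -> np.ndarray:
    """Pairwise cophenetic distances: height of the lowest common ancestor."""
    n = dend.n_leaves
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    for idx, m in enumerate(dend.merges):
        left = members.pop(m.left)
        right = members.pop(m.right)
        for a in left:
            for b in right:
                coph[a, b] = coph[b, a] = m.height
        members[n + idx] = left + right
    return coph


# ---------------------------------------------------------------------------
# export


def _node_name(node: int, n: int) -> str:
    return f"GENE{node}X" if node < n else f"NODE{node - n + 1}X"


def write_cdt_gtr(
    dend: Dendrogram, matrix: LogRatioMatrix, basename: str | Path
) -> tuple[Path, Path]:
    """Write Cluster 3.0-style ``.cdt`` and ``.gtr`` files for TreeView.

    The GTR file lists merges in order as ``NODEkX child1 child2
    similarity`` with similarity = 1 − merge height (the convention for
    correlation-based runs); leaves are named ``GENEiX`` by input row
    index.  The CDT file carries the log-ratio matrix with rows in the
    dendrogram's leaf order, values at 6 significant digits, missing
    cells blank.
    """
    if set(dend.leaf_ids) != set(matrix.strain_ids):
        raise ValidationError("write_cdt_gtr: dendrogram leaves != matrix rows")
    basename = Path(basename)
    gtr_path = basename.with_suffix(".gtr")
    cdt_path = basename.with_suffix(".cdt")
    n = dend.n_leaves

    with open(gtr_path, "w", encoding="utf-8", newline="\n") as fh:
        for idx, m in enumerate(dend.merges):
            fh.write(
                f"NODE{idx + 1}X\t{_node_name(m.left, n)}\t"
                f"{_node_name(m.right, n)}\t{1.0 - m.height:.6g}\n"
            )

    index_of = {sid: i for i, sid in enumerate(dend.leaf_ids)}
    with open(cdt_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("GID\tUNIQID\tNAME\t" + "\t".join(matrix.condition_ids) + "\n")
        for sid in leaf_order(dend):
            row = matrix.values.loc[sid]
            cells = ["" if not np.isfinite(v) else f"{v:.6g}" for v in row]
            fh.write(f"GENE{index_of[sid]}X\t{sid}\t{sid}\t" + "\t".join(cells) + "\n")
    return cdt_path, gtr_path


def to_newick(dend: Dendrogram) -> str:
    """Rooted Newick string with ultrametric branch lengths.

    A node at merge height h sits at depth h/2 from the leaves, so every
    leaf is equidistant from the root and two leaves' path length equals
    their cophenetic distance.
    """
    n = dend.n_leaves

    def height(node: int) -> float:
        return 0.0 if node < n else dend.merges[node - n].height

    def render(node: int, parent_h: float) -> str:
        blen = (parent_h - height(node)) / 2.0
        if node < n:
            return f"{dend.leaf_ids[node]}:{blen:.10g}"
        m = dend.merges[node - n]
        inner = f"({render(m.left, m.height)},{render(m.right, m.height)})"
        return f"{inner}:{blen:.10g}"

    root = dend.root
    m = dend.merges[root - n]
    return f"({render(m.left, m.height)},{render(m.right, m.height)});"


def write_newick(dend: Dendrogram, path: str | Path) -> Path:
    """Write the dendrogram as a rooted ultrametric Newick file."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(to_newick(dend) + "\n")
    return path
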