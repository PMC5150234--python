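"""Distance-based phylogenetics: Jukes-Cantor correction, neighbor
joining and bootstrap support.

Implements the classic Saitou-Nei agglomeration with deterministic
tie-breaking (smallest (i, j) index pair in the Q matrix) so the same
matrix always yields the same tree.  Negative branch lengths are clamped
to zero with the deficit shifted to the sibling edge; the raw values are
kept in a diagnostic field on each edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .community import DistanceMatrix, SequenceRecord

__all__ = [
    "SaturationError",
    "jukes_cantor",
    "Node",
    "PhyloTree",
    "nj_tree",
    "alignment_distances",
    "bootstrap_support",
]

_ACGT = np.frombuffer(b"ACGT", dtype="S1")


class SaturationError(ValueError):
    """p-distance at or beyond 0.75: the Jukes-Cantor correction diverges."""


def jukes_cantor(p):
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3).

    Accepts a scalar or array of fractional p-distances in [0, 0.75);
    saturated values raise :class:`SaturationError`.
    """
    arr = np.asarray(p, dtype=float)
    if (arr < 0).any():
        raise ValueError("p-distance must be >= 0")
    if (arr >= 0.75).any():
        raise SaturationError(
            "p-distance >= 0.75 is saturated; Jukes-Cantor is undefined"
        )
    d = -0.75 * np.log1p(-(4.0 / 3.0) * arr)
    return float(d) if np.isscalar(p) or arr.ndim == 0 else d


@dataclass
class Node:
    """Tree node; ``children`` holds (child, length, raw_length) edges."""

    name: str | None = None
    children: list[tuple["Node", float, float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.name])
        out: set[str] = set()
        for child, _, _ in self.children:
            out |= child.leaf_names()
        return frozenset(out)


def _newick(node: Node, with_support: bool) -> str:
    if node.is_leaf:
        return node.name
    parts = []
    for child, length, _ in node.children:
        label = _newick(child, with_support)
        if not child.is_leaf and with_support and child.support is not None:
            label += f"{int(round(child.support))}"
        parts.append(f"{label}:{length:.10g}")
    return f"({','.join(parts)})"


@dataclass
class PhyloTree:
    """Unrooted tree represented with a trifurcating root node."""

    root: Node

    @property
    def leaves(self) -> frozenset[str]:
        return self.root.leaf_names()

    def to_newick(self, with_support: bool = False) -> str:
        return _newick(self.root, with_support) + ";"

    def _internal_nodes(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            for child, _, _ in node.children:
                if not child.is_leaf:
                    yield child
                    stack.append(child)

    def bipartitions(self) -> frozenset[frozenset[str]]:
        """Non-trivial splits, each normalized to the side *not*
        containing the lexicographically smallest leaf."""
        all_leaves = self.leaves
        ref = min(all_leaves)
        out = set()
        for node in self._internal_nodes():
            side = node.leaf_names()
            if ref in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(side)
        return frozenset(out)

    def supports(self) -> dict[frozenset[str], float]:
        all_leaves = self.leaves
        ref = min(all_leaves)
        out = {}
        for node in self._internal_nodes():
            if node.support is None:
                continue
            side = node.leaf_names()
            if ref in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                out[side] = node.support
        return out

    def path_distances(self) -> DistanceMatrix:
        """Leaf-to-leaf path lengths along tree branches.

        For an additive input matrix, NJ reconstruction makes this an
        identity map.  Distances here may exceed 1, so the result is a
        plain labelled matrix, not validated as fractional.
        """
        adj: dict[int, list[tuple[int, float]]] = {}
        names: dict[int, str] = {}

        def walk(node: Node) -> int:
            nid = id(node)
            adj.setdefault(nid, [])
            if node.is_leaf:
                names[nid] = node.name
            for child, length, _ in node.children:
                cid = walk(child)
                adj[nid].append((cid, length))
                adj[cid].append((nid, length))
            return nid

        walk(self.root)
        leaf_ids = sorted(names, key=lambda i: names[i])
        labels = tuple(names[i] for i in leaf_ids)
        n = len(leaf_ids)
        dist = np.zeros((n, n))
        index = {nid: k for k, nid in enumerate(leaf_ids)}
        for src in leaf_ids:
            seen = {src: 0.0}
            stack = [src]
            while stack:
                cur = stack.pop()
                for nxt, w in adj[cur]:
                    if nxt not in seen:
                        seen[nxt] = seen[cur] + w
                        stack.append(nxt)
            i = index[src]
            for dst in leaf_ids:
                dist[i, index[dst]] = seen[dst]
        return _LabelledMatrix(labels, dist)


@dataclass(frozen=True)
class _LabelledMatrix:
    """Symmetric labelled matrix without the [0, 1] range constraint."""

    ids: tuple[str, ...]
    values: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def _clamp_pair(li: float, lj: float) -> tuple[float, float, float, float]:
    """Clamp a sibling edge pair to >= 0, shifting the deficit across."""
    ri, rj = li, lj
    if li < 0:
        lj = max(lj + li, 0.0)
        li = 0.0
    elif lj < 0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj, ri, rj


def nj_tree(dm) -> PhyloTree:
    """Neighbor joining (Saitou-Nei) from a distance matrix.

    ``dm`` is any object with ``ids`` and a square ``values`` array.
    Ties in the Q criterion break on the smallest (i, j) pair.  The
    returned tree is unrooted, encoded with a trifurcating root.
    """
    labels = list(dm.ids)
    d = np.array(dm.values, dtype=float)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains undefined entries")

    nodes: list[Node] = [Node(name=lab) for lab in labels]
    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # row-major argmin lands on the smallest (i, j) with i < j
        flat = int(np.argmin(q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj, ri, rj = _clamp_pair(li, lj)
        parent = Node(children=[(nodes[i], li, ri), (nodes[j], lj, rj)])
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        new_d = np.zeros((m - 1, m - 1))
        new_d[:-1, :-1] = d[np.ix_(keep, keep)]
        new_d[-1, :-1] = new_d[:-1, -1] = dk[keep]
        d = new_d
        nodes = [nodes[k] for k in keep] + [parent]

    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    lens = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    root = Node(
        children=[(node, max(length, 0.0), length) for node, length in zip(nodes, lens)]
    )
    return PhyloTree(root=root)


def _to_matrix(records) -> tuple[tuple[str, ...], np.ndarray]:
    records = list(records)
    if len({len(r.bases) for r in records}) != 1:
        raise ValueError("alignment sequences must share one length")
    ids = tuple(r.id for r in records)
    arr = np.vstack(
        [np.frombuffer(r.bases.encode(), dtype="S1") for r in records]
    )
    return ids, arr


def _pdist_matrix(arr: np.ndarray) -> np.ndarray:
    n = arr.shape[0]
    valid = np.isin(arr, _ACGT)
    d = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid
        diff = (arr[i] != arr) & both
        denom = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            row = np.where(denom > 0, diff.sum(axis=1) / denom, np.nan)
        d[i] = row
    np.fill_diagonal(d, 0.0)
    return d


def alignment_distances(
    records, correction: str = "jc", saturation: str = "error"
) -> DistanceMatrix:
    """Pairwise distances from an equal-length alignment.

    Gapped/ambiguous sites are dropped pairwise (pairwise deletion).
    ``correction="jc"`` applies Jukes-Cantor; ``saturation="clamp"``
    caps saturated p-distances just below 0.75 instead of raising (used
    by bootstrap replicates, where resampling can saturate a pair).
    """
    ids, arr = _to_matrix(records)
    p = _pdist_matrix(arr)
    if correction == "p":
        return DistanceMatrix(ids=ids, values=p)
    if correction != "jc":
        raise ValueError("correction must be 'jc' or 'p'")
    if saturation == "clamp":
        p = np.minimum(p, 0.75 - 1e-9)
    d = jukes_cantor(p)
    np.fill_diagonal(d, 0.0)
    return _LabelledMatrix(ids, d)


def bootstrap_support(
    records, n_replicates: int = 1000, seed: int | None = None
) -> PhyloTree:
    """NJ tree with bootstrap support on internal edges.

    Resamples alignment columns with replacement ``n_replicates`` times,
    rebuilds the NJ tree per replicate (Jukes-Cantor distances, pairwise
    deletion, saturation clamped), and annotates each internal edge of
    the full-data tree with the percentage of replicates containing its
    bipartition.
    """
    records = list(records)
    if len(records) < 4:
        raise ValueError("bootstrap support needs >= 4 taxa")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ids, arr = _to_matrix(records)
    n_cols = arr.shape[1]

    tree = nj_tree(alignment_distances(records, saturation="clamp"))
    all_leaves = tree.leaves
    ref = min(all_leaves)

    counts: dict[frozenset[str], int] = {bip: 0 for bip in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        p = _pdist_matrix(arr[:, cols])
        p = np.minimum(p, 0.75 - 1e-9)
        d = jukes_cantor(p)
        np.fill_diagonal(d, 0.0)
        rep = nj_tree(_LabelledMatrix(ids, d))
        for bip in rep.bipartitions():
            if bip in counts:
                counts[bip] += 1

    for node in tree._internal_nodes():
        side = node.leaf_names()
        if ref in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            node.support = 100.0 * counts[side] / n_replicates
    return tree
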