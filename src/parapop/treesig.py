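"""Distance-based phylogenetics for concerted-evolution diagnostics.

Concerted evolution shows up as paralogues clustering together (within a
species) instead of with their orthologues. The toolkit here is the
distance route: Jukes-Cantor distances under complete gap deletion,
neighbor-joining trees, bootstrap support, a BootScan-style windowed
monophyly signal, and normalized Robinson-Foulds topology comparisons
with a random-tree baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .popdata import HaplotypeAlignment
from .windows import WindowSpec, make_windows

#: distance assigned when the JC transform saturates (p >= 3/4)
SATURATION_SENTINEL = 10.0


@dataclass
class DistanceMatrix:
    labels: List[str]
    d: np.ndarray
    saturated: bool = False

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        m = len(self.labels)
        if self.d.shape != (m, m):
            raise ValueError("matrix/label shape mismatch")
        if not np.allclose(self.d, self.d.T) or not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")


def p_distance_matrix(seqs: Sequence[str], labels: Sequence[str]) -> DistanceMatrix:
    """Mismatch proportions over columns that are gap-free in every sequence."""
    arr = np.array([list(s) for s in seqs])
    good = ~np.isin(arr, ["-", "N"]).any(axis=0)
    if not good.any():
        raise ValueError("no gap-free columns under complete deletion")
    sub = arr[:, good]
    m = len(seqs)
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d[i, j] = d[j, i] = (sub[i] != sub[j]).mean()
    return DistanceMatrix(list(labels), d)


def jc_distance_matrix(aln: HaplotypeAlignment,
                       gap_rule: str = "complete_deletion") -> DistanceMatrix:
    """JC69 distances d = -3/4 ln(1 - 4p/3); saturated pairs get a sentinel."""
    if gap_rule != "complete_deletion":
        raise ValueError(f"unsupported gap_rule {gap_rule!r}")
    pd_ = p_distance_matrix(aln.seqs, aln.ids)
    d = pd_.d.copy()
    saturated = False
    for i in range(d.shape[0]):
        for j in range(i + 1, d.shape[0]):
            p = d[i, j]
            if p >= 0.75:
                d[i, j] = d[j, i] = SATURATION_SENTINEL
                saturated = True
            else:
                d[i, j] = d[j, i] = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    return DistanceMatrix(pd_.labels, d, saturated=saturated)


class PhyloTree:
    """Unrooted tree: adjacency map node -> [(neighbor, branch_length)].

    Tips are their string labels; internal nodes are integers.
    """

    def __init__(self, adjacency: Dict, tips: Sequence[str]):
        self.adj = adjacency
        self.tips = list(tips)
        self.supports: Dict[FrozenSet[str], float] = {}

    def neighbors(self, v) -> List[Tuple[object, float]]:
        return self.adj[v]

    def _side(self, u, v) -> Set[str]:
        """Tip labels reachable from v without crossing edge (u, v)."""
        seen = {u, v}
        stack = [v]
        tips: Set[str] = set()
        while stack:
            x = stack.pop()
            if isinstance(x, str):
                tips.add(x)
            for y, _ in self.adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return tips

    def bipartitions(self) -> Set[FrozenSet[str]]:
        """Non-trivial bipartitions, each as the side not containing the
        alphabetically first tip (canonical)."""
        ref = min(self.tips)
        out: Set[FrozenSet[str]] = set()
        seen_edges = set()
        for u in self.adj:
            for v, _ in self.adj[u]:
                key = frozenset({("t", u) if isinstance(u, str) else ("i", u),
                                 ("t", v) if isinstance(v, str) else ("i", v)})
                if key in seen_edges:
                    continue
                seen_edges.add(key)
                if isinstance(u, str) or isinstance(v, str):
                    continue  # trivial (tip) edge
                side = self._side(u, v)
                if ref in side:
                    side = set(self.tips) - side
                if 2 <= len(side) <= len(self.tips) - 2:
                    out.add(frozenset(side))
        return out

    def has_cherry(self, a: str, b: str) -> bool:
        """True when tips a and b attach to the same internal node."""
        na = self.adj[a][0][0]
        nb = self.adj[b][0][0]
        return na == nb and not isinstance(na, str)

    def path_length(self, a: str, b: str) -> float:
        dist = {a: 0.0}
        stack = [a]
        while stack:
            x = stack.pop()
            for y, l in self.adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + l
                    if y == b:
                        return dist[y]
                    stack.append(y)
        raise KeyError(f"no path {a} -> {b}")

    def to_newick(self) -> str:
        # root at an arbitrary internal node (or a tip's neighbor)
        start = next((v for v in self.adj if not isinstance(v, str)), self.tips[0])

        def rec(v, parent) -> str:
            kids = [(u, l) for u, l in self.adj[v] if u is not parent and u != parent]
            if isinstance(v, str):
                return v
            inner = ",".join(f"{rec(u, v)}:{l:.6g}" for u, l in kids)
            return f"({inner})"

        return rec(start, None) + ";"


def tree_from_newick(text: str) -> PhyloTree:
    """Parse a newick string (possibly rooted) into an unrooted PhyloTree."""
    import dendropy
    dt = dendropy.Tree.get(data=text, schema="newick")
    adj: Dict = {}
    counter = [0]
    node_map: Dict = {}

    def get_node(nd):
        if nd not in node_map:
            if nd.is_leaf():
                node_map[nd] = nd.taxon.label.replace(" ", "_")
            else:
                node_map[nd] = counter[0]
                counter[0] += 1
            adj[node_map[nd]] = []
        return node_map[nd]

    for edge in dt.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        u = get_node(edge.tail_node)
        v = get_node(edge.head_node)
        l = edge.length if edge.length is not None else 0.0
        adj[u].append((v, l))
        adj[v].append((u, l))
    tips = [v for v in adj if isinstance(v, str)]
    tree = PhyloTree(adj, tips)
    _suppress_degree_two(tree)
    return tree


def _suppress_degree_two(tree: PhyloTree) -> None:
    """Remove internal nodes of degree 2 (artifacts of rooting)."""
    changed = True
    while changed:
        changed = False
        for v in list(tree.adj):
            if not isinstance(v, str) and len(tree.adj[v]) == 2:
                (a, la), (b, lb) = tree.adj[v]
                tree.adj[a] = [(x, l) for x, l in tree.adj[a] if x is not v and x != v]
                tree.adj[b] = [(x, l) for x, l in tree.adj[b] if x is not v and x != v]
                tree.adj[a].append((b, la + lb))
                tree.adj[b].append((a, la + lb))
                del tree.adj[v]
                changed = True
                break


# ---------------------------------------------------------------------------
# Neighbor joining (Saitou & Nei)

def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining; negative branch lengths are clamped to
    zero with the deficit moved to the adjacent branch."""
    m = len(dm.labels)
    if m < 3:
        raise ValueError("NJ needs at least 3 taxa")
    nodes: List[object] = list(dm.labels)
    D = dm.d.copy()
    adj: Dict = {lab: [] for lab in dm.labels}
    next_internal = 0

    def add_edge(u, v, l):
        l = float(l)
        adj.setdefault(u, []).append((v, l))
        adj.setdefault(v, []).append((u, l))

    def fix_negative(lu, lv):
        # clamp one negative member of a sibling pair, shifting the deficit
        if lu < 0:
            lv += lu
            lu = 0.0
        if lv < 0:
            lu += lv
            lv = 0.0
        return max(lu, 0.0), max(lv, 0.0)

    while len(nodes) > 3:
        r = len(nodes)
        sums = D.sum(axis=1)
        Q = (r - 2) * D - sums[:, None] - sums[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (sums[i] - sums[j]) / (2.0 * (r - 2))
        lj = D[i, j] - li
        li, lj = fix_negative(li, lj)
        new = next_internal
        next_internal += 1
        adj[new] = []
        add_edge(nodes[i], new, li)
        add_edge(nodes[j], new, lj)
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [x for x in range(r) if x not in (i, j)]
        D = np.vstack([np.hstack([D[np.ix_(keep, keep)], dnew[keep][:, None]]),
                       np.hstack([dnew[keep][None, :], [[0.0]]])])
        nodes = [nodes[x] for x in keep] + [new]
    # final star join of the last three nodes
    a, b, c = nodes
    center = next_internal
    adj[center] = []
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    for node, l in ((a, la), (b, lb), (c, lc)):
        add_edge(node, center, max(l, 0.0))
    return PhyloTree(adj, dm.labels)


def nj_from_alignment(aln: HaplotypeAlignment) -> PhyloTree:
    return nj_tree(jc_distance_matrix(aln))


# ---------------------------------------------------------------------------
# Bootstrap

def _resample_columns(seqs: List[str], rng: np.random.Generator) -> List[str]:
    L = len(seqs[0])
    idx = rng.integers(0, L, size=L)
    arr = np.array([list(s) for s in seqs])
    return ["".join(row) for row in arr[:, idx]]


def bootstrap_support(aln: HaplotypeAlignment, B: int = 1000,
                      rng: Optional[np.random.Generator] = None) -> PhyloTree:
    """NJ tree with bootstrap support (%) on each internal bipartition."""
    rng = rng if rng is not None else np.random.default_rng()
    tree = nj_from_alignment(aln)
    target = tree.bipartitions()
    hits = {bp: 0 for bp in target}
    for _ in range(B):
        seqs = _resample_columns(list(aln.seqs), rng)
        rep = nj_tree(jc_distance_matrix(
            HaplotypeAlignment(list(aln.ids), seqs, list(aln.counts))))
        rep_bp = rep.bipartitions()
        for bp in target:
            if bp in rep_bp:
                hits[bp] += 1
    tree.supports = {bp: 100.0 * h / B for bp, h in hits.items()}
    return tree


def bootscan_signal(aln: HaplotypeAlignment, pair: Tuple[str, str],
                    spec: Optional[WindowSpec] = None, B: int = 100,
                    rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Windowed % of bootstrap NJ trees in which ``pair`` forms a clade
    against all other taxa (a cherry)."""
    spec = spec or WindowSpec()
    if len(aln.ids) < 4:
        raise ValueError("pair monophyly needs at least 4 taxa")
    a, b = pair
    if a not in aln.ids or b not in aln.ids:
        raise ValueError("pair taxa not in alignment")
    rng = rng if rng is not None else np.random.default_rng()
    rows = []
    for start, end in make_windows(aln.L, spec):
        cols = slice(start - 1, end)
        seqs = [s[cols] for s in aln.seqs]
        hits = 0
        for _ in range(B):
            rseqs = _resample_columns(seqs, rng)
            try:
                tree = nj_tree(jc_distance_matrix(
                    HaplotypeAlignment(list(aln.ids), rseqs, list(aln.counts))))
            except ValueError:  # all columns gapped after resampling
                continue
            if tree.has_cherry(a, b):
                hits += 1
        rows.append({"start": start, "end": end,
                     "midpoint": (start + end) / 2.0,
                     "pct_trees": 100.0 * hits / B})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Robinson-Foulds

def robinson_foulds_normalized(t1: PhyloTree, t2: PhyloTree) -> float:
    """Symmetric-difference bipartition count / 2(t-3), in [0, 1]."""
    if set(t1.tips) != set(t2.tips):
        raise ValueError("trees have different tip sets")
    t = len(t1.tips)
    if t < 4:
        return 0.0
    b1 = t1.bipartitions()
    b2 = t2.bipartitions()
    denom = 2 * (t - 3)
    return len(b1 ^ b2) / denom


def random_topology(tips: Sequence[str], rng: np.random.Generator) -> PhyloTree:
    """Uniform random resolved unrooted topology via sequential addition."""
    tips = list(tips)
    if len(tips) < 3:
        raise ValueError("need at least 3 tips")
    adj: Dict = {}
    center = 0
    adj[center] = []
    edges: List[Tuple[object, object]] = []

    def add_edge(u, v, l=1.0):
        adj.setdefault(u, []).append((v, l))
        adj.setdefault(v, []).append((u, l))
        edges.append((u, v))

    for t in tips[:3]:
        add_edge(t, center)
    next_internal = 1
    for t in tips[3:]:
        u, v = edges[rng.integers(len(edges))]
        # split edge (u, v) with a new internal node carrying the new tip
        new = next_internal
        next_internal += 1
        adj[new] = []
        adj[u] = [(x, l) for x, l in adj[u] if x != v]
        adj[v] = [(x, l) for x, l in adj[v] if x != u]
        edges.remove((u, v))
        add_edge(u, new)
        add_edge(v, new)
        add_edge(t, new)
    return PhyloTree(adj, tips)


def random_rf_baseline(reference: PhyloTree, R: int = 100,
                       rng: Optional[np.random.Generator] = None
                       ) -> Tuple[float, float]:
    """Mean normalized RF of R uniform random topologies against the
    reference, with the normal-approximation 95% CI half-width."""
    if len(reference.tips) < 4:
        raise ValueError("need at least 4 tips")
    rng = rng if rng is not None else np.random.default_rng()
    vals = [robinson_foulds_normalized(reference, random_topology(reference.tips, rng))
            for _ in range(R)]
    mean = float(np.mean(vals))
    half = 1.96 * float(np.std(vals, ddof=1)) / math.sqrt(R) if R > 1 else 0.0
    return mean, half
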