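"""Tree inference: neighbour-joining, Fitch parsimony, bootstrap consensus.

Trees are held in a lightweight unrooted adjacency structure (:class:`UTree`)
for fast NNI search and bipartition counting, and converted to
:mod:`dendropy` only for Newick serialisation. Supports are percentages of
bootstrap replicates containing an internal edge's leaf bipartition;
the returned tree is the majority-rule (>50%) consensus.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

_CODE = {"A": 1, "C": 2, "G": 4, "T": 8}


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(m < 0):
            raise ValueError("distances must be nonnegative")
        self.matrix = m


class UTree:
    """Unrooted tree: leaves are labels, internal nodes are ints."""

    def __init__(self) -> None:
        self.adj: dict[object, dict[object, float | None]] = {}
        self.support: dict[frozenset, float] = {}
        self._next_internal = 0

    # -- construction -----------------------------------------------------
    def new_internal(self):
        node = ("i", self._next_internal)
        self._next_internal += 1
        self.adj[node] = {}
        return node

    def add_leaf(self, label: str):
        if label in self.adj:
            raise ValueError(f"duplicate leaf label {label!r}")
        self.adj[label] = {}
        return label

    def connect(self, a, b, length: float | None = None) -> None:
        self.adj[a][b] = length
        self.adj[b][a] = length

    def disconnect(self, a, b) -> None:
        del self.adj[a][b]
        del self.adj[b][a]

    # -- queries ----------------------------------------------------------
    @property
    def leaves(self) -> list[str]:
        return sorted(n for n in self.adj if not isinstance(n, tuple))

    def copy(self) -> "UTree":
        t = UTree()
        t.adj = {n: dict(nb) for n, nb in self.adj.items()}
        t._next_internal = self._next_internal
        t.support = dict(self.support)
        return t

    def internal_edges(self) -> list[tuple]:
        out = []
        seen: set[frozenset] = set()
        for a in self.adj:
            if not isinstance(a, tuple):
                continue
            for b in self.adj[a]:
                if isinstance(b, tuple):
                    key = frozenset((a, b))
                    if key not in seen:
                        seen.add(key)
                        out.append((a, b))
        return out

    def bipartitions(self) -> dict[frozenset, float | None]:
        """Internal-edge bipartitions as the leaf set not containing the
        alphabetically first leaf, mapped to the edge length."""
        anchor = self.leaves[0]
        out: dict[frozenset, float | None] = {}
        for a, b in self.internal_edges():
            side = frozenset(self._leafset(b, a))
            if anchor in side:
                side = frozenset(set(self.leaves) - side)
            out[side] = self.adj[a][b]
        return out

    def _leafset(self, node, parent) -> set[str]:
        acc: set[str] = set()
        stack = [(node, parent)]
        while stack:
            cur, par = stack.pop()
            if not isinstance(cur, tuple):
                acc.add(cur)
                continue
            for nb in self.adj[cur]:
                if nb != par:
                    stack.append((nb, cur))
        return acc

    def support_of(self, side: frozenset) -> float:
        """Bootstrap support of the edge splitting ``side`` from the rest."""
        anchor = self.leaves[0]
        if anchor in side:
            side = frozenset(set(self.leaves) - side)
        return self.support.get(frozenset(side), 0.0)

    def is_isomorphic(self, other: "UTree") -> bool:
        return (set(self.leaves) == set(other.leaves)
                and set(self.bipartitions()) == set(other.bipartitions()))

    # -- dendropy bridge --------------------------------------------------
    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        tns = taxon_namespace or dendropy.TaxonNamespace(self.leaves)
        tree = dendropy.Tree(taxon_namespace=tns)
        tree.is_rooted = False
        start = next(n for n in self.adj if isinstance(n, tuple)) \
            if any(isinstance(n, tuple) for n in self.adj) else self.leaves[0]
        supports = self.support

        def build(node, parent, dnode):
            for nb, ln in self.adj[node].items():
                if nb == parent:
                    continue
                child = dendropy.Node()
                child.edge.length = ln
                if not isinstance(nb, tuple):
                    child.taxon = tns.get_taxon(nb) or tns.new_taxon(nb)
                dnode.add_child(child)
                build(nb, node, child)
            if isinstance(node, tuple) and parent is not None:
                side = frozenset(self._leafset(node, parent))
                anchor = self.leaves[0]
                if anchor in side:
                    side = frozenset(set(self.leaves) - side)
                if side in supports:
                    dnode.label = str(int(round(supports[side])))

        build(start, None, tree.seed_node)
        return tree

    def newick(self) -> str:
        from .io_formats import tree_to_newick
        return tree_to_newick(self.to_dendropy())


# ---------------------------------------------------------------------------
# neighbour-joining

def nj_tree(dm: DistanceMatrix, _collect_joins: list | None = None) -> UTree:
    """Saitou-Nei neighbour joining with the Studier-Keppler Q criterion.

    Negative branch lengths are clamped to zero; Q ties resolve to the
    smallest label-pair index in the input order.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    tree = UTree()
    nodes = [tree.add_leaf(lab) for lab in dm.labels]
    d = dm.matrix.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # scan in index order so ties break to the smallest pair
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if best is None or q[i, j] < best[0] - 1e-12:
                    best = (q[i, j], i, j)
        _, i, j = best
        ai, aj = active[i], active[j]
        dij = d[ai, aj]
        li = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        parent = tree.new_internal()
        tree.connect(nodes[ai], parent, max(li, 0.0))
        tree.connect(nodes[aj], parent, max(lj, 0.0))
        if _collect_joins is not None:
            _collect_joins.append((ai, aj))
        # distances from the new node to the rest
        new_row = np.zeros(d.shape[0])
        for k in active:
            if k in (ai, aj):
                continue
            new_row[k] = (d[ai, k] + d[aj, k] - dij) / 2
        d = np.vstack([d, new_row])
        d = np.hstack([d, np.append(new_row, 0.0)[:, None]])
        nodes.append(parent)
        new_idx = d.shape[0] - 1
        active = [a for a in active if a not in (ai, aj)] + [new_idx]

    a, b, c = active
    center = tree.new_internal()
    la = (d[a, b] + d[a, c] - d[b, c]) / 2
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2
    for node, ln in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        tree.connect(node, center, max(ln, 0.0))
    if _collect_joins is not None:
        _collect_joins.append((a, b, c))
    return tree


# ---------------------------------------------------------------------------
# Fitch parsimony

def _encode_msa(labels: list[str], rows: list[str]) -> dict[str, np.ndarray]:
    states = {}
    for lab, row in zip(labels, rows):
        arr = np.array([_CODE.get(ch, 15) for ch in row], dtype=np.uint8)
        states[lab] = arr
    return states


def fitch_score(tree: UTree, labels: list[str], rows: list[str]) -> int:
    """Two-pass Fitch length: minimum state changes summed over columns."""
    if set(tree.leaves) != set(labels):
        raise ValueError("tree leaves do not match alignment labels")
    states = _encode_msa(labels, rows)
    root = next((n for n in tree.adj if isinstance(n, tuple)), None)
    if root is None:  # two-leaf tree
        a, b = tree.leaves
        return int(np.sum((states[a] & states[b]) == 0))
    order: list[tuple] = []
    stack = [(root, None)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        if isinstance(node, tuple):
            for nb in tree.adj[node]:
                if nb != parent:
                    stack.append((nb, node))
    changes = None
    sets: dict = {}
    for node, parent in reversed(order):
        if not isinstance(node, tuple):
            sets[node] = states[node]
            continue
        children = [nb for nb in tree.adj[node] if nb != parent]
        acc = sets[children[0]]
        if changes is None:
            changes = np.zeros(len(acc), dtype=np.int64)
        for ch in children[1:]:
            inter = acc & sets[ch]
            empty = inter == 0
            changes += empty
            acc = np.where(empty, acc | sets[ch], inter)
        sets[node] = acc
    return int(changes.sum())


def enumerate_topologies(labels: list[str]):
    """All distinct unrooted binary topologies by stepwise addition."""
    if len(labels) < 3:
        raise ValueError("need >= 3 taxa")
    base = UTree()
    center = base.new_internal()
    for lab in labels[:3]:
        base.add_leaf(lab)
        base.connect(lab, center)
    trees = [base]
    for lab in labels[3:]:
        nxt = []
        for t in trees:
            edges = [(a, b) for a in t.adj for b in t.adj[a] if str(a) < str(b)]
            for a, b in edges:
                t2 = t.copy()
                t2.disconnect(a, b)
                mid = t2.new_internal()
                t2.add_leaf(lab)
                t2.connect(a, mid)
                t2.connect(b, mid)
                t2.connect(lab, mid)
                nxt.append(t2)
        trees = nxt
    return trees


def nni_neighbors(tree: UTree):
    """The two NNI rearrangements of every internal edge."""
    for a, b in tree.internal_edges():
        a_sub = [n for n in tree.adj[a] if n != b]
        b_sub = [n for n in tree.adj[b] if n != a]
        if len(a_sub) != 2 or len(b_sub) != 2:
            continue
        for swap_b in b_sub:
            t2 = tree.copy()
            x = a_sub[1]
            lx = t2.adj[a][x]
            ls = t2.adj[b][swap_b]
            t2.disconnect(a, x)
            t2.disconnect(b, swap_b)
            t2.connect(a, swap_b, ls)
            t2.connect(b, x, lx)
            yield t2


def fitch_parsimony(
    labels: list[str],
    rows: list[str],
    tree: UTree | None = None,
    exhaustive_max: int = 8,
    restarts: int = 5,
    seed: int = 0,
) -> tuple[int, UTree]:
    """Parsimony score; searches topologies when no tree is given.

    Exhaustive enumeration for <= ``exhaustive_max`` taxa, otherwise NNI
    hill-climbing from the NJ tree with seeded random restarts.
    """
    if tree is not None:
        return fitch_score(tree, labels, rows), tree
    n = len(labels)
    if n <= exhaustive_max:
        best = None
        for t in enumerate_topologies(labels):
            s = fitch_score(t, labels, rows)
            if best is None or s < best[0]:
                best = (s, t)
        return best
    rng = np.random.default_rng(seed)
    start = nj_tree(p_distance_matrix_from_rows(labels, rows))
    best_overall = None
    for restart in range(restarts):
        t = start.copy()
        if restart > 0:
            for _ in range(int(rng.integers(1, 4))):
                neigh = list(nni_neighbors(t))
                if neigh:
                    t = neigh[int(rng.integers(len(neigh)))]
        s = fitch_score(t, labels, rows)
        improved = True
        while improved:
            improved = False
            for t2 in nni_neighbors(t):
                s2 = fitch_score(t2, labels, rows)
                if s2 < s:
                    t, s = t2, s2
                    improved = True
                    break
        if best_overall is None or s < best_overall[0]:
            best_overall = (s, t)
    return best_overall


def p_distance_matrix_from_rows(labels: list[str], rows: list[str]) -> DistanceMatrix:
    arr = np.array([list(r) for r in rows])
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = np.mean(arr[i] != arr[j])
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# bootstrap + consensus

def majority_rule_consensus(
    trees: list[UTree],
    lengths_from: UTree | None = None,
) -> UTree:
    """Tree of all bipartitions appearing in > 50% of the input trees,
    labelled with their percentage frequency."""
    if not trees:
        raise ValueError("no trees to summarise")
    leaves = trees[0].leaves
    counts: dict[frozenset, int] = {}
    for t in trees:
        for bp in t.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    n = len(trees)
    majority = {bp: 100.0 * c / n for bp, c in counts.items() if c > n / 2}
    ref_lengths = lengths_from.bipartitions() if lengths_from is not None else {}

    cons = UTree()
    root = cons.new_internal()
    parent_of: dict[str, object] = {}
    for lab in leaves:
        cons.add_leaf(lab)
        cons.connect(lab, root)
        parent_of[lab] = root
    # insert bipartitions smallest-last so nesting resolves naturally
    for bp in sorted(majority, key=len, reverse=True):
        group = sorted(bp)
        host = parent_of[group[0]]
        if any(parent_of[g] != host for g in group):
            continue  # incompatible with already-inserted splits (ties)
        node = cons.new_internal()
        cons.connect(node, host, ref_lengths.get(bp))
        cons.support[bp] = majority[bp]
        for g in group:
            ln = cons.adj[g][host]
            cons.disconnect(g, host)
            cons.connect(g, node, ln)
            parent_of[g] = node
    return cons


def bootstrap_consensus(
    labels: list[str],
    rows: list[str],
    method: str = "nj",
    reps: int = 1000,
    seed: int = 0,
) -> UTree:
    """Column-resampled bootstrap; majority-rule consensus with supports."""
    if reps < 1:
        raise ValueError("bootstrap replicates must be >= 1")
    if method not in ("nj", "parsimony"):
        raise ValueError(f"unknown method {method!r}")
    L = len(rows[0])
    if any(len(r) != L for r in rows):
        raise ValueError("alignment rows differ in length")
    rng = np.random.default_rng(seed)
    n = len(labels)

    if method == "nj":
        arr = np.array([np.frombuffer(r.encode(), dtype=np.uint8) for r in rows])
        pair_mismatch = np.zeros((n * (n - 1) // 2, L), dtype=np.uint8)
        pidx = 0
        pairs = []
        for i in range(n):
            for j in range(i + 1, n):
                pair_mismatch[pidx] = arr[i] != arr[j]
                pairs.append((i, j))
                pidx += 1
        full = nj_tree(DistanceMatrix(labels, _dist_from_counts(
            pair_mismatch @ np.ones(L), L, pairs, n)))
        replicate_trees = []
        for _ in range(reps):
            counts = np.bincount(rng.integers(0, L, size=L), minlength=L)
            mism = pair_mismatch @ counts
            dm = DistanceMatrix(labels, _dist_from_counts(mism, L, pairs, n))
            replicate_trees.append(nj_tree(dm))
        return majority_rule_consensus(replicate_trees, lengths_from=full)

    score, full = fitch_parsimony(labels, rows, seed=seed)
    replicate_trees = []
    for rep in range(reps):
        cols = rng.integers(0, L, size=L)
        rrows = ["".join(r[c] for c in cols) for r in rows]
        _, t = fitch_parsimony(labels, rrows, seed=seed + rep + 1)
        replicate_trees.append(t)
    return majority_rule_consensus(replicate_trees, lengths_from=full)


def _dist_from_counts(mism, L, pairs, n):
    d = np.zeros((n, n))
    for (i, j), m in zip(pairs, np.asarray(mism, dtype=float) / L):
        d[i, j] = d[j, i] = m
    return d


# ---------------------------------------------------------------------------
# marker concatenation

def concatenate_markers(
    per_subgenome: dict[str, dict[str, str]],
    reference_lengths: dict[str, int],
    order: tuple[str, ...] = ("tub2", "tefA", "perA"),
) -> tuple[dict[str, str], list[tuple[str, str]]]:
    """Join marker copies per sub-genome in the stated order.

    A sub-genome missing a marker is padded with N of the reference length
    and reported in the flag list.
    """
    if not order:
        raise ValueError("empty marker order")
    out: dict[str, str] = {}
    flags: list[tuple[str, str]] = []
    for sub, markers in per_subgenome.items():
        parts = []
        for m in order:
            if m in markers and markers[m]:
                parts.append(markers[m])
            else:
                parts.append("N" * reference_lengths[m])
                flags.append((sub, m))
        out[sub] = "".join(parts)
    return out, flags
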