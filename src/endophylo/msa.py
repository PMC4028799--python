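"""Progressive multiple sequence alignment and alignment utilities.

The aligner follows the classic progressive recipe: a neighbour-joining
guide tree on k-mer dissimilarities fixes the merge order, and profiles are
merged bottom-up by affine-gap global dynamic programming (match +1,
mismatch -2, gap open -5, extend -2; end gaps cost extension only). The
horizontal gap state is computed with a max-plus prefix scan so each DP row
is a vectorised numpy operation.

Gap/N columns can then be eliminated (the complete-deletion rule used
before distance and parsimony computation) and uncorrected p-distances
derived.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .similarity import GAP_EXTEND, GAP_OPEN, MATCH, MISMATCH

_SYMBOLS = "ACGTN-"
_SYM_INDEX = {c: i for i, c in enumerate(_SYMBOLS)}

# column-vs-column scoring: bases match/mismatch, N and '-' are neutral
_SCORE = np.zeros((6, 6), dtype=np.float32)
for _i in range(4):
    for _j in range(4):
        _SCORE[_i, _j] = MATCH if _i == _j else MISMATCH


@dataclass
class Msa:
    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("duplicate labels in alignment")
        if len({len(r) for r in self.rows} or {0}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def _profile(rows: list[str]) -> np.ndarray:
    arr = np.zeros((len(rows[0]), 6), dtype=np.float32)
    for row in rows:
        idx = np.array([_SYM_INDEX[c] for c in row])
        arr[np.arange(len(row)), idx] += 1.0
    return arr / len(rows)


def _align_profiles(pa: np.ndarray, pb: np.ndarray) -> tuple[list[str], int, int]:
    """Affine-gap global alignment of two column profiles.

    Returns the operation string per column ('M' both, 'X' gap in B,
    'Y' gap in A) plus final lengths, via traceback over stored matrices.
    """
    n, m = len(pa), len(pb)
    NEG = np.float32(-1e9)
    open_, ext = -float(GAP_OPEN), -float(GAP_EXTEND)

    ga = pa @ _SCORE                       # n x 6
    M = np.full((n + 1, m + 1), NEG, dtype=np.float32)
    X = np.full((n + 1, m + 1), NEG, dtype=np.float32)  # gap in B (consume A)
    Y = np.full((n + 1, m + 1), NEG, dtype=np.float32)  # gap in A (consume B)
    M[0, 0] = 0.0
    Y[0, 1:] = -open_ - ext * np.arange(m, dtype=np.float32)

    j_ext = ext * np.arange(m + 1, dtype=np.float32)
    for i in range(1, n + 1):
        s = ga[i - 1] @ pb.T               # m-vector of column scores
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = s + prev_best[:-1]
        X[i] = np.maximum(M[i - 1] - open_, X[i - 1] - ext)
        # Y[i, j] = max(M[i, j-1] - open, Y[i, j-1] - ext) as a max-plus
        # prefix scan: Y[i, j] = max_{j0<=j} (M[i, j0-1] + j0*ext) - open - j*ext
        entry = M[i, :m] + j_ext[1:]
        acc = np.maximum.accumulate(entry)
        Y[i, 1:] = acc - open_ - j_ext[1:]

    ops: list[str] = []
    i, j = n, m
    state = int(np.argmax([M[n, m], X[n, m], Y[n, m]]))
    while i > 0 or j > 0:
        if state == 0:                     # M
            ops.append("M")
            i, j = i - 1, j - 1
            if i >= 0 and j >= 0:
                state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
        elif state == 1:                   # X: consumed A[i]
            ops.append("X")
            came_m = M[i - 1, j] - open_
            came_x = X[i - 1, j] - ext
            i -= 1
            state = 0 if came_m >= came_x else 1
        else:                              # Y: consumed B[j]
            ops.append("Y")
            came_m = M[i, j - 1] - open_
            came_y = Y[i, j - 1] - ext
            j -= 1
            state = 0 if came_m >= came_y else 2
        if i == 0 and j > 0 and state != 2:
            state = 2
        if j == 0 and i > 0 and state != 1:
            state = 1
    ops.reverse()
    return ops, n, m


def _merge(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    ops, _, _ = _align_profiles(_profile(rows_a), _profile(rows_b))
    ia = ib = 0
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    for op in ops:
        if op == "M":
            for r, row in zip(out_a, rows_a):
                r.append(row[ia])
            for r, row in zip(out_b, rows_b):
                r.append(row[ib])
            ia += 1
            ib += 1
        elif op == "X":
            for r, row in zip(out_a, rows_a):
                r.append(row[ia])
            for r in out_b:
                r.append("-")
            ia += 1
        else:
            for r in out_a:
                r.append("-")
            for r, row in zip(out_b, rows_b):
                r.append(row[ib])
            ib += 1
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def _kmer_distance(a: str, b: str, k: int = 8) -> float:
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def progressive_align(labels: list[str], seqs: list[str]) -> Msa:
    """Guide-tree-ordered progressive alignment; rows in input order."""
    if len(seqs) != len(labels):
        raise ValueError("labels and sequences must align")
    if len(seqs) == 0:
        raise ValueError("nothing to align")
    if len(seqs) == 1:
        return Msa(list(labels), list(seqs))

    from .phylo import DistanceMatrix, nj_tree

    groups: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i]]) for i in range(len(seqs))
    }
    if len(seqs) == 2:
        join_plan = [(0, 1)]
    else:
        n = len(seqs)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = _kmer_distance(seqs[i], seqs[j])
        joins: list[tuple] = []
        nj_tree(DistanceMatrix([str(i) for i in range(n)], d), _collect_joins=joins)
        join_plan = joins

    next_id = len(seqs)
    for join in join_plan:
        if len(join) == 2:
            ai, bi = join
            ra, rb = _merge(groups[ai][1], groups[bi][1])
            groups[next_id] = (groups[ai][0] + groups[bi][0], ra + rb)
            del groups[ai], groups[bi]
            next_id += 1
        else:  # final 3-way join of the unrooted guide tree
            ids = [g for g in join if g in groups]
            while len(ids) > 1:
                a, b = ids[0], ids[1]
                ra, rb = _merge(groups[a][1], groups[b][1])
                groups[next_id] = (groups[a][0] + groups[b][0], ra + rb)
                del groups[a], groups[b]
                ids = [next_id] + ids[2:]
                next_id += 1
    # any clusters never reached by the plan (defensive): merge sequentially
    remaining = sorted(groups)
    while len(remaining) > 1:
        a, b = remaining[0], remaining[1]
        ra, rb = _merge(groups[a][1], groups[b][1])
        groups[next_id] = (groups[a][0] + groups[b][0], ra + rb)
        del groups[a], groups[b]
        remaining = [next_id] + remaining[2:]
        next_id += 1

    order, rows = groups[remaining[0]]
    by_input = {idx: row for idx, row in zip(order, rows)}
    return Msa(list(labels), [by_input[i] for i in range(len(seqs))])


def strip_ambiguous_columns(msa: Msa) -> Msa:
    """Remove every column containing '-' or 'N' in any row."""
    if not msa.rows:
        raise ValueError("empty alignment")
    arr = np.array([np.frombuffer(r.encode(), dtype=np.uint8) for r in msa.rows])
    bad = np.any((arr == ord("-")) | (arr == ord("N")), axis=0)
    if bad.all():
        raise ValueError("no informative columns remain after gap elimination")
    keep = ~bad
    rows = ["".join(chr(c) for c in row[keep]) for row in arr]
    return Msa(list(msa.labels), rows)


def p_distance_matrix(msa: Msa):
    """Uncorrected pairwise mismatch fractions of a stripped alignment."""
    from .phylo import DistanceMatrix

    if msa.n_cols == 0:
        raise ValueError("zero-length alignment")
    arr = np.array([np.frombuffer(r.encode(), dtype=np.uint8) for r in msa.rows])
    n = len(msa.labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = float(np.mean(arr[i] != arr[j]))
    return DistanceMatrix(list(msa.labels), d)
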