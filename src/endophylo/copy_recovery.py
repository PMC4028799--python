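"""Reference-guided recovery of homeologous nuclear gene copies.

Work flow per marker gene:

1. **recruit**: read pairs in which either mate has a local hit to the
   reference gene at E <= 0.1 are extracted; antisense mates are
   reverse-complemented so every returned read is reference-sense.
2. **pad**: each read is placed at the start coordinate of its best hit and
   laid out in reference coordinates (leading offset + gap characters at
   copy-specific deletions), so reads stack into reference-frame columns.
3. **variant columns**: a column is variant when at least two alleles each
   reach a depth and allele-fraction floor; '-' (deleted base) counts as an
   allele, padding outside a read's span does not.
4. **phase**: read pairs are clustered by shared alleles across linked
   variant columns; each allele-consistent cluster is one homeologous copy,
   and its majority consensus (deletions preserved as gap runs) is the
   recovered gene-copy sequence.

This replaces the manual multiple-sequence-editor assembly step of the
original workflow with a deterministic variant-linkage phasing.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np

from .io_formats import ReadPair, revcomp
from .similarity import LocalHit, LocalSearch


@dataclass
class OrientedRead:
    """A recruited read, reference-sense, with its recruiting hit if any."""

    pair_id: str
    mate: int               # 1 or 2
    seq: str
    hit: LocalHit | None


@dataclass
class PaddedRead:
    pair_id: str
    mate: int
    start: int              # 0-based reference offset of the placed sequence
    placed: str             # over {A,C,G,T,N,-}; '-' = deleted reference base

    @property
    def end(self) -> int:   # exclusive
        return self.start + len(self.placed)


@dataclass
class GeneCopySet:
    marker: str
    k: int
    consensi: list[str]                 # reference-length rows over {A,C,G,T,N,-}
    assignments: dict[str, int]         # pair_id -> copy index
    unassigned_fraction: float
    unphased: bool = False

    def copy_sequences(self) -> list[str]:
        """Gap- and N-stripped consensus sequences, one per copy."""
        return [c.replace("-", "").replace("N", "") for c in self.consensi]


def recruit_read_pairs(
    pairs: list[ReadPair],
    reference: str,
    evalue_threshold: float = 0.1,
    search: LocalSearch | None = None,
) -> list[tuple[OrientedRead, OrientedRead]]:
    """Extract and orient read pairs matching the reference gene.

    A pair is recruited if either mate hits at E <= threshold; both mates
    are returned. Mates hitting antisense are reverse-complemented; a mate
    with no hit of its own inherits the opposite orientation of its mate
    (FR libraries place the two mates on opposite strands).
    """
    if len(reference) < 200:
        raise ValueError("reference gene shorter than 200 bp")
    search = search or LocalSearch(reference)
    recruited = []
    for pair in pairs:
        h1 = search.best_hit(pair.id, pair.r1.seq)
        h2 = search.best_hit(pair.id, pair.r2.seq)
        if h1 is not None and h1.evalue > evalue_threshold:
            h1 = None
        if h2 is not None and h2.evalue > evalue_threshold:
            h2 = None
        if h1 is None and h2 is None:
            continue
        recruited.append((
            _orient(pair.id, 1, pair.r1.seq, h1, other=h2),
            _orient(pair.id, 2, pair.r2.seq, h2, other=h1),
        ))
    return recruited


def _orient(pair_id: str, mate: int, seq: str, hit: LocalHit | None,
            other: LocalHit | None) -> OrientedRead:
    if hit is not None:
        strand = hit.strand
    else:
        # FR orientation: mates lie on opposite strands of the fragment
        strand = "-" if (other is not None and other.strand == "+") else "+"
    return OrientedRead(pair_id, mate, seq if strand == "+" else revcomp(seq), hit)


def pad_to_reference(
    recruited: list[tuple[OrientedRead, OrientedRead]],
    reference: str,
    search: LocalSearch | None = None,
    min_placed_len: int = 30,
) -> tuple[list[PaddedRead], list[OrientedRead]]:
    """Place oriented reads at reference coordinates.

    Returns the stacked reads and the unplaced bin (reads with no scorable
    placement, e.g. flank-only mates). Placements spanning fewer than
    ``min_placed_len`` reference positions — bare seed-word stubs from
    chance word matches elsewhere in the genome — carry no phasing
    information and go to the unplaced bin as well.
    """
    search = search or LocalSearch(reference)
    stack: list[PaddedRead] = []
    unplaced: list[OrientedRead] = []
    for pair in recruited:
        for read in pair:
            hit = read.hit
            if hit is None or not hit.aligned_query:
                # reads are already reference-sense: search the sense strand only
                hit = search.best_hit(read.pair_id, read.seq)
            if hit is None:
                unplaced.append(read)
                continue
            placed = hit.aligned_query
            if hit.strand == "-":
                # hit was found on the antisense of the original read; the
                # oriented read is its reverse complement, so re-derive the
                # projection from the oriented sequence
                rehit = search.best_hit(read.pair_id, read.seq)
                if rehit is None or rehit.strand != "+":
                    unplaced.append(read)
                    continue
                hit = rehit
                placed = rehit.aligned_query
            if len(placed) < min_placed_len:
                unplaced.append(read)
                continue
            stack.append(PaddedRead(read.pair_id, read.mate, hit.ref_start - 1, placed))
    stack.sort(key=lambda r: (r.start, r.pair_id, r.mate))
    return stack, unplaced


@dataclass
class VariantColumn:
    position: int                  # 0-based reference column
    alleles: dict[str, int]        # allele -> count (pads excluded)


def call_variant_columns(
    stack: list[PaddedRead],
    ref_len: int,
    min_depth: int = 4,
    min_allele_fraction: float = 0.2,
) -> list[VariantColumn]:
    """Columns where >= 2 alleles each reach depth and fraction floors."""
    counts: list[Counter] = [Counter() for _ in range(ref_len)]
    for read in stack:
        for i, base in enumerate(read.placed):
            pos = read.start + i
            if 0 <= pos < ref_len and base != "N":
                counts[pos][base] += 1
    variants: list[VariantColumn] = []
    for pos, ctr in enumerate(counts):
        total = sum(ctr.values())
        if total == 0:
            continue
        qualifying = {a: n for a, n in ctr.items()
                      if n >= min_depth and n / total >= min_allele_fraction}
        if len(qualifying) >= 2:
            variants.append(VariantColumn(pos, dict(qualifying)))
    return variants


def phase_gene_copies(
    stack: list[PaddedRead],
    variants: list[VariantColumn],
    ref_len: int,
    marker: str = "gene",
    k_max: int = 3,
    min_link: int = 3,
    min_cluster_frac: float = 0.10,
) -> GeneCopySet:
    """Cluster read pairs by shared alleles at variant columns.

    Pairs (fragments) are greedily agglomerated: a fragment joins the
    cluster with which it agrees at the most shared variant columns,
    provided agreement >= 80%; clusters smaller than ``min_cluster_frac``
    of the phased fragments are dissolved into the unassigned pool. The
    number of surviving clusters, capped at ``k_max``, is the copy number.
    """
    fragments = _fragment_alleles(stack, variants)
    if not variants or not fragments:
        consensus = _consensus([r for r in stack], ref_len, None, None)
        return GeneCopySet(marker, 1, [consensus], {}, 0.0)

    order = sorted(fragments, key=lambda pid: -len(fragments[pid]))
    clusters: list[dict[int, Counter]] = []   # column -> allele counts
    majority: list[dict[int, str]] = []       # cached per-column majority allele
    members: list[list[str]] = []
    unassigned: list[str] = []
    for pid in order:
        alleles = fragments[pid]
        best, best_score = -1, 0
        for ci, maj in enumerate(majority):
            matches = mismatches = 0
            for c, a in alleles.items():
                m = maj.get(c)
                if m is None:
                    continue
                if m == a:
                    matches += 1
                else:
                    mismatches += 1
            shared = matches + mismatches
            if shared == 0 or matches / shared < 0.8:
                continue
            score = matches - mismatches
            if score > best_score:
                best, best_score = ci, score
        if best >= 0:
            prof, maj = clusters[best], majority[best]
            for c, a in alleles.items():
                ctr = prof.setdefault(c, Counter())
                ctr[a] += 1
                if maj.get(c) is None or ctr[a] >= ctr[maj[c]]:
                    maj[c] = max(ctr, key=lambda x: (ctr[x], x))
            members[best].append(pid)
        else:
            clusters.append({c: Counter({a: 1}) for c, a in alleles.items()})
            majority.append(dict(alleles))
            members.append([pid])

    clusters, members, unassigned = _merge_compatible(clusters, members, min_link)
    n_phased = sum(len(m) for m in members)
    ambiguous = _stitch_phase_blocks(clusters, members,
                                     min_size=max(3, int(0.05 * n_phased)))
    # dissolve dust clusters
    keep = [i for i, m in enumerate(members)
            if len(m) >= max(2, min_cluster_frac * n_phased)]
    unphased = ambiguous
    if len(keep) > k_max:
        keep = sorted(keep, key=lambda i: -len(members[i]))[:k_max]
        keep.sort()
        unphased = True
    for i, m in enumerate(members):
        if i not in keep:
            unassigned.extend(m)
    clusters = [clusters[i] for i in keep]
    members = [members[i] for i in keep]

    pair_reads: dict[str, list[PaddedRead]] = defaultdict(list)
    for read in stack:
        pair_reads[read.pair_id].append(read)
    assignments = {pid: ci for ci, mem in enumerate(members) for pid in mem}
    consensi = []
    for ci in range(len(members)):
        reads = [r for pid in members[ci] for r in pair_reads[pid]]
        consensi.append(_consensus(reads, ref_len, None, None))
    # pairs spanning zero variant columns are unassigned by construction
    total_pairs = len(pair_reads)
    unassigned_fraction = (total_pairs - sum(len(m) for m in members)) / total_pairs
    return GeneCopySet(marker, len(members), consensi, assignments,
                       unassigned_fraction, unphased)


def _fragment_alleles(stack, variants) -> dict[str, dict[int, str]]:
    """Pair-level allele observations at variant columns (mates linked)."""
    vpos = {v.position: set(v.alleles) for v in variants}
    frags: dict[str, dict[int, str]] = defaultdict(dict)
    for read in stack:
        for i, base in enumerate(read.placed):
            pos = read.start + i
            if pos in vpos and base in vpos[pos]:
                frags[read.pair_id][pos] = base
    return {pid: a for pid, a in frags.items() if a}


def _stitch_phase_blocks(clusters, members, min_size) -> bool:
    """Join clusters whose variant-column intervals are fully disjoint.

    A copy-specific deletion (or any variant desert longer than the largest
    fragment) breaks linkage, splitting one gene copy into left/right phase
    blocks. Recruited copies span the whole reference, so substantial
    clusters with non-overlapping column intervals are blocks of the same
    copy; they are paired smallest-size-difference first. Returns True if
    any pairing had a competing alternative (reported as unphased).
    """
    ambiguous = False
    while True:
        idx = [i for i in range(len(clusters)) if len(members[i]) >= min_size]
        candidates = []
        for ai in range(len(idx)):
            for bi in range(ai + 1, len(idx)):
                i, j = idx[ai], idx[bi]
                cols_i, cols_j = clusters[i].keys(), clusters[j].keys()
                if cols_i & cols_j:
                    # clusters of distinct copies overlap at shared variant
                    # columns; zero sharing marks split phase blocks
                    continue
                overlap = max(0, min(max(cols_i), max(cols_j))
                              - max(min(cols_i), min(cols_j)))
                candidates.append(
                    (overlap, abs(len(members[i]) - len(members[j])), i, j))
        if not candidates:
            return ambiguous
        candidates.sort()
        if len(candidates) > 1:
            ambiguous = True
        _, _, i, j = candidates[0]
        for c, ctr in clusters[j].items():
            clusters[i].setdefault(c, Counter()).update(ctr)
        members[i].extend(members[j])
        del clusters[j], members[j]


def _merge_compatible(clusters, members, min_link):
    """Merge clusters whose shared variant columns agree (chained phasing)."""
    majority = [{c: ctr.most_common(1)[0][0] for c, ctr in prof.items()}
                for prof in clusters]
    merged = True
    while merged and len(clusters) > 1:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                shared = [c for c in majority[i] if c in majority[j]]
                if len(shared) < min_link and not (
                        len(shared) >= 1 and min(len(members[i]), len(members[j])) <= 2):
                    continue
                if not shared:
                    continue
                agree = sum(majority[i][c] == majority[j][c] for c in shared)
                if agree / len(shared) >= 0.8:
                    for c, ctr in clusters[j].items():
                        acc = clusters[i].setdefault(c, Counter())
                        acc.update(ctr)
                        majority[i][c] = max(acc, key=lambda x: (acc[x], x))
                    members[i].extend(members[j])
                    del clusters[j], members[j], majority[j]
                    merged = True
                    break
            if merged:
                break
    return clusters, members, []


def _consensus(reads: list[PaddedRead], ref_len: int, _a, _b) -> str:
    """Reference-length majority call; uncovered columns become 'N'."""
    counts: list[Counter] = [Counter() for _ in range(ref_len)]
    for read in reads:
        for i, base in enumerate(read.placed):
            pos = read.start + i
            if 0 <= pos < ref_len and base != "N":
                counts[pos][base] += 1
    out = []
    for ctr in counts:
        if not ctr:
            out.append("N")
        else:
            out.append(ctr.most_common(1)[0][0])
    return "".join(out)
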