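"""Local similarity search and pairwise-alignment helpers.

The recruiter is an exact k-mer-seeded local search: a query shares a seed
word with the subject (either strand), the hit is extended, and the score is
converted to a BLAST-style E-value with fixed nucleotide Karlin-Altschul
parameters. A Hamming fast path handles the overwhelmingly common case of a
read matching the reference without gaps; gapped placements fall back to an
affine-gap local alignment (Bio.Align.PairwiseAligner).

Scoring: match +1, mismatch -2, gap open -5, gap extend -2 (classic
megablast-like nucleotide scheme); lambda = 1.28, K = 0.46.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio import Align

from .io_formats import revcomp

SEED_LEN = 13
MATCH = 1
MISMATCH = -2
GAP_OPEN = -5
GAP_EXTEND = -2
KA_LAMBDA = 1.28
KA_K = 0.46


def evalue(score: float, query_len: int, subject_len: int) -> float:
    """Karlin-Altschul E = K m n exp(-lambda S)."""
    return KA_K * query_len * subject_len * math.exp(-KA_LAMBDA * score)


def make_local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def make_global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    # free end gaps: the query may hang over the subject ends
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


@dataclass
class LocalHit:
    query_id: str
    ref_start: int      # 1-based inclusive on the subject
    ref_end: int
    query_start: int    # 1-based inclusive on the query (sense strand)
    query_end: int
    strand: str
    score: float
    evalue: float
    aligned_query: str = ""   # query over the subject span, '-' at deletions


class SeedIndex:
    """Exact-word index of a subject sequence, both strands."""

    def __init__(self, subject: str, seed_len: int = SEED_LEN):
        self.subject = subject
        self.seed_len = seed_len
        self.fwd: dict[str, list[int]] = {}
        for i in range(len(subject) - seed_len + 1):
            self.fwd.setdefault(subject[i : i + seed_len], []).append(i)

    def seed_diagonals(self, query: str) -> dict[int, int]:
        """Diagonal (ref_pos - query_pos) -> seed vote count."""
        diags: dict[int, int] = {}
        k = self.seed_len
        fwd = self.fwd
        for qpos in range(len(query) - k + 1):
            hits = fwd.get(query[qpos : qpos + k])
            if hits:
                for rpos in hits:
                    d = rpos - qpos
                    diags[d] = diags.get(d, 0) + 1
        return diags


class LocalSearch:
    """Seeded local search of queries against one subject sequence."""

    def __init__(self, subject: str, seed_len: int = SEED_LEN):
        if len(subject) < seed_len:
            raise ValueError(
                f"subject length {len(subject)} shorter than seed length {seed_len}")
        self.subject = subject
        self.index = SeedIndex(subject, seed_len)
        self._aligner = make_local_aligner()

    def best_hit(self, query_id: str, query: str) -> LocalHit | None:
        """Best local hit of the query on either strand, or None if unseeded."""
        best: LocalHit | None = None
        for strand, q in (("+", query), ("-", revcomp(query))):
            hit = self._search_strand(query_id, q, strand)
            if hit and (best is None or hit.score > best.score):
                best = hit
        return best

    def _search_strand(self, query_id: str, q: str, strand: str) -> LocalHit | None:
        diags = self.index.seed_diagonals(q)
        if not diags:
            return None
        # smallest start coordinate wins score ties
        diag = max(sorted(diags), key=lambda d: (diags[d], -d))
        hit = self._ungapped_hit(query_id, q, strand, diag)
        if hit is not None:
            return hit
        return self._gapped_hit(query_id, q, strand)

    def _ungapped_hit(self, query_id, q, strand, diag) -> LocalHit | None:
        """Hamming fast path along the voted diagonal; None if too noisy."""
        sub = self.subject
        r0 = max(diag, 0)
        q0 = r0 - diag
        span = min(len(q) - q0, len(sub) - r0)
        if span < self.index.seed_len:
            return None
        qseg = q[q0 : q0 + span]
        rseg = sub[r0 : r0 + span]
        mism = sum(a != b for a, b in zip(qseg, rseg))
        if mism > 0.12 * span:
            return None
        score = (span - mism) * MATCH + mism * MISMATCH
        return LocalHit(query_id, r0 + 1, r0 + span, q0 + 1, q0 + span, strand,
                        score, evalue(score, len(q), len(sub)), qseg)

    def _gapped_hit(self, query_id, q, strand) -> LocalHit | None:
        alns = self._aligner.align(self.subject, q)
        if len(alns) == 0:
            return None
        aln = alns[0]
        (rs, re) = (int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1]))
        (qs, qe) = (int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1]))
        placed = _project_query(aln)
        score = float(aln.score)
        return LocalHit(query_id, rs + 1, re, qs + 1, qe, strand, score,
                        evalue(score, len(q), len(self.subject)), placed)


def _project_query(aln) -> str:
    """Query bases laid out over the subject span; '-' where the subject has
    bases the query lacks; query insertions are dropped."""
    ref_blocks, q_blocks = aln.aligned
    query = str(aln.sequences[1])
    out: list[str] = []
    prev_ref_end = int(ref_blocks[0][0])
    for (rs, re), (qs, qe) in zip(ref_blocks, q_blocks):
        rs, re, qs, qe = int(rs), int(re), int(qs), int(qe)
        if rs > prev_ref_end:
            out.append("-" * (rs - prev_ref_end))
        out.append(query[qs:qe])
        prev_ref_end = re
    return "".join(out)


def align_identity(a: str, b: str) -> float:
    """Global alignment identity (matches / aligned columns) of two sequences."""
    aligner = make_global_aligner()
    aln = aligner.align(a, b)[0]
    a_blocks, b_blocks = aln.aligned
    matches = 0
    cols = 0
    prev_a = int(a_blocks[0][0]) if len(a_blocks) else 0
    prev_b = int(b_blocks[0][0]) if len(b_blocks) else 0
    for (as_, ae), (bs, be) in zip(a_blocks, b_blocks):
        as_, ae, bs, be = int(as_), int(ae), int(bs), int(be)
        cols += (as_ - prev_a) + (bs - prev_b)
        seg_a = a[as_:ae]
        seg_b = b[bs:be]
        matches += sum(x == y for x, y in zip(seg_a, seg_b))
        cols += ae - as_
        prev_a, prev_b = ae, be
    return matches / cols if cols else 0.0
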