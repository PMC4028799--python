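"""Depth-based mitochondrial genome recovery.

The mt genome is present at tens to thousands of copies per cell, so mt
k-mers and contigs sit in a high-depth mode well separated from the nuclear
mode. The pipeline: (1) a minimal de Bruijn assembler turns reads into
unitigs with per-contig mean k-mer depth; (2) contigs similar to a
reference mt genome (E <= 0.001) whose depth clears the valley between the
two modes of the log-depth histogram are classified as mitochondrial;
(3) mt contigs are ordered and merged against the reference (circular
rotation handled by placing on a doubled reference), with unfilled
reference intervals recorded as gaps; (4) gaps are confirmed by re-aligning
reads across each junction; (5) protein-coding genes are annotated from a
reference gene set and concatenated in reference order for phylogenetics.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .io_formats import ReadPair, SeqRecord, revcomp
from .similarity import LocalSearch, make_local_aligner


@dataclass
class Contig:
    seq: str
    depth: float

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Annotation:
    gene: str
    start: int        # 1-based inclusive on the draft sequence
    end: int
    strand: str
    identity: float
    ref_index: int    # position in the reference gene order


@dataclass
class MtGenomeDraft:
    sequence: str
    source_intervals: list[tuple[int, int, int, int]]  # draft s,e / ref s,e (1-based)
    gaps: list[tuple[int, int]]                        # reference coords, 1-based
    annotations: list[Annotation] = field(default_factory=list)
    missing_genes: list[str] = field(default_factory=list)
    conflicts: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# de Bruijn assembly

def count_kmers(seqs: list[str], k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for seq in seqs:
        for s in (seq, revcomp(seq)):
            for i in range(len(s) - k + 1):
                kmer = s[i : i + k]
                if "N" not in kmer:
                    counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def prune_threshold(counts: dict[str, int]) -> int:
    """max(2, depth mode / 20): a documented stand-in for auto cutoffs."""
    hist = Counter(c for c in counts.values() if c >= 2)
    if not hist:
        return 2
    mode = hist.most_common(1)[0][0]
    return max(2, mode // 20)


def assemble_contigs(
    reads: list[str] | list[ReadPair],
    k: int,
    min_contig_len: int = 200,
    prune: int | None = None,
) -> list[Contig]:
    """Maximal non-branching paths of the k-mer graph, low-frequency pruned.

    Per-contig depth is the mean multiplicity of its k-mers (both strands
    counted, reported per strand). Contigs shorter than the floor are
    dropped; reverse-complement duplicates are collapsed.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    seqs = _flatten(reads)
    if seqs and k >= max(len(s) for s in seqs):
        raise ValueError("k must be smaller than the read length")
    counts = count_kmers(seqs, k)
    thr = prune if prune is not None else prune_threshold(counts)
    counts = {km: c for km, c in counts.items() if c >= thr}
    if not counts:
        warnings.warn("no k-mers survive pruning; empty assembly")
        return []

    prefix_out: dict[str, list[str]] = {}
    suffix_in: dict[str, list[str]] = {}
    for km in counts:
        prefix_out.setdefault(km[:-1], []).append(km)
        suffix_in.setdefault(km[1:], []).append(km)

    def successors(km: str) -> list[str]:
        return prefix_out.get(km[1:], [])

    def predecessors(km: str) -> list[str]:
        return suffix_in.get(km[:-1], [])

    visited: set[str] = set()
    raw: list[tuple[str, float]] = []

    def walk(start: str) -> None:
        chain = [start]
        visited.add(start)
        cur = start
        while True:
            succ = successors(cur)
            if len(succ) != 1:
                break
            nxt = succ[0]
            if nxt in visited or len(predecessors(nxt)) != 1:
                break
            chain.append(nxt)
            visited.add(nxt)
            cur = nxt
        seq = chain[0] + "".join(km[-1] for km in chain[1:])
        # a closed cycle (clean circular genome) repeats its first k-1 bases
        if len(chain) > 1 and chain[0] in successors(cur):
            seq = seq[: len(chain)]
        depth = float(np.mean([counts[km] for km in chain]))
        raw.append((seq, depth))

    for km in counts:
        if km in visited:
            continue
        preds = predecessors(km)
        if len(preds) != 1 or len(successors(preds[0])) != 1:
            walk(km)
    # remaining k-mers lie on simple cycles (e.g. a clean circular genome)
    for km in list(counts):
        if km not in visited:
            walk(km)

    seen: set[str] = set()
    contigs: list[Contig] = []
    for seq, depth in sorted(raw, key=lambda t: (-len(t[0]), t[0])):
        if len(seq) < min_contig_len:
            continue
        canon = min(seq, revcomp(seq))
        if canon in seen:
            continue
        # a circular genome yields one cycle per strand, broken at arbitrary
        # points: collapse rotations of an equal-length kept contig
        if any(len(c.seq) == len(canon)
               and (canon in c.seq + c.seq or revcomp(canon) in c.seq + c.seq)
               for c in contigs):
            continue
        seen.add(canon)
        contigs.append(Contig(canon, depth))
    return contigs


def _flatten(reads) -> list[str]:
    if reads and isinstance(reads[0], ReadPair):
        return [r for p in reads for r in (p.r1.seq, p.r2.seq)]
    return list(reads)


def n50(lengths: list[int]) -> int:
    if not lengths:
        return 0
    total = sum(lengths)
    acc = 0
    for ln in sorted(lengths, reverse=True):
        acc += ln
        if acc * 2 >= total:
            return ln
    return lengths[-1]


def select_assembly(
    reads,
    kmer_min: int,
    kmer_max: int,
    reference_len: int,
    min_contig_len: int = 200,
) -> tuple[int, list[Contig]]:
    """Try every odd k in range; prefer assemblies whose total length is
    within 20% of the reference length, then maximise N50."""
    candidates: list[tuple[bool, int, int, list[Contig]]] = []
    for k in range(kmer_min, kmer_max + 1, 2):
        contigs = assemble_contigs(reads, k, min_contig_len)
        total = sum(len(c) for c in contigs)
        ok = abs(total - reference_len) <= 0.2 * reference_len
        candidates.append((ok, n50([len(c) for c in contigs]), k, contigs))
    candidates.sort(key=lambda t: (t[0], t[1]), reverse=True)
    best = candidates[0]
    return best[2], best[3]


# ---------------------------------------------------------------------------
# coverage classification

def depth_cutoff(depths: list[float]) -> float | None:
    """Valley of the (smoothed) log10-depth histogram separating the
    high-depth mt mode from the low-depth nuclear mode; None if unimodal."""
    if len(depths) < 2:
        return None
    logs = np.log10(np.asarray(depths, dtype=float))
    if len(logs) < 30:
        # sparse case: the valley is the largest gap between sorted depths
        srt = np.sort(logs)
        gaps = np.diff(srt)
        i = int(np.argmax(gaps))
        if gaps[i] < 0.5:
            return None
        return float(10 ** ((srt[i] + srt[i + 1]) / 2))
    hist, edges = np.histogram(logs, bins=24)
    smooth = gaussian_filter1d(hist.astype(float), sigma=1.0)
    peaks = [i for i in range(len(smooth))
             if smooth[i] > 0
             and (i == 0 or smooth[i] >= smooth[i - 1])
             and (i == len(smooth) - 1 or smooth[i] >= smooth[i + 1])]
    if len(peaks) < 2:
        return None
    peaks = sorted(peaks, key=lambda i: -smooth[i])[:2]
    lo, hi = sorted(peaks)
    valley = lo + int(np.argmin(smooth[lo : hi + 1]))
    # a genuine bimodal split: well-separated peaks with a deep valley
    if (edges[hi] - edges[lo] < 0.5
            or smooth[valley] > 0.5 * min(smooth[lo], smooth[hi])):
        return None
    return float(10 ** ((edges[valley] + edges[valley + 1]) / 2))


def classify_mt_contigs(
    contigs: list[Contig],
    reference_mt: str,
    mt_evalue: float = 0.001,
) -> tuple[list[Contig], float | None]:
    """Similarity-candidate contigs above the coverage cut-off."""
    if not contigs:
        raise ValueError("no contigs to classify")
    search = LocalSearch(reference_mt)
    candidates = []
    for c in contigs:
        hit = search.best_hit("contig", c.seq)
        if hit is not None and hit.evalue <= mt_evalue:
            candidates.append(c)
    cutoff = depth_cutoff([c.depth for c in contigs])
    if cutoff is None:
        warnings.warn("unimodal depth distribution; similarity-only mt classification")
        return candidates, None
    return [c for c in candidates if c.depth >= cutoff], cutoff


def assemble_mt(
    reads,
    reference_mt: str,
    kmer_min: int = 39,
    kmer_max: int = 51,
    min_contig_len: int = 200,
    mt_evalue: float = 0.001,
) -> tuple[list[Contig], float | None, int]:
    """Two-pass mt assembly: identify the coverage cut-off from a first
    assembly, then re-assemble with that cut-off as the k-mer pruning floor
    so recurrent sequencing-error and nuclear k-mers vanish.

    Returns (mt contigs, cutoff, chosen k).
    """
    k, contigs = select_assembly(reads, kmer_min, kmer_max,
                                 len(reference_mt), min_contig_len)
    if not contigs:
        return [], None, k
    mt_first, cutoff = classify_mt_contigs(contigs, reference_mt, mt_evalue)
    if cutoff is None:
        return mt_first, None, k
    second = assemble_contigs(_flatten(reads), k, min_contig_len,
                              prune=max(2, int(cutoff)))
    if not second:
        return mt_first, cutoff, k
    search = LocalSearch(reference_mt)
    mt_second = [c for c in second
                 if c.depth >= cutoff
                 and (h := search.best_hit("contig", c.seq)) is not None
                 and h.evalue <= mt_evalue]
    return (mt_second or mt_first), cutoff, k


# ---------------------------------------------------------------------------
# ordering / merging

def order_and_merge_contigs(mt_contigs: list[Contig], reference: str) -> MtGenomeDraft:
    """Place contigs on the reference, reference-sense, and merge.

    Placement uses a doubled reference so a contig rotated across the
    circular origin is split at the origin instead of dangling. Exact
    overlaps >= 20 bp are merged; unfilled reference intervals are recorded
    as gaps and padded with N to preserve the reference frame.
    """
    if not mt_contigs:
        raise ValueError("no mt contigs to order")
    L = len(reference)
    search = LocalSearch(reference + reference)
    pieces: list[tuple[int, str, float]] = []   # (ref start 0-based, seq, depth)
    for c in mt_contigs:
        hit = search.best_hit("contig", c.seq)
        if hit is None:
            continue
        seq = c.seq if hit.strand == "+" else revcomp(c.seq)
        start = (hit.ref_start - 1) % L
        placed = hit.aligned_query
        if start + len(placed) <= L:
            pieces.append((start, placed, c.depth))
        else:
            split = L - start
            pieces.append((start, placed[:split], c.depth))
            pieces.append((0, placed[split:], c.depth))
    if not pieces:
        raise ValueError("no mt contig could be placed on the reference")
    pieces.sort(key=lambda t: (t[0], -len(t[1])))

    conflicts: list[str] = []
    merged: list[tuple[int, str, float]] = []
    for start, seq, depth in pieces:
        if not merged:
            merged.append((start, seq, depth))
            continue
        ms, mseq, mdepth = merged[-1]
        mend = ms + len(mseq)
        if start > mend:
            merged.append((start, seq, depth))
            continue
        overlap = mend - start
        if overlap >= len(seq):
            # fully contained; keep the higher-depth version
            if depth > mdepth and seq != mseq[start - ms : start - ms + len(seq)]:
                conflicts.append(f"contained contig at ref {start + 1} differs; kept deeper")
            continue
        if overlap >= 20 and mseq[-overlap:] == seq[:overlap]:
            merged[-1] = (ms, mseq + seq[overlap:], max(mdepth, depth))
        elif overlap < 20:
            # tiny or inexact overlap: butt-join at the reference coordinate
            merged[-1] = (ms, mseq[: start - ms] + seq, max(mdepth, depth))
        else:
            conflicts.append(
                f"inconsistent overlap of {overlap} bp at ref {start + 1}; kept deeper")
            if depth > mdepth:
                merged[-1] = (ms, mseq[: start - ms] + seq, depth)

    out: list[str] = []
    intervals: list[tuple[int, int, int, int]] = []
    gaps: list[tuple[int, int]] = []
    pos = 0
    draft_pos = 0
    for start, seq, _depth in merged:
        if start > pos:
            gaps.append((pos + 1, start))
            out.append("N" * (start - pos))
            draft_pos += start - pos
        out.append(seq)
        intervals.append((draft_pos + 1, draft_pos + len(seq), start + 1, start + len(seq)))
        draft_pos += len(seq)
        pos = max(pos, start + len(seq))
    if pos < L:
        gaps.append((pos + 1, L))
    draft = MtGenomeDraft("".join(out), intervals, gaps)
    draft.conflicts = conflicts
    return draft


# ---------------------------------------------------------------------------
# gap confirmation

@dataclass
class GapEvidence:
    ref_start: int
    ref_end: int
    spanning_reads: int
    confirmed: bool


def verify_gaps(
    reads: list[ReadPair],
    draft: MtGenomeDraft,
    reference: str,
    max_gap_openings: int = 5,
    min_support: int = 3,
    window: int = 150,
) -> list[GapEvidence]:
    """Confirm each recorded gap by aligning reads across the junction."""
    report: list[GapEvidence] = []
    aligner = make_local_aligner()
    seqs = _flatten(reads)
    for ref_s, ref_e in draft.gaps:
        win, jx = _junction_window(draft, ref_s, ref_e, window)
        if win is None or len(win) < 40:
            report.append(GapEvidence(ref_s, ref_e, 0, False))
            continue
        search = LocalSearch(win)
        support = 0
        for seq in seqs:
            hit = search.best_hit("r", seq)
            if hit is None or hit.evalue > 1e-3:
                continue
            if not (hit.ref_start <= jx - 10 and hit.ref_end >= jx + 10):
                continue
            q = seq if hit.strand == "+" else revcomp(seq)
            aln = aligner.align(win, q)[0]
            openings = len(aln.aligned[0]) - 1
            if openings <= max_gap_openings:
                support += 1
                if support >= min_support:
                    break
        report.append(GapEvidence(ref_s, ref_e, support, support >= min_support))
    return report


def _junction_window(draft: MtGenomeDraft, gap_s: int, gap_e: int,
                     window: int) -> tuple[str | None, int]:
    """Sequence across the gap junction: tail of the contig ending before the
    gap joined to the head of the contig starting after it."""
    left = right = None
    for ds, de, rs, re in draft.source_intervals:
        if re < gap_s and (left is None or re > left[3]):
            left = (ds, de, rs, re)
        if rs > gap_e and (right is None or rs < right[2]):
            right = (ds, de, rs, re)
    if left is None or right is None:
        return None, 0
    tail = draft.sequence[max(left[0] - 1, left[1] - window) : left[1]]
    head = draft.sequence[right[0] - 1 : min(right[1], right[0] - 1 + window)]
    return tail + head, len(tail)


def group_gaps(per_isolate: dict[str, list[tuple[int, int]]],
               taxon_of: dict[str, str]) -> dict[tuple[str, tuple[int, int]], list[str]]:
    """Group identical gap coordinates across isolates of the same taxon."""
    grouped: dict[tuple[str, tuple[int, int]], list[str]] = {}
    for isolate, gaps in per_isolate.items():
        for gap in gaps:
            grouped.setdefault((taxon_of[isolate], gap), []).append(isolate)
    return grouped


# ---------------------------------------------------------------------------
# annotation / stats

def annotate_protein_genes(
    mt_seq: str,
    ref_genes: list[SeqRecord],
    min_identity: float = 0.70,
) -> tuple[list[Annotation], list[str]]:
    """Best local-alignment interval for each reference gene, either strand,
    reported in reference order; genes below the identity floor are missing."""
    aligner = make_local_aligner()
    annos: list[Annotation] = []
    missing: list[str] = []
    for idx, gene in enumerate(ref_genes):
        best = None
        for strand, q in (("+", gene.seq), ("-", revcomp(gene.seq))):
            aln = aligner.align(mt_seq, q)[0]
            if best is None or aln.score > best[0].score:
                best = (aln, strand)
        aln, strand = best
        ident = _aln_identity(aln)
        if ident < min_identity:
            missing.append(gene.id)
            continue
        start = int(aln.aligned[0][0][0]) + 1
        end = int(aln.aligned[0][-1][1])
        annos.append(Annotation(gene.id, start, end, strand, ident, idx))
    annos.sort(key=lambda a: a.ref_index)
    return annos, missing


def _aln_identity(aln) -> float:
    t_blocks, q_blocks = aln.aligned
    target = str(aln.sequences[0])
    query = str(aln.sequences[1])
    matches = cols = 0
    prev_t = int(t_blocks[0][0])
    prev_q = int(q_blocks[0][0])
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        ts, te, qs, qe = int(ts), int(te), int(qs), int(qe)
        cols += (ts - prev_t) + (qs - prev_q) + (te - ts)
        matches += sum(a == b for a, b in zip(target[ts:te], query[qs:qe]))
        prev_t, prev_q = te, qe
    return matches / cols if cols else 0.0


def concatenate_complement(
    annotations: list[Annotation],
    mt_seq: str,
) -> str:
    """Strand-resolved gene subsequences joined in reference order."""
    if not annotations:
        raise ValueError("no complement: empty annotation list")
    parts = []
    for a in sorted(annotations, key=lambda a: a.ref_index):
        sub = mt_seq[a.start - 1 : a.end]
        parts.append(sub if a.strand == "+" else revcomp(sub))
    return "".join(parts)


@dataclass
class GenomeStats:
    total_length_bp: int
    pct_protein_gene_content: float
    pct_identity_complement: float | None


def genome_stats(
    draft_seq: str,
    annotations: list[Annotation],
    reference_complement: str | None = None,
) -> GenomeStats:
    """Table-style summary: total length, % protein gene content, and %
    identity of the concatenated complement to the reference complement."""
    gene_len = sum(a.end - a.start + 1 for a in annotations)
    content = 100.0 * gene_len / len(draft_seq) if draft_seq else 0.0
    ident = None
    if reference_complement is not None and annotations:
        from .similarity import align_identity
        cat = concatenate_complement(annotations, draft_seq)
        ident = 100.0 * align_identity(cat, reference_complement)
    return GenomeStats(len(draft_seq), round(content, 2),
                       round(ident, 2) if ident is not None else None)
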