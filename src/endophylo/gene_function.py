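"""Structural comparison of recovered gene copies and functionality calls.

A recovered copy is globally aligned to its reference gene with affine
gaps. Maximal runs of reference positions absent from the copy (>= 10 bp
by default) are reported as deletion intervals in 1-based inclusive
reference coordinates. Functionality is predicted by projecting the
reference coding exons through the alignment and translating the copy's
coding sequence: a copy is functional only if the reading frame is intact,
translation has no internal stop, and the protein covers >= 95% of the
reference protein length.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .synthetic import CdsModel
from .similarity import make_global_aligner


@dataclass
class DeletionInterval:
    marker: str
    copy_id: str
    start: int     # 1-based inclusive reference coordinates
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class FunctionCall:
    marker: str
    copy_id: str
    verdict: str   # "functional" | "non-functional"
    reason: str    # "intact" | "frameshift" | "premature stop" | "truncated"


class NotHomologousError(ValueError):
    pass


def _global_alignment(copy_seq: str, reference: str, min_identity: float = 0.5):
    aligner = make_global_aligner()
    aln = aligner.align(reference, copy_seq)[0]
    r_blocks, q_blocks = aln.aligned
    matches = 0
    for (rs, re), (qs, qe) in zip(r_blocks, q_blocks):
        seg_r = reference[int(rs) : int(re)]
        seg_q = copy_seq[int(qs) : int(qe)]
        matches += sum(a == b for a, b in zip(seg_r, seg_q))
    # identity over the shorter sequence, so free end gaps cannot hide a
    # spurious high-identity core
    denom = min(len(reference), len(copy_seq))
    if denom == 0 or matches / denom < min_identity:
        raise NotHomologousError(
            f"copy aligns at identity {matches / max(denom, 1):.2f} < {min_identity}")
    return aln


def _ref_to_copy_map(aln, ref_len: int) -> list[int | None]:
    """For each 0-based reference position: matched copy position or None."""
    mapping: list[int | None] = [None] * ref_len
    r_blocks, q_blocks = aln.aligned
    for (rs, re), (qs, qe) in zip(r_blocks, q_blocks):
        rs, re, qs = int(rs), int(re), int(qs)
        for off in range(re - rs):
            mapping[rs + off] = qs + off
    return mapping


def detect_structural_deletions(
    copy_seq: str,
    reference: str,
    marker: str = "gene",
    copy_id: str = "copy1",
    min_del_len: int = 10,
) -> list[DeletionInterval]:
    """Maximal unmatched reference runs >= min_del_len, in ref coordinates."""
    aln = _global_alignment(copy_seq, reference)
    mapping = _ref_to_copy_map(aln, len(reference))
    deletions: list[DeletionInterval] = []
    run_start: int | None = None
    for pos in range(len(reference) + 1):
        absent = pos < len(reference) and mapping[pos] is None
        if absent and run_start is None:
            run_start = pos
        elif not absent and run_start is not None:
            if pos - run_start >= min_del_len:
                deletions.append(DeletionInterval(marker, copy_id, run_start + 1, pos))
            run_start = None
    return deletions


def classify_copy_functionality(
    copy_seq: str,
    reference: str,
    cds: CdsModel,
    marker: str = "gene",
    copy_id: str = "copy1",
    min_protein_frac: float = 0.95,
) -> FunctionCall:
    """Predict whether a gene copy encodes an intact protein.

    Reference exon intervals are projected through the pairwise alignment;
    the copy's spliced coding sequence is translated with the standard
    nuclear genetic code.
    """
    aln = _global_alignment(copy_seq, reference)
    mapping = _ref_to_copy_map(aln, len(reference))

    ref_cds_len = cds.length
    copy_cds_parts: list[str] = []
    net_shift = 0
    for (ex_s, ex_e) in cds.exons:
        idxs = [mapping[p] for p in range(ex_s - 1, ex_e)]
        present = [i for i in idxs if i is not None]
        if not present:
            continue
        lo, hi = present[0], present[-1]
        # unaligned exon edges are truncation, not internal indels: count
        # only deletions strictly inside the aligned span
        lead = next(i for i, v in enumerate(idxs) if v is not None)
        trail = next(i for i, v in enumerate(reversed(idxs)) if v is not None)
        internal_del = sum(v is None for v in idxs[lead : len(idxs) - trail])
        internal_ins = (hi - lo + 1) - sum(v is not None for v in idxs)
        net_shift += internal_ins - internal_del
        # keep the reference codon frame when the exon start is clipped
        segment = copy_seq[lo : hi + 1]
        copy_cds_parts.append(segment[(-lead) % 3 :])
    copy_cds = "".join(copy_cds_parts)
    if not copy_cds:
        return FunctionCall(marker, copy_id, "non-functional", "truncated")
    if net_shift % 3 != 0:
        return FunctionCall(marker, copy_id, "non-functional", "frameshift")

    protein = str(Seq(copy_cds[: len(copy_cds) - len(copy_cds) % 3]).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        return FunctionCall(marker, copy_id, "non-functional", "premature stop")
    if len(protein) < min_protein_frac * (ref_cds_len // 3 - 1):
        return FunctionCall(marker, copy_id, "non-functional", "truncated")
    return FunctionCall(marker, copy_id, "functional", "intact")
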