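"""Quality trimming and filtering of read pairs.

Sliding-window 3' trimming: a read is cut at the first window whose mean
Phred quality drops below the threshold, then discarded if shorter than the
minimum length. By default a pair is dropped whenever either mate fails,
because downstream recruitment assumes intact pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import FastqRecord, ReadPair


@dataclass
class QcParams:
    window_len: int = 4
    min_mean_q: float = 20.0
    min_read_len: int = 50
    drop_pair_if_either_fails: bool = True

    def __post_init__(self) -> None:
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        if not (0 <= self.min_mean_q <= 60):
            raise ValueError("min_mean_q must be in [0, 60]")


@dataclass
class QcStats:
    pairs_in: int = 0
    pairs_out: int = 0
    mean_q_in: float = 0.0
    mean_q_out: float = 0.0
    bases_in: int = 0
    bases_out: int = 0


def trim_read(rec: FastqRecord, params: QcParams) -> FastqRecord | None:
    """Trim at the first failing quality window; None if too short after.

    Within the failing window, bases still at or above the threshold are
    kept, so a clean run directly abutting the low-quality tail survives.
    """
    q = np.asarray(rec.qual, dtype=float)
    w = params.window_len
    cut = len(q)
    for start in range(0, len(q) - w + 1):
        if q[start : start + w].mean() < params.min_mean_q:
            cut = start
            while cut < len(q) and q[cut] >= params.min_mean_q:
                cut += 1
            break
    if cut < params.min_read_len or cut == 0:
        return None
    if cut == len(q):
        return rec
    return FastqRecord(rec.id, rec.seq[:cut], rec.qual[:cut])


def trim_and_filter(pairs: list[ReadPair], params: QcParams) -> tuple[list[ReadPair], QcStats]:
    stats = QcStats(pairs_in=len(pairs))
    q_in: list[int] = []
    q_out: list[int] = []
    surviving: list[ReadPair] = []
    for pair in pairs:
        q_in.extend(pair.r1.qual)
        q_in.extend(pair.r2.qual)
        t1 = trim_read(pair.r1, params)
        t2 = trim_read(pair.r2, params)
        if params.drop_pair_if_either_fails:
            if t1 is None or t2 is None:
                continue
        else:
            if t1 is None and t2 is None:
                continue
            t1 = t1 or FastqRecord(pair.r1.id, "N", [0])
            t2 = t2 or FastqRecord(pair.r2.id, "N", [0])
        surviving.append(ReadPair(t1, t2))
        q_out.extend(t1.qual)
        q_out.extend(t2.qual)
    stats.pairs_out = len(surviving)
    stats.bases_in = len(q_in)
    stats.bases_out = len(q_out)
    stats.mean_q_in = float(np.mean(q_in)) if q_in else 0.0
    stats.mean_q_out = float(np.mean(q_out)) if q_out else 0.0
    return surviving, stats
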