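"""Readers and writers for the plain-text formats the pipeline touches.

FASTA and FASTQ parsing is deliberately strict: the pipeline's sequence
carriers are restricted to the uppercase DNA alphabet ``{A,C,G,T,N}`` and
Phred+33 qualities, and malformed input fails with a :class:`FormatError`
naming the offending line rather than propagating silently.

Newick trees are handled through :mod:`dendropy`; this module only wraps
serialisation so that internal bootstrap-support labels survive a round trip.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import dendropy

DNA_ALPHABET = frozenset("ACGTN")
#: '-' marks a base deleted relative to the reference inside an aligned span.
GAP = "-"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised for malformed FASTA/FASTQ/Newick input."""


@dataclass
class SeqRecord:
    """A named DNA sequence over {A,C,G,T,N}."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.seq:
            raise FormatError(f"record {self.id!r} has empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r} contains illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class FastqRecord:
    """A read with per-base Phred quality scores (Phred+33 on disk)."""

    id: str
    seq: str
    qual: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("FASTQ record with empty id")
        if len(self.qual) != len(self.seq):
            raise FormatError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )
        if self.qual and (min(self.qual) < 0 or max(self.qual) > 60):
            raise FormatError(f"record {self.id!r}: Phred score outside [0, 60]")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReadPair:
    """Two mates of a paired-end fragment, FR orientation as sequenced."""

    r1: FastqRecord
    r2: FastqRecord

    @property
    def id(self) -> str:
        return self.r1.id


def parse_fasta(source: str | os.PathLike) -> list[SeqRecord]:
    """Parse FASTA from a path or a literal text string.

    Line-wrapped sequences are joined; sequences are uppercased.
    """
    text = _read_text(source)
    records: list[SeqRecord] = []
    header: str | None = None
    chunks: list[str] = []
    header_line = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                records.append(_make_fasta_record(header, chunks, header_line))
            header, chunks, header_line = line[1:].strip(), [], lineno
        else:
            if header is None:
                raise FormatError(f"line {lineno}: sequence data before any header")
            chunks.append(line.upper())
    if header is not None:
        records.append(_make_fasta_record(header, chunks, header_line))
    if not records:
        raise FormatError("empty FASTA input")
    return records


def _make_fasta_record(header: str, chunks: list[str], lineno: int) -> SeqRecord:
    parts = header.split(None, 1)
    if not parts:
        raise FormatError(f"line {lineno}: empty FASTA header")
    seq = "".join(chunks)
    if not seq:
        raise FormatError(f"line {lineno}: record {parts[0]!r} has empty sequence")
    try:
        return SeqRecord(parts[0], seq, parts[1] if len(parts) > 1 else "")
    except FormatError as exc:
        raise FormatError(f"line {lineno}: {exc}") from None


def write_fasta(records: list[SeqRecord], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(fasta_text(records, width=width))


def fasta_text(records: list[SeqRecord], width: int = 70) -> str:
    out = io.StringIO()
    for rec in records:
        head = f">{rec.id} {rec.description}".rstrip()
        out.write(head + "\n")
        for i in range(0, len(rec.seq), width):
            out.write(rec.seq[i : i + width] + "\n")
    return out.getvalue()


def _read_text(source: str | os.PathLike) -> str:
    if isinstance(source, str) and ("\n" in source or source.startswith(">")):
        return source
    with open(source) as fh:
        return fh.read()


def decode_qual(qual: str) -> list[int]:
    return [ord(c) - 33 for c in qual]


def encode_qual(scores: list[int]) -> str:
    return "".join(chr(q + 33) for q in scores)


def parse_fastq(path: str | os.PathLike) -> list[FastqRecord]:
    records: list[FastqRecord] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) % 4 != 0:
        raise FormatError(f"{path}: FASTQ line count {len(lines)} not a multiple of 4")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        lineno = i + 1
        if not head.startswith("@"):
            raise FormatError(f"line {lineno}: expected '@' header, got {head[:20]!r}")
        if not plus.startswith("+"):
            raise FormatError(f"line {lineno + 2}: expected '+' separator")
        rid = head[1:].split()[0] if head[1:] else ""
        try:
            records.append(FastqRecord(rid, seq.upper(), decode_qual(qual)))
        except FormatError as exc:
            raise FormatError(f"line {lineno}: {exc}") from None
    return records


def parse_fastq_pairs(path_r1: str | os.PathLike, path_r2: str | os.PathLike) -> list[ReadPair]:
    """Read two position-synchronised FASTQ files into mate pairs."""
    r1 = parse_fastq(path_r1)
    r2 = parse_fastq(path_r2)
    if len(r1) != len(r2):
        raise FormatError(
            f"unpaired files: {len(r1)} records in {path_r1} vs {len(r2)} in {path_r2}"
        )
    return [ReadPair(a, b) for a, b in zip(r1, r2)]


def write_fastq_pairs(pairs: list[ReadPair], path_r1, path_r2) -> None:
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.r1.id}\n{p.r1.seq}\n+\n{encode_qual(p.r1.qual)}\n")
            f2.write(f"@{p.r2.id}\n{p.r2.seq}\n+\n{encode_qual(p.r2.qual)}\n")


# ---------------------------------------------------------------------------
# Newick

def tree_to_newick(tree: dendropy.Tree) -> str:
    """Serialise with branch lengths and internal support labels."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        suppress_internal_node_labels=False,
    ).strip()


def tree_from_newick(text: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(data=text, schema="newick", suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises assorted error types
        raise FormatError(f"Newick parse error: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise FormatError("duplicate leaf labels in Newick input")
    return tree
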