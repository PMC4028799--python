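"""Synthetic heteroploid endophyte genomes with full ground truth.

The simulator emulates the biological structure of asexual grass-endophyte
hybrids: 2-3 diverged progenitor sub-genomes per hybrid, one copy of each
nuclear marker gene (*tub2*, *tefA*, *perA*) per sub-genome with optional
copy loss and explicit multi-hundred-bp deletions, a single high-copy
circular mitochondrial genome carrying an ordered 13-gene protein-coding
complement, and Illumina-style paired-end reads (~400 bp inserts drawn from
100-900 bp fragments, FR orientation).

Every stochastic event is recorded so downstream stages (copy number,
consensus identity, deletion recovery, mt classification, tree topology)
can be scored against truth without re-simulation.

Markers carrying a coding-sequence model evolve under a stop-avoiding
substitution process (purifying selection against nonsense mutations), so a
copy is non-functional only when a lesion is planted deliberately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .io_formats import FastqRecord, ReadPair, SeqRecord, revcomp

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}

#: marker gene lengths (bp); perA is the long peramine-synthetase gene
MARKER_LENGTHS = {"tub2": 1500, "tefA": 1000, "perA": 5500}
MARKER_ORDER = ("tub2", "tefA", "perA")

#: scaled-down 13-gene mitochondrial protein complement, fixed reference order
MT_GENE_LENGTHS = [
    ("nad1", 550), ("nad2", 700), ("nad3", 250), ("nad4", 700),
    ("nad4L", 180), ("nad5", 900), ("nad6", 300), ("cob", 650),
    ("cox1", 950), ("cox2", 450), ("cox3", 500), ("atp6", 450), ("atp8", 120),
]
MT_GENOME_LEN = 15000
FLANK_BP = 2000


@dataclass
class CdsModel:
    """Exon intervals (1-based inclusive) of the coding sequence on a gene."""

    exons: list[tuple[int, int]]

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass
class Ancestor:
    markers: dict[str, str]
    marker_cds: dict[str, CdsModel]
    mt_genes: dict[str, str]          # plus-sense gene sequences
    mt_gene_order: list[str]
    mt_gene_strands: dict[str, str]
    mt_intergenic: list[str]          # spacer i precedes gene i; last closes circle
    background: str


@dataclass
class Lineage:
    label: str
    divergence: float
    markers: dict[str, str]
    mt_genome: str
    mt_annotations: list[tuple[str, int, int, str]]  # (gene, start, end, strand) 1-based
    mt_genes: dict[str, str]
    background: str


@dataclass
class LineageModel:
    ancestor: Ancestor
    labels: list[str]
    divergences: list[float]
    indel_rate: float = 0.0
    indel_mean_len: float = 3.0

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.divergences):
            raise ValueError("labels and divergences must align")
        for p in self.divergences:
            if not (0.0 <= p < 0.75):
                raise ValueError(f"divergence {p} outside [0, 0.75)")
        if self.indel_rate < 0:
            raise ValueError("indel rate must be >= 0")


@dataclass
class CopyTruth:
    marker: str
    copy_id: str
    donor: str
    seq: str                       # copy sequence as embedded (deletions excised)
    strand: str                    # strand of embedding in the hybrid genome
    deletions: list[tuple[int, int]] = field(default_factory=list)
    lesions: list[str] = field(default_factory=list)


@dataclass
class HybridTruth:
    k: int
    donors: list[str]
    copies: dict[str, list[CopyTruth]]
    lost: list[tuple[str, str]]
    deletions: list[tuple[str, str, int, int]]   # (marker, donor, start, end)
    mt_donor: str | None = None
    mt_ratio: float | None = None


@dataclass
class Hybrid:
    genome: str
    truth: HybridTruth


# ---------------------------------------------------------------------------
# ancestor construction

def random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons-2) stop-free codons + TAA."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = random_dna(rng, 3)
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def make_ancestor(seed: int | np.random.Generator) -> Ancestor:
    rng = np.random.default_rng(seed)
    markers: dict[str, str] = {}
    marker_cds: dict[str, CdsModel] = {}
    for name in MARKER_ORDER:
        length = MARKER_LENGTHS[name]
        # 100 bp UTR, then a single-exon CDS filling most of the gene
        n_codons = (length - 200) // 3
        cds = random_cds(rng, n_codons)
        gene = random_dna(rng, 100) + cds + random_dna(rng, length - 100 - len(cds))
        markers[name] = gene
        marker_cds[name] = CdsModel([(101, 100 + len(cds))])

    mt_genes = {name: random_cds(rng, length // 3) for name, length in MT_GENE_LENGTHS}
    order = [name for name, _ in MT_GENE_LENGTHS]
    strands = {name: "+" for name in order}
    strands["nad6"] = "-"
    total_gene = sum(len(s) for s in mt_genes.values())
    spacer = (MT_GENOME_LEN - total_gene) // len(order)
    intergenic = [random_dna(rng, spacer) for _ in order]
    background = random_dna(rng, 24000)
    return Ancestor(markers, marker_cds, mt_genes, order, strands, intergenic, background)


def assemble_mt_genome(
    genes: dict[str, str],
    order: list[str],
    strands: dict[str, str],
    intergenic: list[str],
) -> tuple[str, list[tuple[str, int, int, str]]]:
    """Concatenate spacer+gene blocks; genome origin is the first gene's spacer."""
    parts: list[str] = []
    annos: list[tuple[str, int, int, str]] = []
    pos = 0
    for i, name in enumerate(order):
        parts.append(intergenic[i])
        pos += len(intergenic[i])
        g = genes[name] if strands[name] == "+" else revcomp(genes[name])
        annos.append((name, pos + 1, pos + len(g), strands[name]))
        parts.append(g)
        pos += len(g)
    return "".join(parts), annos


# ---------------------------------------------------------------------------
# sequence evolution

def _substitute(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor-style iid substitution: each site mutates with prob p
    to one of the three alternative bases, uniformly."""
    out = seq.copy()
    hits = np.nonzero(rng.random(len(seq)) < p)[0]
    if len(hits):
        shift = rng.integers(1, 4, size=len(hits))
        idx = np.searchsorted(BASES, out[hits])
        out[hits] = BASES[(idx + shift) % 4]
    return out


def evolve_sequence(
    seq: str,
    p: float,
    rng: np.random.Generator,
    indel_rate: float = 0.0,
    indel_mean_len: float = 3.0,
    protect_cds: CdsModel | None = None,
) -> str:
    """Evolve by iid substitutions at rate p and (optionally) short indels.

    With ``protect_cds``, substitutions creating an in-frame stop codon are
    redrawn, the initiator ATG and terminal stop are kept, and no indels are
    introduced inside exons (frame-preserving purifying selection).
    """
    if not (0.0 <= p < 0.75):
        raise ValueError(f"substitution rate {p} outside [0, 0.75)")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = _substitute(arr, p, rng)
    if protect_cds is not None:
        out = _repair_cds(out, arr, protect_cds, rng)
    result = out.tobytes().decode()
    if indel_rate > 0:
        result = _apply_indels(result, indel_rate, indel_mean_len, rng, protect_cds)
    return result


def _repair_cds(out, orig, cds: CdsModel, rng) -> np.ndarray:
    out = out.copy()
    for start, end in cds.exons:
        s0 = start - 1
        # keep initiator and terminal codons fixed
        out[s0 : s0 + 3] = orig[s0 : s0 + 3]
        out[end - 3 : end] = orig[end - 3 : end]
        for cpos in range(s0 + 3, end - 3, 3):
            codon = out[cpos : cpos + 3].tobytes().decode()
            if codon in _STOPS:
                while True:
                    j = int(rng.integers(3))
                    trial = bytearray(codon.encode())
                    trial[j] = int(BASES[rng.integers(4)])
                    t = trial.decode()
                    if t not in _STOPS:
                        out[cpos : cpos + 3] = np.frombuffer(bytes(trial), dtype=np.uint8)
                        break
    return out


def _apply_indels(seq: str, rate: float, mean_len: float, rng, protect: CdsModel | None) -> str:
    protected = np.zeros(len(seq), dtype=bool)
    if protect is not None:
        for s, e in protect.exons:
            protected[s - 1 : e] = True
    n_events = rng.poisson(rate * len(seq))
    sites = sorted(rng.integers(0, len(seq), size=n_events), reverse=True)
    out = seq
    for pos in sites:
        if protected[pos]:
            continue
        length = 1 + rng.geometric(1.0 / mean_len)
        if rng.random() < 0.5:
            out = out[:pos] + out[pos + length :]
        else:
            out = out[:pos] + random_dna(rng, length) + out[pos:]
    return out


def evolve_lineages(model: LineageModel, seed: int | np.random.Generator) -> dict[str, Lineage]:
    """Derive each progenitor lineage from the shared ancestor."""
    rng = np.random.default_rng(seed)
    anc = model.ancestor
    lineages: dict[str, Lineage] = {}
    for label, p in zip(model.labels, model.divergences):
        markers = {
            name: evolve_sequence(anc.markers[name], p, rng,
                                  protect_cds=anc.marker_cds.get(name))
            for name in anc.markers
        }
        genes = {n: evolve_sequence(s, p, rng, protect_cds=CdsModel([(1, len(s))]))
                 for n, s in anc.mt_genes.items()}
        spacers = [
            evolve_sequence(s, p, rng, indel_rate=model.indel_rate,
                            indel_mean_len=model.indel_mean_len)
            for s in anc.mt_intergenic
        ]
        mt_genome, annos = assemble_mt_genome(genes, anc.mt_gene_order,
                                              anc.mt_gene_strands, spacers)
        background = evolve_sequence(anc.background, p, rng,
                                     indel_rate=model.indel_rate,
                                     indel_mean_len=model.indel_mean_len)
        lineages[label] = Lineage(label, p, markers, mt_genome, annos, genes, background)
    return lineages


# ---------------------------------------------------------------------------
# hybrid composition

def apply_deletions(seq: str, deletions: list[tuple[int, int]]) -> str:
    """Excise 1-based inclusive intervals from a sequence."""
    for start, end in deletions:
        if not (1 <= start <= end <= len(seq)):
            raise ValueError(f"deletion {start}-{end} outside sequence of length {len(seq)}")
    out = seq
    for start, end in sorted(deletions, reverse=True):
        out = out[: start - 1] + out[end:]
    return out


def compose_heteroploid(
    lineages: dict[str, Lineage],
    donors: list[str],
    losses: list[tuple[str, str]] | None = None,
    deletions: list[tuple[str, str, int, int]] | None = None,
    stop_lesions: list[tuple[str, str, int]] | None = None,
    mt_donor: str | None = None,
    mt_ratio: float = 100.0,
    seed: int | np.random.Generator = 0,
) -> Hybrid:
    """Assemble a heteroploid hybrid nuclear genome.

    One copy of each marker per donor sub-genome (minus ``losses``), each
    flanked by >= 2 kb of that donor's background sequence; ``deletions``
    are excised from the named donor's copy; ``stop_lesions`` plant a
    premature stop codon at the given CDS codon index.
    """
    losses = losses or []
    deletions = deletions or []
    stop_lesions = stop_lesions or []
    rng = np.random.default_rng(seed)
    for marker, donor in losses:
        if donor not in donors:
            raise ValueError(f"loss donor {donor!r} not among hybrid donors")
    if mt_ratio < 1:
        raise ValueError("mt copy ratio must be >= 1")

    blocks: list[str] = []
    copies: dict[str, list[CopyTruth]] = {m: [] for m in MARKER_ORDER}
    n_markers = len(MARKER_ORDER)
    for di, donor in enumerate(donors):
        lin = lineages[donor]
        bg = lin.background
        seg = len(bg) // (2 * n_markers)
        if seg < FLANK_BP:
            raise ValueError("lineage background too short for 2 kb flanks")
        for mi, marker in enumerate(MARKER_ORDER):
            if (marker, donor) in losses:
                continue
            copy_seq = lin.markers[marker]
            dels = sorted((s, e) for m, d, s, e in deletions if m == marker and d == donor)
            lesions = []
            for m, d, codon_idx in stop_lesions:
                if m == marker and d == donor:
                    copy_seq = _plant_stop(copy_seq, codon_idx)
                    lesions.append(f"premature_stop@codon{codon_idx}")
            copy_seq = apply_deletions(copy_seq, dels)
            strand = "+" if rng.random() < 0.5 else "-"
            embedded = copy_seq if strand == "+" else revcomp(copy_seq)
            flank_l = bg[2 * mi * seg : 2 * mi * seg + FLANK_BP]
            flank_r = bg[(2 * mi + 1) * seg : (2 * mi + 1) * seg + FLANK_BP]
            blocks.append(flank_l + embedded + flank_r)
            copies[marker].append(
                CopyTruth(marker, f"{marker}.copy{di + 1}", donor, copy_seq,
                          strand, dels, lesions)
            )
    order = rng.permutation(len(blocks))
    genome = "".join(blocks[i] for i in order)
    truth = HybridTruth(
        k=len(donors),
        donors=list(donors),
        copies=copies,
        lost=list(losses),
        deletions=list(deletions),
        mt_donor=mt_donor or donors[0],
        mt_ratio=mt_ratio,
    )
    return Hybrid(genome, truth)


def _plant_stop(gene: str, codon_idx: int) -> str:
    # CDS starts at position 101 (1-based) in every synthetic marker
    pos = 100 + 3 * codon_idx
    return gene[:pos] + "TAA" + gene[pos + 3 :]


# ---------------------------------------------------------------------------
# read simulation

@dataclass
class ReadPlacement:
    pair_id: str
    source: str            # "nuclear" | "mt"
    start: int             # 0-based fragment start on the source
    length: int
    strand: str


def _quality_profile(read_len: int) -> np.ndarray:
    q = np.full(read_len, 40, dtype=np.int64)
    tail = min(10, read_len)
    q[read_len - tail :] = np.maximum(40 - 2 * np.arange(1, tail + 1), 2)
    return q


def simulate_paired_reads(
    nuclear_genome: str,
    mt_genome: str | None,
    coverage_nuclear: float,
    mt_ratio: float,
    read_len: int,
    config: PipelineConfig,
    seed: int | np.random.Generator,
    error_rate: float | None = None,
) -> tuple[list[ReadPair], list[ReadPlacement]]:
    """Simulate FR paired-end reads from the hybrid and its mt genome.

    Fragment lengths ~ Normal(insert_size, insert_size/5) truncated to
    [fragment_min, fragment_max]; the mt genome is circular (fragments may
    span the origin) and sampled at ``mt_ratio`` x nuclear coverage.
    Per-base substitution errors follow the quality profile (constant Q40
    with a quality drop over the last 10 cycles) unless ``error_rate``
    overrides it with a flat rate.
    """
    if coverage_nuclear <= 0:
        raise ValueError("coverage must be positive")
    if read_len > config.fragment_min_bp:
        raise ValueError("read length must not exceed the minimum fragment size")
    rng = np.random.default_rng(seed)
    qprof = _quality_profile(read_len)
    if error_rate is not None:
        err = np.full(read_len, error_rate)
        qprof = np.clip(np.round(-10 * np.log10(np.maximum(error_rate, 1e-6))), 2, 60
                        ).astype(np.int64) * np.ones(read_len, dtype=np.int64)
    else:
        err = np.power(10.0, -qprof / 10.0)
    qual = list(qprof)

    pairs: list[ReadPair] = []
    placements: list[ReadPlacement] = []
    jobs = [("nuclear", nuclear_genome, coverage_nuclear, False)]
    if mt_genome is not None:
        jobs.append(("mt", mt_genome, coverage_nuclear * mt_ratio, True))
    for source, genome, cov, circular in jobs:
        n_pairs = int(round(cov * len(genome) / (2 * read_len)))
        lengths = rng.normal(config.insert_size_bp, config.insert_size_bp / 5, size=n_pairs)
        lengths = np.clip(np.round(lengths), max(config.fragment_min_bp, read_len),
                          config.fragment_max_bp).astype(int)
        for i in range(n_pairs):
            flen = int(lengths[i])
            if circular:
                start = int(rng.integers(0, len(genome)))
                frag = _circular_slice(genome, start, flen)
            else:
                if flen >= len(genome):
                    flen = len(genome)
                start = int(rng.integers(0, len(genome) - flen + 1))
                frag = genome[start : start + flen]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                frag = revcomp(frag)
            r1 = _with_errors(frag[:read_len], err, rng)
            r2 = _with_errors(revcomp(frag[-read_len:]), err, rng)
            pid = f"{source}_{i}"
            pairs.append(ReadPair(FastqRecord(pid, r1, qual),
                                  FastqRecord(pid, r2, qual)))
            placements.append(ReadPlacement(pid, source, start, flen, strand))
    return pairs, placements


def _circular_slice(genome: str, start: int, length: int) -> str:
    end = start + length
    if end <= len(genome):
        return genome[start:end]
    return genome[start:] + genome[: end - len(genome)]


def _with_errors(seq: str, err: np.ndarray, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < err[: len(arr)])[0]
    if len(hits):
        shift = rng.integers(1, 4, size=len(hits))
        idx = np.searchsorted(BASES, arr[hits])
        arr[hits] = BASES[(idx + shift) % 4]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# study-scenario builder

@dataclass
class Dataset:
    """One simulated isolate plus the references the pipeline needs."""

    lineages: dict[str, Lineage]
    hybrid: Hybrid
    pairs: list[ReadPair]
    placements: list[ReadPlacement]
    marker_refs: dict[str, SeqRecord]
    marker_cds: dict[str, CdsModel]
    mt_reference: SeqRecord
    mt_ref_genes: list[SeqRecord]
    mt_genome: str


#: per-taxon hybrid structure mirroring the study's copy-number and perA
#: lesion patterns (donor labels are progenitor stand-ins)
TAXON_PATTERNS = {
    "Ncoen": dict(donors=["Ef", "Et", "FGC1"], losses=[],
                  fgc1_deletions=True, stop_lesions=[]),
    "FaTG2": dict(donors=["Ef", "FGC1"], losses=[],
                  fgc1_deletions=True, stop_lesions=[]),
    "FaTG3": dict(donors=["Et", "FGC1"], losses=[],
                  fgc1_deletions=True, stop_lesions=[]),
    "FaTG3like": dict(donors=["Et", "FGC1"], losses=[],
                      fgc1_deletions=False, stop_lesions=[("perA", "FGC1", 400)]),
    "UNS": dict(donors=["Ef", "FGC1"], losses=[],
                fgc1_deletions=True, stop_lesions=[("perA", "Ef", 300)]),
    "Nuncin": dict(donors=["Et", "Ebr"], losses=[("tub2", "Ebr")],
                   fgc1_deletions=False, stop_lesions=[("perA", "Ebr", 350)]),
}

#: the two shared perA deletions of the fescue-derived gene copy 1
FGC1_PERA_DELETIONS = [(1251, 1878), (4590, 4918)]

LINEAGE_LABELS = ["Ef", "Et", "FGC1", "Ebr"]


def build_dataset(
    taxon: str,
    seed: int,
    divergence: float = 0.05,
    coverage: float = 50.0,
    mt_ratio: float | None = None,
    read_len: int = 100,
    config: PipelineConfig | None = None,
    markers: tuple[str, ...] = MARKER_ORDER,
    error_rate: float | None = None,
) -> Dataset:
    """Simulate one isolate of a named taxon pattern, end to end.

    ``divergence`` is each progenitor lineage's expected substitutions/site
    from the common ancestor. ``mt_ratio=None`` skips mt read simulation.
    The marker references handed to recruitment are the ancestral gene
    sequences (the stand-in for the published reference accessions); the mt
    reference gene set is an outgroup-like complement ~10% diverged from the
    ancestor, mirroring the cross-genus reference used for annotation.
    """
    if taxon not in TAXON_PATTERNS:
        raise ValueError(f"unknown taxon pattern {taxon!r}; know {sorted(TAXON_PATTERNS)}")
    cfg = config or PipelineConfig(rng_seed=seed)
    pat = TAXON_PATTERNS[taxon]
    ss = np.random.SeedSequence(seed)
    s_anc, s_lin, s_comp, s_reads, s_out = ss.spawn(5)

    anc = make_ancestor(s_anc)
    model = LineageModel(anc, LINEAGE_LABELS, [divergence] * len(LINEAGE_LABELS))
    lineages = evolve_lineages(model, s_lin)

    deletions = []
    if pat["fgc1_deletions"]:
        deletions = [("perA", "FGC1", s, e) for s, e in FGC1_PERA_DELETIONS]
    hybrid = compose_heteroploid(
        lineages, pat["donors"], losses=pat["losses"], deletions=deletions,
        stop_lesions=pat["stop_lesions"], mt_ratio=mt_ratio or 1.0, seed=s_comp,
    )
    mt_genome = lineages[hybrid.truth.mt_donor].mt_genome
    pairs, placements = simulate_paired_reads(
        hybrid.genome, mt_genome if mt_ratio else None, coverage,
        mt_ratio or 1.0, read_len, cfg, s_reads, error_rate=error_rate,
    )

    out_rng = np.random.default_rng(s_out)
    ref_genes = [
        SeqRecord(n, evolve_sequence(s, 0.05, out_rng, protect_cds=CdsModel([(1, len(s))])))
        for n, s in ((name, anc.mt_genes[name]) for name in anc.mt_gene_order)
    ]
    mt_ref, _ = assemble_mt_genome(anc.mt_genes, anc.mt_gene_order,
                                   anc.mt_gene_strands, anc.mt_intergenic)
    return Dataset(
        lineages=lineages,
        hybrid=hybrid,
        pairs=pairs,
        placements=placements,
        marker_refs={m: SeqRecord(m, anc.markers[m]) for m in markers},
        marker_cds=dict(anc.marker_cds),
        mt_reference=SeqRecord("mt_reference", mt_ref),
        mt_ref_genes=ref_genes,
        mt_genome=mt_genome,
    )
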