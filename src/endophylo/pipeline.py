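"""End-to-end orchestration of the endophyte phylogenomics workflow.

Stages: synthetic data (or user FASTQ) -> quality trimming -> per-marker
read recruitment, padding and copy phasing -> copy functionality calls ->
depth-based mt genome assembly, annotation and stats -> per-marker and
concatenated phylogenies with bootstrap supports. Every product is written
to a report directory as FASTA / Newick / TSV; all randomness derives from
``PipelineConfig.rng_seed`` so identical seeds give identical reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import copy_recovery, gene_function, mito, synthetic
from .config import PipelineConfig
from .io_formats import SeqRecord, fasta_text
from .msa import p_distance_matrix, progressive_align, strip_ambiguous_columns
from .phylo import UTree, bootstrap_consensus, concatenate_markers
from .read_qc import QcParams, trim_and_filter
from .synthetic import MARKER_ORDER, Dataset


@dataclass
class MarkerResult:
    marker: str
    copies: copy_recovery.GeneCopySet
    donor_of_copy: dict[str, str] = field(default_factory=dict)
    pair_support: dict[str, float] = field(default_factory=dict)
    tree: UTree | None = None


@dataclass
class IsolateResult:
    taxon: str
    dataset: Dataset
    markers: dict[str, MarkerResult] = field(default_factory=dict)
    functionality: list[gene_function.FunctionCall] = field(default_factory=list)
    mt_draft: mito.MtGenomeDraft | None = None
    mt_stats: mito.GenomeStats | None = None
    mt_cutoff: float | None = None
    concat_tree: UTree | None = None


def run_isolate(
    taxon: str,
    config: PipelineConfig,
    coverage: float = 50.0,
    mt_ratio: float | None = None,
    divergence: float = 0.05,
    markers: tuple[str, ...] = MARKER_ORDER,
    bootstrap_reps: int | None = None,
    with_mt: bool = False,
) -> IsolateResult:
    """Run every pipeline stage on one simulated isolate."""
    reps = bootstrap_reps if bootstrap_reps is not None else config.bootstrap_reps
    if reps < 1:
        raise ValueError("bootstrap_reps must be >= 1")
    ds = synthetic.build_dataset(
        taxon, seed=config.rng_seed, divergence=divergence, coverage=coverage,
        mt_ratio=mt_ratio if with_mt else None, config=config, markers=markers,
    )
    result = IsolateResult(taxon, ds)
    pairs, _stats = trim_and_filter(ds.pairs, QcParams())

    for marker in markers:
        ref = ds.marker_refs[marker].seq
        result.markers[marker] = _recover_marker(marker, ref, pairs, config, ds, reps)

    # perA functionality against the reference CDS model
    per = result.markers.get("perA")
    if per is not None:
        ref = ds.marker_refs["perA"].seq
        cds = ds.marker_cds["perA"]
        for i, seq in enumerate(per.copies.copy_sequences()):
            result.functionality.append(
                gene_function.classify_copy_functionality(
                    seq, ref, cds, marker="perA", copy_id=f"perA.copy{i + 1}")
            )

    if with_mt:
        _run_mt_stage(result, pairs, config)

    _concatenated_tree(result, ds, reps, config.rng_seed)
    return result


def _recover_marker(marker, ref, pairs, config, ds: Dataset, reps) -> MarkerResult:
    from .similarity import LocalSearch

    search = LocalSearch(ref)
    recruited = copy_recovery.recruit_read_pairs(
        pairs, ref, config.recruit_evalue, search=search)
    stack, _unplaced = copy_recovery.pad_to_reference(recruited, ref, search=search)
    variants = copy_recovery.call_variant_columns(stack, len(ref))
    copies = copy_recovery.phase_gene_copies(stack, variants, len(ref), marker=marker)
    res = MarkerResult(marker, copies)

    # per-gene tree of recovered copies + progenitor reference sequences
    labels = [f"{marker}.copy{i + 1}" for i in range(copies.k)]
    seqs = copies.copy_sequences()
    for lab, lin in ds.lineages.items():
        labels.append(lab)
        seqs.append(lin.markers[marker])
    try:
        msa = strip_ambiguous_columns(progressive_align(labels, seqs))
        res.tree = bootstrap_consensus(msa.labels, msa.rows, method="nj",
                                       reps=reps, seed=config.rng_seed)
        dm = p_distance_matrix(msa)
        donors = [lab for lab in ds.lineages]
        for ci, lab in enumerate(labels[: copies.k]):
            drow = dm.matrix[ci]
            nearest = min(donors, key=lambda d: drow[labels.index(d)])
            res.donor_of_copy[lab] = nearest
            res.pair_support[lab] = res.tree.support_of(frozenset({lab, nearest}))
    except ValueError:
        res.tree = None
    return res


def _run_mt_stage(result: IsolateResult, pairs, config: PipelineConfig) -> None:
    ds = result.dataset
    mt_contigs, cutoff, _k = mito.assemble_mt(
        pairs, ds.mt_reference.seq, config.kmer_min, config.kmer_max,
        config.min_contig_len, config.mt_evalue)
    result.mt_cutoff = cutoff
    if not mt_contigs:
        return
    draft = mito.order_and_merge_contigs(mt_contigs, ds.mt_reference.seq)
    annos, missing = mito.annotate_protein_genes(draft.sequence, ds.mt_ref_genes)
    draft.annotations = annos
    draft.missing_genes = missing
    ref_cat = "".join(g.seq for g in ds.mt_ref_genes)
    result.mt_draft = draft
    result.mt_stats = mito.genome_stats(draft.sequence, annos, ref_cat)


def _concatenated_tree(result: IsolateResult, ds: Dataset, reps: int, seed: int) -> None:
    """Supermatrix tree over sub-genomes and progenitor lineages."""
    markers = list(result.markers)
    donors = list(ds.lineages)
    per_sub: dict[str, dict[str, str]] = {}
    for marker, mres in result.markers.items():
        seqs = mres.copies.copy_sequences()
        for ci, seq in enumerate(seqs):
            donor = mres.donor_of_copy.get(f"{marker}.copy{ci + 1}")
            if donor is None:
                continue
            per_sub.setdefault(f"sub_{donor}", {})[marker] = seq
    for donor in donors:
        per_sub[donor] = {m: ds.lineages[donor].markers[m] for m in markers}
    if len(per_sub) < 4:
        return
    ref_lengths = {m: len(ds.marker_refs[m].seq) for m in markers}
    cat, _flags = concatenate_markers(per_sub, ref_lengths,
                                      order=tuple(m for m in MARKER_ORDER if m in markers))
    labels = list(cat)
    try:
        msa = strip_ambiguous_columns(progressive_align(labels, [cat[l] for l in labels]))
        result.concat_tree = bootstrap_consensus(
            msa.labels, msa.rows, method="nj", reps=reps, seed=seed)
    except ValueError:
        result.concat_tree = None


def write_report(result: IsolateResult, outdir: str | Path) -> Path:
    out = Path(outdir)
    (out / "copies").mkdir(parents=True, exist_ok=True)
    (out / "trees").mkdir(exist_ok=True)

    counts = {m: r.copies.k for m, r in result.markers.items()}
    pd.DataFrame([{"taxon": result.taxon, **counts}]).to_csv(
        out / "copy_counts.tsv", sep="\t", index=False)

    for marker, mres in result.markers.items():
        recs = [SeqRecord(f"{marker}.copy{i + 1}", seq or "N")
                for i, seq in enumerate(mres.copies.copy_sequences())]
        (out / "copies" / f"{marker}.fasta").write_text(fasta_text(recs))
        if mres.tree is not None:
            (out / "trees" / f"{marker}.nwk").write_text(mres.tree.newick() + "\n")

    if result.functionality:
        pd.DataFrame([{
            "taxon": result.taxon, "marker": f.marker, "copy": f.copy_id,
            "verdict": f.verdict, "reason": f.reason,
        } for f in result.functionality]).to_csv(
            out / "functionality.tsv", sep="\t", index=False)

    if result.mt_draft is not None:
        (out / "mt_genome.fasta").write_text(
            fasta_text([SeqRecord(f"{result.taxon}_mt", result.mt_draft.sequence)]))
        pd.DataFrame([{
            "gene": a.gene, "start": a.start, "end": a.end,
            "strand": a.strand, "identity": round(a.identity, 4),
        } for a in result.mt_draft.annotations]).to_csv(
            out / "mt_annotations.tsv", sep="\t", index=False)
        st = result.mt_stats
        pd.DataFrame([{
            "taxon": result.taxon,
            "total_length_bp": st.total_length_bp,
            "pct_protein_gene_content": st.pct_protein_gene_content,
            "pct_identity_complement": st.pct_identity_complement,
        }]).to_csv(out / "mt_stats.tsv", sep="\t", index=False)

    if result.concat_tree is not None:
        (out / "trees" / "concatenated.nwk").write_text(
            result.concat_tree.newick() + "\n")
    return out


def run_pipeline(
    config: PipelineConfig,
    taxon: str,
    outdir: str | Path,
    **kwargs,
) -> IsolateResult:
    """Simulate one isolate, run all stages, and write the report directory."""
    result = run_isolate(taxon, config, **kwargs)
    write_report(result, outdir)
    return result
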