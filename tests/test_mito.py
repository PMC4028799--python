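"""de Bruijn assembly, depth classification, ordering, annotation, stats."""

import numpy as np
import pytest

from endophylo import mito, synthetic
from endophylo.config import PipelineConfig
from endophylo.io_formats import SeqRecord, revcomp
from endophylo.mito import (Contig, annotate_protein_genes, assemble_contigs,
                            classify_mt_contigs, concatenate_complement,
                            depth_cutoff, genome_stats, order_and_merge_contigs,
                            verify_gaps)
from endophylo.synthetic import simulate_paired_reads


def circle_reads(genome, coverage, rng, read_len=100):
    reads = []
    n = int(coverage * len(genome) / read_len)
    for _ in range(n):
        start = int(rng.integers(0, len(genome)))
        frag = synthetic._circular_slice(genome, start, read_len)
        reads.append(frag if rng.random() < 0.5 else revcomp(frag))
    return reads


class TestAssembly:
    def test_clean_circle_single_contig(self, rng):
        genome = synthetic.random_dna(rng, 5000)
        reads = circle_reads(genome, 50, rng)
        contigs = assemble_contigs(reads, k=31)
        assert len(contigs) == 1
        c = contigs[0]
        # matches the genome up to rotation and strand
        assert len(c.seq) >= len(genome)
        doubled = genome + genome
        assert c.seq[:5000] in doubled or revcomp(c.seq)[:5000] in doubled

    def test_min_contig_length_floor(self, rng):
        genome = synthetic.random_dna(rng, 150)
        reads = [genome[i : i + 60] for i in range(0, 90, 5)] * 5
        assert assemble_contigs(reads, k=31, min_contig_len=200) == []

    def test_contig_depth_tracks_coverage(self, rng):
        # k-mer coverage identity: depth ~ C (L_read - k + 1) / L_read
        genome = synthetic.random_dna(rng, 4000)
        k, C, L = 31, 60, 100
        depths = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            contigs = assemble_contigs(circle_reads(genome, C, r, L), k=k)
            depths.append(max(c.depth for c in contigs))
        expected = C * (L - k + 1) / L
        sd = np.std(depths, ddof=1)
        assert abs(np.mean(depths) - expected) <= max(3 * sd, 0.05 * expected)

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            assemble_contigs(["ACGT" * 30], k=30)

    def test_no_surviving_kmers_warns_empty(self):
        with pytest.warns(UserWarning):
            out = assemble_contigs(["ACGTACGTACGTACGTACGTACGTACGTACGTA"], k=31,
                                   prune=5)
        assert out == []


class TestClassification:
    def test_valley_between_planted_modes(self, rng):
        # brute-force oracle: the cutoff must separate depth modes 30 / 3000
        depths = list(rng.normal(30, 3, 40)) + list(rng.normal(3000, 300, 40))
        cut = depth_cutoff([max(d, 1) for d in depths])
        assert 40 < cut < 2400

    def test_sparse_depths_largest_gap(self):
        cut = depth_cutoff([3.0, 3.5, 4.0, 900.0, 950.0])
        assert 4.0 < cut < 900.0

    def test_unimodal_returns_none(self, rng):
        assert depth_cutoff(list(rng.normal(50, 5, 100))) is None

    def test_classification_separates_planted_modes(self, rng):
        mt_ref = synthetic.random_dna(rng, 3000)
        contigs = ([Contig(mt_ref[i : i + 600], float(rng.normal(3000, 100)))
                    for i in range(0, 2400, 600)]
                   + [Contig(synthetic.random_dna(rng, 600),
                             float(rng.normal(30, 3))) for _ in range(8)])
        mt, cutoff = classify_mt_contigs(contigs, mt_ref)
        assert 30 < cutoff < 3000
        assert len(mt) == 4
        assert all(c.depth > 1000 for c in mt)

    def test_no_similar_contigs_empty_set(self, rng):
        mt_ref = synthetic.random_dna(rng, 3000)
        contigs = [Contig(synthetic.random_dna(rng, 500), 10.0),
                   Contig(synthetic.random_dna(rng, 500), 1000.0)]
        mt, _ = classify_mt_contigs(contigs, mt_ref)
        assert mt == []

    def test_raising_cutoff_monotone(self, rng):
        depths = [10.0, 20.0, 500.0, 1000.0]
        contigs = [Contig(synthetic.random_dna(rng, 300), d) for d in depths]
        for lo, hi in [(15, 30), (30, 600)]:
            bigger = [c for c in contigs if c.depth >= lo]
            smaller = [c for c in contigs if c.depth >= hi]
            assert set(id(c) for c in smaller) <= set(id(c) for c in bigger)


class TestOrderMerge:
    def test_exact_overlap_merges(self, rng):
        ref = synthetic.random_dna(rng, 6000)
        a, b = Contig(ref[:3000], 100.0), Contig(ref[2950:6000], 100.0)
        draft = order_and_merge_contigs([a, b], ref)
        assert draft.sequence == ref
        assert draft.gaps == []

    def test_shuffled_order_and_strand_follow_reference(self, rng):
        ref = synthetic.random_dna(rng, 6000)
        a = Contig(revcomp(ref[2950:6000]), 90.0)
        b = Contig(ref[:3000], 90.0)
        draft = order_and_merge_contigs([a, b], ref)
        assert draft.sequence == ref

    def test_gap_recorded_between_contigs(self, rng):
        ref = synthetic.random_dna(rng, 6000)
        draft = order_and_merge_contigs(
            [Contig(ref[:3000], 50.0), Contig(ref[3500:6000], 50.0)], ref)
        assert draft.gaps == [(3001, 3500)]
        assert draft.sequence == ref[:3000] + "N" * 500 + ref[3500:]

    def test_rotated_circular_contig_realigned(self, rng):
        ref = synthetic.random_dna(rng, 5000)
        rotated = ref[2000:] + ref[:2000]
        draft = order_and_merge_contigs([Contig(rotated, 200.0)], ref)
        assert draft.sequence == ref


class TestGapVerification:
    def test_true_deletion_confirmed_by_spanning_reads(self, rng):
        ref = synthetic.random_dna(rng, 6000)
        genome = ref[:2000] + ref[2500:]   # 500 bp deletion vs reference
        pairs, _ = simulate_paired_reads(genome, None, 30.0, 1.0, 100,
                                         PipelineConfig(), seed=4)
        draft = order_and_merge_contigs(
            [Contig(genome[:2000], 80.0), Contig(genome[2000:], 80.0)], ref)
        assert (2001, 2500) in draft.gaps
        report = verify_gaps(pairs, draft, ref)
        ev = next(e for e in report if (e.ref_start, e.ref_end) == (2001, 2500))
        assert ev.confirmed

    def test_identical_draft_no_gaps(self, rng):
        ref = synthetic.random_dna(rng, 4000)
        draft = order_and_merge_contigs([Contig(ref, 100.0)], ref)
        assert draft.gaps == []
        assert verify_gaps([], draft, ref) == []

    def test_shared_gaps_grouped_within_taxon(self):
        grouped = mito.group_gaps(
            {"iso1": [(2001, 2500)], "iso2": [(2001, 2500)], "iso3": [(900, 950)]},
            {"iso1": "taxA", "iso2": "taxA", "iso3": "taxB"})
        assert grouped[("taxA", (2001, 2500))] == ["iso1", "iso2"]
        assert grouped[("taxB", (900, 950))] == ["iso3"]


class TestAnnotation:
    def test_exact_gene_found_at_full_identity(self, rng):
        gene = synthetic.random_dna(rng, 600)
        mt = synthetic.random_dna(rng, 2000) + gene + synthetic.random_dna(rng, 2000)
        annos, missing = annotate_protein_genes(mt, [SeqRecord("cox1", gene)])
        assert missing == []
        a = annos[0]
        assert (a.start, a.end, a.strand) == (2001, 2600, "+")
        assert a.identity == 1.0

    def test_diverged_gene_identity_tracks_divergence(self, rng):
        gene = synthetic.random_dna(rng, 900)
        diverged = synthetic.evolve_sequence(gene, 0.10, rng)
        mt = synthetic.random_dna(rng, 1000) + diverged + synthetic.random_dna(rng, 1000)
        annos, _ = annotate_protein_genes(mt, [SeqRecord("cob", gene)])
        assert abs(annos[0].identity * 100 - 90) <= 2

    def test_minus_strand_gene_found(self, rng):
        gene = synthetic.random_dna(rng, 500)
        mt = synthetic.random_dna(rng, 800) + revcomp(gene) + synthetic.random_dna(rng, 800)
        annos, _ = annotate_protein_genes(mt, [SeqRecord("nad6", gene)])
        assert annos[0].strand == "-"

    def test_thirteen_genes_reference_order(self, rng):
        anc = synthetic.make_ancestor(3)
        mt, _ = synthetic.assemble_mt_genome(anc.mt_genes, anc.mt_gene_order,
                                             anc.mt_gene_strands, anc.mt_intergenic)
        refs = [SeqRecord(n, anc.mt_genes[n]) for n in anc.mt_gene_order]
        annos, missing = annotate_protein_genes(mt, refs)
        assert missing == []
        assert [a.gene for a in annos] == anc.mt_gene_order
        assert len(annos) == 13


class TestComplementStats:
    def test_single_gene_concatenation_identity(self, rng):
        gene = synthetic.random_dna(rng, 300)
        mt = "AAA" + gene + "TTT"
        annos, _ = annotate_protein_genes(mt, [SeqRecord("g", gene)])
        assert concatenate_complement(annos, mt) == gene

    def test_concatenation_additive_and_ordered(self, rng):
        g1, g2 = synthetic.random_dna(rng, 300), synthetic.random_dna(rng, 600)
        mt = g1 + "ACGTACGT" * 10 + g2
        annos, _ = annotate_protein_genes(mt, [SeqRecord("a", g1), SeqRecord("b", g2)])
        cat = concatenate_complement(list(reversed(annos)), mt)
        assert len(cat) == 900
        assert cat == g1 + g2  # shuffled input, reference order restored

    def test_empty_annotations_rejected(self):
        with pytest.raises(ValueError, match="no complement"):
            concatenate_complement([], "ACGT")

    def test_content_arithmetic(self, rng):
        g1, g2 = synthetic.random_dna(rng, 300), synthetic.random_dna(rng, 600)
        mt = g1 + synthetic.random_dna(rng, 2100) + g2
        annos, _ = annotate_protein_genes(mt, [SeqRecord("a", g1), SeqRecord("b", g2)])
        stats = genome_stats(mt, annos)
        assert stats.total_length_bp == 3000
        assert stats.pct_protein_gene_content == pytest.approx(30.0, abs=0.01)

    def test_single_gene_genome_full_content(self, rng):
        gene = synthetic.random_dna(rng, 1000)
        annos, _ = annotate_protein_genes(gene, [SeqRecord("g", gene)])
        assert genome_stats(gene, annos).pct_protein_gene_content == 100.0

    def test_content_invariant_to_rotation(self, rng):
        anc = synthetic.make_ancestor(5)
        mt, _ = synthetic.assemble_mt_genome(anc.mt_genes, anc.mt_gene_order,
                                             anc.mt_gene_strands, anc.mt_intergenic)
        refs = [SeqRecord(n, anc.mt_genes[n]) for n in anc.mt_gene_order]
        base = genome_stats(mt, annotate_protein_genes(mt, refs)[0])
        rot = mt[4000:] + mt[:4000]
        rotated = genome_stats(rot, annotate_protein_genes(rot, refs)[0])
        assert abs(base.pct_protein_gene_content
                   - rotated.pct_protein_gene_content) < 0.5
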