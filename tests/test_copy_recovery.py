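"""Recruitment, padding, variant calling and copy phasing."""

import itertools

import numpy as np
import pytest

from endophylo import copy_recovery, synthetic
from endophylo.config import PipelineConfig
from endophylo.copy_recovery import (PaddedRead, call_variant_columns,
                                     pad_to_reference, phase_gene_copies,
                                     recruit_read_pairs)
from endophylo.io_formats import FastqRecord, ReadPair, revcomp
from endophylo.similarity import LocalSearch


def mkpair(pid, s1, s2):
    return ReadPair(FastqRecord(pid, s1, [40] * len(s1)),
                    FastqRecord(pid, s2, [40] * len(s2)))


@pytest.fixture(scope="module")
def reference(ancestor):
    return ancestor.markers["tefA"]


class TestRecruitment:
    def test_exact_substring_recruited_sense(self, reference):
        read = reference[200:300]
        other = "A" * 100
        rec = recruit_read_pairs([mkpair("p", read, other)], reference)
        assert len(rec) == 1
        assert rec[0][0].seq == read

    def test_reverse_complement_recruited_and_flipped(self, reference):
        read = revcomp(reference[400:500])
        rec = recruit_read_pairs([mkpair("p", read, "A" * 100)], reference)
        assert len(rec) == 1
        assert rec[0][0].seq == reference[400:500]

    def test_both_mates_returned_on_single_hit(self, reference):
        rec = recruit_read_pairs([mkpair("p", reference[100:200], "ACGT" * 25)],
                                 reference)
        assert len(rec[0]) == 2

    def test_random_reads_rarely_recruited(self, reference, rng):
        # score-distribution oracle: simulate iid 100-mers, observed
        # false-recruitment rate must stay under 1%
        n = 10_000
        pairs = [mkpair(f"p{i}", synthetic.random_dna(rng, 100),
                        synthetic.random_dna(rng, 100)) for i in range(n)]
        rec = recruit_read_pairs(pairs, reference, 0.1)
        assert len(rec) / n <= 0.01

    def test_monotone_in_threshold(self, reference, rng):
        seqs = [reference[i : i + 100] for i in range(0, 600, 60)]
        pairs = [mkpair(f"p{i}", s, synthetic.random_dna(rng, 100))
                 for i, s in enumerate(seqs)]
        loose = {p[0].pair_id for p in recruit_read_pairs(pairs, reference, 0.1)}
        tight = {p[0].pair_id for p in recruit_read_pairs(pairs, reference, 1e-30)}
        assert tight <= loose

    def test_short_reference_rejected(self):
        with pytest.raises(ValueError):
            recruit_read_pairs([], "ACGT" * 10)


class TestPadding:
    def test_offset_arithmetic(self, reference):
        rec = recruit_read_pairs([mkpair("p", reference[100:200], "A" * 100)],
                                 reference)
        stack, _ = pad_to_reference(rec, reference)
        placed = next(r for r in stack if r.mate == 1)
        assert placed.start == 100
        assert placed.placed == reference[100:200]

    def test_flank_mate_lands_in_unplaced_bin(self, reference, rng):
        rec = recruit_read_pairs(
            [mkpair("p", reference[100:200], synthetic.random_dna(rng, 100))],
            reference)
        stack, unplaced = pad_to_reference(rec, reference)
        assert len(stack) == 1 and len(unplaced) == 1

    def test_deletion_spanning_read_opens_gap(self, reference):
        # copy lacks reference positions 500-529; a read with 100 bp flanks
        # on both sides of the junction must bridge the deletion (gap cost
        # 5 + 30*2 < the 100 matches gained — same optimum as the affine-gap
        # local alignment oracle) and place a 30-base gap run there
        copy = reference[:500] + reference[530:]
        read = copy[400:600]
        rec = recruit_read_pairs([mkpair("p", read, "A" * 100)], reference)
        stack, _ = pad_to_reference(rec, reference)
        placed = next(r for r in stack if r.mate == 1)
        assert placed.start == 400
        span = placed.placed
        # boundary may shift by a base or two where junction flanks repeat
        assert span.count("-") == 30
        gap_at = span.index("-")
        assert abs(gap_at - 100) <= 2
        assert span[gap_at : gap_at + 30] == "-" * 30

    def test_identical_reads_identical_placement(self, reference):
        pairs = [mkpair("a", reference[300:400], "A" * 100),
                 mkpair("b", reference[300:400], "A" * 100)]
        stack, _ = pad_to_reference(recruit_read_pairs(pairs, reference), reference)
        placed = [r for r in stack if r.mate == 1]
        assert placed[0].start == placed[1].start
        assert placed[0].placed == placed[1].placed


class TestVariantColumns:
    def test_uniform_stack_no_variants(self, reference):
        stack = [PaddedRead(f"p{i}", 1, 0, reference[:100]) for i in range(20)]
        assert call_variant_columns(stack, len(reference)) == []

    def test_symmetric_forced_column(self):
        stack = [PaddedRead(f"a{i}", 1, 0, "AAAA") for i in range(20)]
        stack += [PaddedRead(f"g{i}", 1, 0, "AGAA") for i in range(20)]
        cols = call_variant_columns(stack, 4, min_depth=4, min_allele_fraction=0.2)
        assert len(cols) == 1
        assert cols[0].position == 1 and cols[0].alleles == {"A": 20, "G": 20}

    def test_sequencing_errors_below_fraction_floor(self, rng):
        # binomial tail: at depth 100 and 1% error, a spurious allele
        # reaching the 20% floor needs P(X >= 20; n=100, p=0.01) ~ 1e-20
        base = "A" * 50
        stack = []
        for i in range(100):
            seq = list(base)
            errs = rng.random(50) < 0.01
            for j in np.nonzero(errs)[0]:
                seq[j] = "G"
            stack.append(PaddedRead(f"p{i}", 1, 0, "".join(seq)))
        assert call_variant_columns(stack, 50) == []


class TestPhasing:
    def test_uniform_stack_single_copy(self, reference):
        stack = [PaddedRead(f"p{i}", 1, i * 10, reference[i * 10 : i * 10 + 100])
                 for i in range(30)]
        cset = phase_gene_copies(stack, [], len(reference))
        assert cset.k == 1
        cons = cset.consensi[0]
        covered = cons[: 290 + 100]
        assert covered == reference[: len(covered)]

    def test_two_copies_match_bruteforce_bipartition(self, rng):
        # two planted haplotypes differing at 6 columns; every read spans
        # >= 2 variant columns. The recovered partition must equal the
        # exhaustive bipartition maximising within-cluster allele consistency.
        L = 620
        ref = synthetic.random_dna(rng, L)
        cols = [50, 150, 250, 350, 450, 550]
        hapA = ref
        hapB = list(ref)
        for c in cols:
            hapB[c] = {"A": "C", "C": "G", "G": "T", "T": "A"}[hapB[c]]
        hapB = "".join(hapB)
        stack = []
        truth = {}
        n = 0
        for hap, name in ((hapA, "A"), (hapB, "B")):
            for start in range(0, L - 200 + 1, 10):
                pid = f"{name}{n}"
                stack.append(PaddedRead(pid, 1, start, hap[start : start + 200]))
                truth[pid] = name
                n += 1
        variants = call_variant_columns(stack, L)
        assert {v.position for v in variants} == set(cols)
        cset = phase_gene_copies(stack, variants, L)
        assert cset.k == 2

        # brute-force oracle over the 2^6 allele phase assignments
        frags = {r.pair_id: {c: r.placed[c - r.start]
                             for c in cols if r.start <= c < r.start + 200}
                 for r in stack}
        best = None
        allele_pairs = [(hapA[c], hapB[c]) for c in cols]
        for assign in itertools.product([0, 1], repeat=6):
            # assign[i]: which allele of column i belongs to haplotype 1
            h1 = {c: allele_pairs[i][assign[i]] for i, c in enumerate(cols)}
            h2 = {c: allele_pairs[i][1 - assign[i]] for i, c in enumerate(cols)}
            score = 0
            for alleles in frags.values():
                s1 = sum(h1[c] == a for c, a in alleles.items())
                s2 = sum(h2[c] == a for c, a in alleles.items())
                score += max(s1, s2)
            if best is None or score > best[0]:
                best = (score, h1, h2)
        _, h1, h2 = best
        oracle_part = {}
        for pid, alleles in frags.items():
            s1 = sum(h1[c] == a for c, a in alleles.items())
            s2 = sum(h2[c] == a for c, a in alleles.items())
            oracle_part[pid] = 0 if s1 >= s2 else 1
        # compare partitions up to label swap
        ours = {pid: cset.assignments[pid] for pid in frags}
        agree = sum(ours[p] == oracle_part[p] for p in frags)
        assert agree in (0, len(frags)) or agree in (len(frags), )
        # consensus sequences equal the planted haplotypes
        recovered = sorted(c.replace("N", "") for c in cset.consensi)
        assert sorted([hapA, hapB]) == recovered

    def test_k_capped_and_sizes_partition(self, trimmed_pairs, two_copy_dataset):
        ds = two_copy_dataset
        ref = ds.marker_refs["tefA"].seq
        search = LocalSearch(ref)
        rec = recruit_read_pairs(trimmed_pairs, ref, search=search)
        stack, _ = pad_to_reference(rec, ref, search=search)
        variants = call_variant_columns(stack, len(ref))
        cset = phase_gene_copies(stack, variants, len(ref), k_max=3)
        assert 1 <= cset.k <= 3
        n_pairs = len({r.pair_id for r in stack})
        assigned = len(cset.assignments)
        assert assigned + round(cset.unassigned_fraction * n_pairs) == n_pairs

    def test_synthetic_two_copy_recovery(self, trimmed_pairs, two_copy_dataset):
        ds = two_copy_dataset
        ref = ds.marker_refs["tefA"].seq
        search = LocalSearch(ref)
        rec = recruit_read_pairs(trimmed_pairs, ref, search=search)
        stack, _ = pad_to_reference(rec, ref, search=search)
        variants = call_variant_columns(stack, len(ref))
        cset = phase_gene_copies(stack, variants, len(ref))
        assert cset.k == 2
        from endophylo.similarity import align_identity
        for seq in cset.copy_sequences():
            best = max(align_identity(seq, c.seq)
                       for c in ds.hybrid.truth.copies["tefA"])
            assert best >= 0.995
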