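# Methods

`endophylo` implements a phylogenomic workflow for asexual, heteroploid
grass endophytes (*Epichloë*/*Neotyphodium*-type fungi): hybrids whose
nuclei carry 2–3 progenitor-derived sub-genomes, hence 2–3 homeologous
copies of each nuclear marker gene, alongside a single high-copy
mitochondrial genome inherited from one progenitor. The pipeline recovers
the individual gene copies and the mt genome from whole-genome paired-end
reads and reconstructs their evolutionary relationships. All components are
exercised against a bundled simulator that provides complete ground truth.

## The synthetic heteroploid model

The simulator is the package's definition of the study conditions, not a
test convenience.

**Progenitor lineages.** A random ancestor supplies three marker genes —
*tub2* (1,500 bp), *tefA* (1,000 bp) and *perA* (5,500 bp) — a 15 kb
circular mt genome carrying 13 protein-coding genes in a fixed order (one,
*nad6*, on the minus strand), and 24 kb of background sequence. Each
lineage evolves from the ancestor by iid Jukes–Cantor-style substitutions
at rate *p* (expected substitutions/site; default 0.05, configurable —
real progenitor divergences are not published, and 2–10% keeps phasing
both feasible and non-trivial) plus optional short indels
(geometric lengths, mean 3) in non-coding sequence. Marker and mt genes
evolve under a stop-avoiding substitution process: a draw that would
create an in-frame stop codon is redrawn, and exons accept no indels. This
models purifying selection and guarantees that a gene copy is
non-functional only when a lesion is planted deliberately — necessary for
the functionality-pattern experiments to have known truth.

**Hybrids.** A hybrid genome embeds one copy of each marker per donor
sub-genome (minus planted losses), each flanked by 2 kb of that donor's
background, on a random strand, in shuffled block order. Planted lesions
are (a) explicit deletions given as 1-based inclusive intervals — the
shared *perA* copy-1 pattern uses 1251–1878 and 4590–4918 — and (b)
premature-stop point lesions at a chosen codon. Six named taxon patterns
fix the published copy-number/lesion structure: a 3-donor hybrid
(3,3,3), four 2-donor hybrids (2,2,2) with varying lesion patterns, and a
2-donor hybrid with a *tub2* loss (2,1,2).

**Reads.** Fragments are uniform over the genome with lengths
~Normal(400, 80) truncated to [100, 900] bp; mates are the two fragment
ends, FR-oriented, 100 bp. The mt genome is circular (fragments may span
the origin) and sampled at *r* × nuclear coverage (*r* ≥ 1, reflecting
organellar copy numbers of tens to thousands per cell). Base errors are
substitutions drawn per-base from the quality model: constant Q40 with a
linear drop over the last 10 cycles; a flat error rate can override it.
Indel sequencing errors and PCR duplicates are not modelled, so passing
tests say nothing about indel-error robustness on real data; the real
workflow's quality trimming compensates there.

**Scaled sizes.** Real genomes in this system are ~30–60 Mb nuclear and
52–96 kb mitochondrial; the simulator uses a tens-of-kb nuclear genome and
a 15 kb mt genome with proportionally shortened genes (13 genes, ~44% of
the genome vs 15–28% in the real genomes) so that every stage — including
de Bruijn assembly across a k-mer sweep — runs end to end in seconds to
minutes. Copy phasing, depth classification and tree inference operate on
per-gene and per-genome scales, so the reduction changes runtimes, not the
structure of the problems.

## Read QC

Sliding-window 3′ trimming (window 4, mean Q20, minimum length 50): a read
is cut at the first window whose mean quality falls below threshold,
keeping any leading above-threshold bases of that window; by default a
pair is dropped if either mate fails, because recruitment assumes intact
pairs. The published workflow used an unpublished script; these thresholds
are this package's own choice and are exposed in `QcParams`.

## Copy recovery

1. **Recruitment.** A seeded local search (exact 13-mer words, both
   strands; Hamming fast path on the best diagonal, affine-gap local
   alignment via Biopython's `PairwiseAligner` when the fast path rejects;
   match +1 / mismatch −2 / gap −5,−2) scores each mate against the
   reference gene; scores convert to E-values with fixed Karlin–Altschul
   nucleotide parameters (λ=1.28, K=0.46). A pair is recruited when either
   mate has E ≤ 0.1; both mates are kept and antisense hits are
   reverse-complemented, a hit-less mate inheriting the opposite
   orientation of its mate (FR geometry).
2. **Padding.** Each read is placed at its best hit's reference start;
   the placed string covers the hit's reference span with `-` at reference
   positions the read lacks (deletions); read insertions are dropped.
   Placements spanning < 30 reference positions are routed to the
   unplaced bin: at E ≤ 0.1 a bare 13–14 bp word match from elsewhere in
   the genome is a legitimate hit, and at high depth one such shared word
   yields dozens of coherent reference-allele stubs that would otherwise
   nucleate a phantom copy. Equal-score placements resolve to the smallest
   start coordinate.
3. **Variant columns.** A reference column is variant when ≥ 2 alleles
   (`-` included, pads excluded) each reach depth ≥ 4 and fraction ≥ 0.2.
   At depth ~100 and ~1% sequencing error the probability of a spurious
   allele reaching the 20% floor is astronomically small, which is what
   makes the fraction floor safe.
4. **Phasing.** Read pairs (fragments) carrying alleles at variant columns
   are greedily agglomerated: a fragment joins the cluster maximising
   matches−mismatches of cluster-majority alleles over shared columns,
   subject to ≥ 80% agreement; otherwise it seeds a new cluster. Clusters
   whose shared columns agree ≥ 80% are then merged. **Phase-block
   stitching:** a variant desert longer than the largest fragment — e.g.
   the interval of a copy-specific deletion, where only one copy
   contributes sequence — breaks linkage and splits a copy into left/right
   blocks. Because recruited copies span the whole reference, substantial
   clusters with *zero* shared variant columns are blocks of one copy and
   are merged, smallest size-difference first; a competing alternative
   pairing sets the `unphased` flag. Clusters below 10% of phased
   fragments dissolve into the unassigned pool; the surviving cluster
   count (capped at 3) is the copy number, and each cluster's per-column
   majority is its consensus, with deletions preserved as gap runs and
   uncovered columns as N. Fragments spanning no variant column are
   unassigned by construction and only affect consensus depth.

Recovered consensi are routinely 100% identical to planted copies at 50×
per copy and 5% divergence; copies carrying the large deletions come out
at ~99%, the deficit concentrated in thin junction-edge coverage where
deletion-spanning reads clip.

## Mitochondrial assembly

A minimal de Bruijn assembler (plain dict k-mer graph, both strands,
maximal non-branching paths, reverse-complement and rotation dedup,
closed cycles trimmed of the duplicated k−1 suffix) replaces the original
workflow's assembler. Low-frequency k-mers are pruned at max(2, depth
mode/20) — a documented rule standing in for the original "auto" cutoff.
All odd k in [39, 51] are tried; the accepted assembly prefers total
length within 20% of the reference mt length, then maximal N50.

Classification uses the high organellar copy number: contigs with a hit to
the reference mt genome at E ≤ 0.001 whose depth clears the valley of the
smoothed log₁₀-depth histogram (largest-gap rule below 30 contigs; a
shallow or narrow valley falls back to similarity-only classification with
a warning) are mitochondrial. A second assembly with the identified
cut-off as the pruning floor then eliminates nuclear and recurrent-error
k-mers — this two-pass scheme is what turns a fragmented high-depth
assembly into a single clean contig, and it is also the only defence
against nuclear copies of mt sequence (numts): no sequence-signature
filter is applied. Whether the cut-off is expressed in k-mer-depth or
read-depth units was left open by the source workflow; this package
defines contig depth as mean k-mer multiplicity (k-mer coverage
≈ read coverage × (L−k+1)/L).

Ordering/merging places each contig by its best hit on a *doubled*
reference, so a contig rotated across the circular origin is split at the
origin instead of dangling; exact overlaps ≥ 20 bp merge, tiny overlaps
butt-join, unfilled reference intervals are recorded as gaps and N-padded
to preserve the reference frame, and placement conflicts keep the deeper
contig and log the event. Gap confirmation re-aligns reads across each
junction (window built from the flanking contigs, ≤ 5 gap openings,
≥ 3 concordant spanning reads) and groups identical gap coordinates within
a taxon. Protein genes are annotated by best local alignment of each
reference gene (either strand, identity ≥ 70%) and concatenated in
reference order; genome stats report total length, % protein-gene content
and % identity of the concatenated complement to the reference complement.

## Gene structure and functionality

Copies are globally aligned to the reference (affine gaps, free end gaps);
identity is measured over the shorter sequence so end-gap clipping cannot
fake homology, and < 50% raises a not-homologous error. Deletions are
maximal unmatched reference runs ≥ 10 bp, reported 1-based inclusive with
length end−start+1. Junction homology can shift a boundary by a base or
two; downstream tolerances allow ±2 bp. (The two shared *perA* intervals
have inclusive lengths 628 and 329 bp; adjacent literature rounds these to
627/328 under an exclusive convention — this package reports inclusive
arithmetic.)

Functionality projects the reference exons through the alignment:
unaligned exon edges count as truncation; internal insertions minus
deletions not divisible by 3 → `frameshift`; otherwise the spliced copy
CDS is translated (standard code; the mold mitochondrial code would apply
to mt sequence, which this pipeline never translates) — an internal stop →
`premature stop`; protein < 95% of reference length → `truncated`; else
`functional/intact`. A single 329 bp or 628 bp deletion is a frameshift;
both together restore net frame (957 ≡ 0 mod 3) but the out-of-frame
segment between them guarantees internal stops, so the verdict is still
non-functional.

## Phylogenetics

- **Progressive alignment:** NJ guide tree on 8-mer set dissimilarity;
  profiles merged bottom-up by affine-gap global DP over column frequency
  vectors (match +1, mismatch −2, gaps −5/−2, end gaps extension-only,
  N and gap columns scoring 0), with the horizontal gap state computed as
  a max-plus prefix scan so each DP row is one vectorised numpy pass.
- **Column elimination:** every column containing `-` or `N` in any row is
  removed before distances or parsimony (complete-deletion rule); this is
  also how N-padded missing markers in the concatenated supermatrix drop
  out.
- **Distances:** uncorrected p-distances (the original analysis used its
  program's defaults, which are unpublished; p-distance is the documented
  choice here, and exact branch lengths are therefore not comparable).
- **NJ:** Studier–Keppler Q-criterion agglomeration; negative branch
  lengths clamp to zero; Q ties resolve to the smallest pair index. On
  additive distances the generating topology and path lengths are
  recovered exactly (within 1e-9), and the topology matches scikit-bio's
  independent implementation in tests.
- **Fitch parsimony:** two-pass algorithm, bitmask state sets vectorised
  across columns; search is exhaustive over all unrooted topologies for
  ≤ 8 taxa (10,395 at n=8) and NNI hill-climbing from the NJ tree with 5
  seeded restarts above that.
- **Bootstrap:** columns resampled with replacement; NJ replicates reuse a
  precomputed pair×column mismatch matrix so each replicate is a matrix
  product; supports are the percentage of replicates containing each
  internal-edge bipartition; the returned tree is the >50% majority-rule
  consensus (all such splits are mutually compatible), with branch lengths
  copied from the full-data tree where edges coincide. Default 1,000
  replicates; figure conventions label supports > 70%.
- **Concatenation:** per sub-genome, copies join in the order
  *tub2*–*tefA*–*perA*; a missing marker is N-padded to reference length
  and flagged. Copies are assigned to donor sub-genomes by nearest
  p-distance donor in the per-gene alignment, with the copy–donor cherry's
  bootstrap support reported alongside.

## Numerical and degenerate-input choices

Deterministic behaviour is a contract: every stochastic step takes a seed
derived from `PipelineConfig.rng_seed` via `SeedSequence`, and equal seeds
give byte-identical reports. Degenerate inputs fail loudly (empty FASTA,
unpaired FASTQ files, n < 3 for NJ, reps < 1, empty annotation lists) or
degrade with a warning and an explicit marker (unimodal depth histograms,
unsupported gaps labelled unconfirmed, contradictory phasing flagged
`unphased` rather than failing).

## Problem sizes used in the shipped experiments

Copy-number runs use all three markers at 50× per copy (≈15k read pairs
for the 3-donor hybrid); the fidelity sweep uses twenty 2-donor isolates
with the 1 kb marker; the mt experiment uses nuclear coverage 5× with
mt:nuclear ratio 100 (mt ≈ 500×, ≈38k pairs); bootstrap placement uses
1,000 NJ replicates. These sizes are the package's chosen demonstration
scale; the operations themselves take arbitrary inputs.

## Known limitations

- Phasing requires variant linkage: copies identical over a region longer
  than the largest fragment cannot be separated there (stitching assumes
  full-length copies; genuinely partial copies could be mis-stitched and
  are only flagged, not resolved).
- Copy-number estimation caps at k_max = 3 (the biological range here).
- The recruiter is a reimplementation contract, not bit-compatible with
  any BLAST release; only recruit/reject behaviour at E ≤ 0.1 is promised.
- Mt assembly assumes a dominant depth separation (ratio ≥ ~20); at low
  ratios the histogram valley disappears and classification degrades to
  similarity-only.
- ML tree inference and split networks are out of scope; NJ and parsimony
  are the implemented engines.
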