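# Methods

## Problem and model

A diploid subject's amplicon pool from a single polymorphic locus is a
mixture of noisy copies of two allele sequences, possibly at very
unequal proportions (unbalanced PCR amplification), contaminated by
reads from paralogous loci and pseudogenes. Genotyping is cast as:
(i) clean and orient the reads, (ii) partition them into two allelic
groups, (iii) name each group by its nearest known allele, and
(iv) stabilise the call against sampling noise by bootstrap
aggregating. The approach assumes the locus is short enough that each
read spans the whole informative exon (no assembly), that allele-
defining differences are substitutions at well-sequenced positions, and
that a curated allele library exists for the final naming step.

## Preprocessing

Reads are demultiplexed by exact match of the leading MID barcode
(no mismatch tolerance: error-correcting barcode designs keep distinct
barcodes ≥3 changes apart, so exact matching is conservative and the
corruption rate is measurable as the unassigned count). The exon is
located by exact search for a start and an end boundary motif, first in
the read and then in its reverse complement; the trimmed product must
fall in [250, 290] bp, the plausible size range for class II exon 2
amplicons. Reads containing any blacklist motif — substrings diagnostic
of pseudogene or paralog amplicons — are then removed. Motifs are
configuration inputs (flat key=value file): the real motif sets used on
production data are locus- and primer-specific, so the package ships
only the synthetic locus's own motifs. Coordinates are 0-based
half-open; first motif occurrence wins; stage counts are logged and are
monotonically non-increasing by construction.

## Quality-weighted similarity

Pairs are globally aligned under match +1 / mismatch −1 / gap −2
(Biopython's PairwiseAligner; for same-locus, near-identical ~270 bp
amplicons global alignment is exact, making heuristic seed-and-extend
machinery unnecessary). The similarity score is

    S(a,b) = L_aln − Σ_k w_k − G,

with w_k = `low_quality_weight` (default 0.5) when the mismatch column's
lower Phred quality is below `quality_threshold` (default Q30), else 1;
gap columns subtract 1 each — indels are frequent pyrosequencing
artifacts and ignoring them would inflate similarity. The binary
threshold form is the simplest scheme consistent with "trust confident
disagreements, discount doubtful ones"; the weight and threshold are
parameters, not constants, because the best values depend on the
instrument's quality calibration.

Co-optimal alignments can differ in their mismatch/gap composition, so
the pair is aligned in a canonical order (lexicographically smaller
sequence first) and positions mirrored back; this makes S exactly
symmetric and bitwise deterministic. Dissimilarity is
D_ij = 1 − S_ij / min(S_ii, S_jj), clipped to [0,1]: dividing by the
shorter read's self-similarity makes D scale-free so one kernel
bandwidth serves across read-length variation.

## Diffusion embedding and clustering

The kernel is W_ij = exp(−D_ij²/ε), row-normalised to a Markov matrix
P. Eigenpairs are computed on the symmetric conjugate
A = Δ^{1/2} P Δ^{−1/2} (Δ = diag of kernel row sums), which shares
eigenvalues with P and guarantees real eigenpairs; right eigenvectors
of P are recovered as ψ = Δ^{−1/2}v, the trivial λ=1 constant
eigenvector is dropped, and coordinates are λ_k^t ψ_k(i). Defaults:

- ε: median of squared nonzero dissimilarities (self-tuning; puts the
  typical pair at kernel weight e^{−1} ≈ 0.37 so neither saturates to 1
  nor underflows). Robust over at least two decades around the default
  on two-group read sets (property-tested).
- t = 1, m = 4: a two-allele pool concentrates its structure in the
  first nontrivial coordinate; extra coordinates are kept as slack for
  outlier reads but more are not informative at n ≈ 20.
- Eigenvector sign fixed by making the largest-magnitude entry
  positive, for reproducibility.

K is fixed at 2 — one cluster per haplotype of a diploid locus;
homozygotes are resolved downstream when both cluster consensuses match
the same allele, which avoids any model-selection step. K-means runs in
the diffusion coordinates with k-means++ initialisation and 30 seeded
restarts, keeping the best within-cluster sum of squares. Thirty
restarts rather than a more customary ten: on instances this small
(a bagging subsample is ~20 points) ten random initialisations
measurably miss the global 2-partition optimum on a few percent of
instances even though that optimum is Lloyd-stable; thirty drive the
miss rate to zero at negligible cost (0/500 on random n ≤ 8 instances).
Coincident coordinates (e.g. identical reads) can leave a sklearn
cluster empty; a deterministic repopulation step moves one point so
both clusters are always non-empty, and downstream both then yield the
same consensus.

## Consensus and allele matching

Each cluster's medoid (maximal summed similarity to cluster mates)
anchors a star alignment: O(n) pairwise alignments instead of a full
multiple alignment, adequate because same-cluster reads are
near-identical. Columns are keyed by medoid position, with inserted
columns keyed between positions; reads lacking an inserted column
contribute a gap there. Per column the plurality symbol wins; ties go
to the larger summed Phred quality, then alphabetically. A gap
plurality deletes the column — homopolymer over-calls are the dominant
454 artifact, and deletion restores the modal length. The consensus is
matched against every library allele by global-alignment percent
identity (100 × match columns / alignment columns, unrounded until
report writing); equally-near alleles are reported alphabetically first
with all tied names kept in an ambiguity annotation rather than
guessed between. A consensus matching no allele at 100% is reported
with its sub-100 identity; novel-allele discovery is out of scope.

## Bagging and the genotype decision

Each of B iterations draws N = 20 reads uniformly *without* replacement
(each iteration sees a subset of the reads; subjects with fewer than N
reads use all reads every iteration and are flagged low-coverage),
clusters, calls both consensuses, and merges the two calls when they
name the same allele (summed cluster size; size-weighted mean
identity — the merge rule keeps homozygote support comparable to a
heterozygote's two clusters). Aggregation per distinct allele: call
rate = 100 × detections/B, mean cluster size and mean identity over
detecting iterations. The final genotype takes the top aggregate, and
the second if its call rate ≥ `min_call_rate` (default 10%): the
threshold sits below the minor-allele detectability that a bagged run
achieves at realistic imbalance while staying above the rate at which
spurious alleles (consensus errors on unlucky subsamples) recur. Note
B = 5 quantises call rates to multiples of 20%, so at the default
threshold a single detection suffices at B = 5 while B = 60 demands six
— small-B results are inherently coarser.

Per-iteration randomness is seeded by hashing (master seed, subject id,
iteration index), so results are independent of subject processing
order, a run with B iterations is exactly extended by a run with more,
and the whole pipeline is a pure function of (reads, library, config).
Per-subject alignment memos (pair scores keyed by read indices;
library-match results keyed by consensus sequence) make repeated
subsampling affordable without affecting results.

## Synthetic data generator

The simulator emulates the read structure the pipeline consumes:
barcode + amplicon in either orientation, from a fixed synthetic 270 bp
locus with 12 bp boundary motifs, eight alleles at pairwise Hamming
distances 4–18 substitutions (shaped like class II exon 2 diversity
without shipping database content), and two pseudogene-like templates
carrying blacklist motifs. Conditions modelled: per-subject depth drawn
from a truncated normal (mean 340, sd 132, floor 40 — matching reported
per-subject coverage for this assay class), allele imbalance via
`minor_fraction`, substitution error (default 1% per base) with
error bases drawn from the low-quality Phred component (mean Q15)
and correct bases mostly high quality (mean Q35, 8% low), optional
homopolymer indels adjacent to runs ≥ 3, contaminant reads, and
single-base barcode corruption. Truth tables record realised counts so
preprocessing can be scored exactly.

Not modelled: flowgram-level 454 noise, PCR chimeras, quality-by-cycle
trends, and cross-subject index hopping. Consequently, passing tests
demonstrate the statistical machinery (clustering separability,
dropout rescue by bagging, consensus majority-voting) under controlled
error, not performance on a real instrument's full artifact spectrum —
on real data the absolute sensitivity thresholds would be worse, and
the clean-cohort saturation seen in the sensitivity experiments (100%
detection across the tested minor-fraction grid) reflects the
simulator's benign error model.

## Problem sizes in tests and the acceptance script

Experiments are sized for a single CPU: genotype recovery uses 30
subjects at simulated-truth depth (tests) and 12 (acceptance script),
B = 20; the sensitivity sweep uses 60 reads/subject over minor
fractions {5, 10, 15, 20}% with 30 seeds per fraction (tests) and 10
seeds at the 10% fraction (script); consensus accuracy uses 1,000
(tests) or 200 (script) clusters of 20 reads. B = 5 aggregates are read
off the first five iterations of the B = 60 run, which the seeding
scheme makes exactly equivalent to an independent B = 5 run.

## Known limitations

- Exact barcode and motif matching: no fuzzy recovery of singly
  mutated barcodes or motifs; such reads are counted, not rescued.
- The O(n²) similarity matrix and O(n) star alignments dominate cost;
  the N = 20 subsample keeps each iteration at 190 pairwise alignments,
  but very large B on many subjects is compute-bound in alignment.
- Two-cluster structure is assumed; a sample contaminated by a third
  allele-like sequence (e.g. cross-subject bleed-through surviving the
  blacklist) is forced into two groups, surfacing only as depressed
  identity scores or spurious low-call-rate aggregates.
- G-group and other library naming conventions are passed through
  verbatim; no collapsing of alleles identical over the sequenced exon
  is attempted, so ties are reported as ambiguity annotations.
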