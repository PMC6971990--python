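# Methods

## Coordinate model

All internal coordinates are 0-based, half-open, genomic; exons are stored
sorted by genomic start regardless of strand, and conversion to the 1-based
inclusive GTF convention happens only at the I/O boundary. A donor site is
the boundary coordinate at an exon's 3' end in transcription direction, an
acceptor the next exon's 5' boundary; on the minus strand these are the
genomic interval's end and start respectively. This makes junction
identity, motif offsets and the splice-chain grammar strand-symmetric by
construction, which the test suite verifies by reflecting whole loci.

## Event detection and the splice-chain code

Events are derived pairwise between isoforms and deduplicated, rather than
built from a multi-transcript splice graph: all eleven named structures are
two-variant codes, and structural deduplication reproduces gene-level
counts (the pre-deduplication incidence count is also exposed). The
algorithm: compute both isoforms' internal splice-site chains; shared sites
are exact (position, kind) matches; restrict to the genomic overlap of the
two isoforms; each maximal run of non-shared sites flanked on both sides by
a shared site — or by an overlap boundary where both isoforms are exonic —
is one event. Sites in the run are numbered 1..n in transcription order
across both chains, each chain concatenates its own numbers with `^`
(donor) or `-` (acceptor), an empty chain renders as `0`, and the two
chains are joined by ascending first site number with `0` last. The code
string is looked up in the eleven-entry table; anything else is `complex`.

Two deliberate consequences: terminal variation (alternative transcription
start/end, or a run whose anchor would fall where one isoform has already
ended) is not an event, since no code in the table describes it; and a
non-shared site lying exactly on the overlap boundary is treated as
terminal rather than event variation. Codes are written with ASCII `-`
throughout (typeset dashes in published tables are normalized away).

An independent check lives in the tests: a brute-force enumerator derives
splice sites from per-base exon-membership arrays and re-implements the
numbering and rendering from scratch; implementation and oracle agree on
code, type and anchors over 1,000 random isoform pairs.

## Junction classification

A junction is a deduplicated intron keyed by (contig, strand, donor,
acceptor); identical coordinates on opposite strands are distinct because
donor/acceptor identity is strand-defined. Novelty is assessed against the
reference at the site level: `annotated` if the exact pair occurs in the
reference, `partial_novel` if exactly one of the two sites does,
`complete_novel` otherwise. Gene-region classification uses the reference
isoform with the longest CDS as the frame of reference (a deterministic
rule for multi-isoform genes); each junction extremity is placed in
5'UTR/CDS/3'UTR by its position relative to the CDS genomic span, oriented
by strand, and mixed extremities yield the boundary classes 5UTR-CDS and
CDS-3UTR. Dinucleotide pairs are read from the genome in transcription
orientation and reported in the DNA alphabet (GT-AG is the RNA GU-AG);
introns shorter than 4 nt are excluded and counted.

## Branch point and polypyrimidine tract

Published branch-site searches in this setting are typically unpublished
in-script heuristics, so the scan here is a declared, reproducible
concretization with every constant exposed in `BranchParams`: candidate
branch adenosines are scanned where the offset to the 3' splice site lies
in [15, 150] nt (clipped to the intron, never within the first 10 intronic
nt); each 5-mer is scored against the C-T-R-A-Y consensus with the A at
position 4 mandatory and +1 for each other consensus match (R = A/G,
Y = C/T); the maximum wins with ties broken toward the 3'ss. The PPT is the
maximal-scoring interval between the branch A and the 3'ss under +1
pyrimidine / −2 purine, reported when at least 9 nt long. Reported offsets
count nucleotides from the branch A (exclusive) to the last intron base
(inclusive).

## ORF projection and PTC calls

ORFs are projected from the annotated start rather than re-predicted: the
reference start codon's genomic position is mapped through the isoform's
exon chain (absent when that position is not exonic there, in which case
the isoform is excluded from PTC counts), and translation uses the standard
genetic code (no selenocysteine) to the first in-frame stop. `is_ptc`
requires the stop's genomic position to differ from the reference stop's
and the protein to be shorter than the reference protein. The 50-nt
last-junction rule is reported as an advisory NMD flag only, never used for
filtering.

## Differential expression and DAGs

The DE statistic follows the two-library MA-plot normal approximation:
replicate TPMs are averaged per condition, gene totals rescaled to integer
pseudo-counts of a nominal 10^6 library, and under the null that a gene's
proportion is equal in both libraries, M = log2 k_A − log2 k_B is tested
against expectation log2(n_A/n_B) with the binomial variance propagated to
log2 space by the delta method; p-values are two-sided normal and BH
corrected. A gene is DE when q < 0.01 *and* its condition-mean fold change
(with a pseudo-value of 0.1 on both means to avoid division by zero)
exceeds 2 in either direction. Pooling replicates makes the binomial
statistic anti-conservative under biological overdispersion — with a 10^6
pseudo-library, tiny proportion shifts reach small q-values — so the fold-
change condition carries most of the specificity, and a replicate-aware
Welch-t alternative (`method="welch"`) is exposed for designs with more
replicates. The DE decision rule's operating characteristics (FDR ≤ 0.05,
power ≥ 0.8 at the simulated noise, ≤ 2 % null calls) are asserted on the
planted simulation. DAG status is DE ∧ (gene in the union of the two
contrast conditions' AS-gene sets). Enrichment is a one-sided
hypergeometric test per term with BH correction; thresholds such as
fdr < 0.05 are presentation defaults, not output filters.

## Metabolite association

Differential metabolites: Welch t on log2(x+1) replicate abundances,
flagged at p < 0.05 and condition-mean fold change > 2; a zero-variance
metabolite with equal means gets p = 1 by convention. Associations use
Pearson r over condition means (the time-course framing; replicate-level
correlation is available behind a flag), p from the t distribution with
n−2 df, and |r| > 0.7 as the strong-association threshold. With only 3–5
condition points this threshold is statistically weak — the null
distribution of r at n = 5 has ≈ 19 % of its mass beyond |0.7| — which the
analysis scripts surface rather than hide; the threshold is kept because it
is the field's stated criterion.

## Synthetic data: what is emulated, and what is not

Each simulated gene is built in transcription space around its planted
event and then mirrored onto the genome for minus-strand genes. Intron
interiors are A-free outside the planted motifs (donor/acceptor
dinucleotides, a CTAAC branch 5-mer, a G-gap, a T/C polypyrimidine tract),
so the branch scan has a unique maximal hit and motif recovery is exact by
construction; planted stops and coding sequence are written as stop-free
codons with a repair pass that never touches motif bases. Specifics worth
knowing:

- **Branch offsets** are drawn from a normal (mean 55 nt, sd 30 nt)
  truncated *symmetrically* to ±39 nt so the truncated mean is still
  exactly 55; one-sided clipping to the searchable window would bias the
  planted mean upward by ~6 nt and make mean-recovery claims ambiguous.
- **Dinucleotide classes** are i.i.d. per intron at the configured mix
  (96.5 / 1.7 / 0.5 / 1.3 % by default). Junctions derived by exon
  skipping combine one intron's donor with another's acceptor and can
  therefore land in the `other` class; the ground truth records each
  junction's realized pair, and the contamination is well within the
  binomial tolerance used in the tests.
- **Intron retention isoforms** retain frame-neutral introns (lengths are
  multiples of 3); with probability `ptc_fraction` an in-frame TAA is
  planted early in the retained intron (upstream of the branch motif so it
  cannot perturb motif recovery), otherwise the construction guarantees no
  in-frame stop, giving exact PTC sensitivity/specificity targets. Other
  event types shift frames naturally and may produce PTCs; those are not
  constrained.
- **Expression** is log-normal per transcript with multiplicative
  replicate noise (log2 sd 0.25) and planted ±2 log2-fold changes on a
  `de_fraction` of genes in all non-baseline conditions; columns are
  normalized to sum to 10^6, which perturbs realized fold changes by the
  (small) ratio of column scale factors.
- **Metabolite tables** plant the condition-mean sample correlation
  *exactly*: a linked metabolite's mean profile is ρ·x̃ + √(1−ρ²)·ẽ⊥
  against the standardized measured profile of its probe transcript, and
  an unlinked metabolite's profile is residualized to r = 0 against its
  probe, before small replicate noise (log2 sd 0.05, 6 replicates) is
  added. With ≤ 5 condition points, stochastic "ρ plus noise" planting
  cannot be recovered reliably through a 0.7 threshold, so exact planting
  is what makes the association tests sharp.

What the generator does **not** emulate: read-level sequencing (coverage,
errors, assembly artifacts), quantification uncertainty that correlates
across isoforms of a gene, overlapping genes and shared exons between
loci, genuinely degraded or intronless annotations, U12-type spliceosome
biology beyond the AT-AC label, and LC-MS peak-calling noise structure.
Passing tests therefore demonstrate correctness of the analysis logic on
well-formed inputs, not robustness to assembler noise.

## Problem sizes and numerics

The simulation studies use 200 genes for DE operating characteristics, 500
genes (~2,000 junctions) for dinucleotide-mix recovery, ~260 genes (~1,000
controlled introns) for branch-offset recovery, and 500 IR genes for PTC
checks; these sizes give the statistical assertions comfortable margins
while keeping each script and the whole test suite fast on one CPU. The
enrichment null-calibration uses a 20,000-gene universe with study size
4,000 so that the discrete hypergeometric p-value mixture is smooth enough
for a meaningful KS comparison against the uniform. Ties in the branch
scan go to the site nearest the 3'ss; BH correction and hypergeometric
tails come from statsmodels/scipy and are cross-checked against hand-rolled
implementations in the tests. All pipeline outputs are written with fixed
float formatting and sorted keys, making reruns byte-identical.
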