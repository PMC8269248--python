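# Methods

## Overview

`termscape` implements a genome-wide analysis of transcript 3'-end positions
(TEPs) for bacterial term-seq data, aimed at GC-rich actinobacterial genomes
where intrinsic terminators carry unusually stable hairpins. The pipeline has
four stages: (1) call TEPs from replicate per-strand 3'-end count tracks;
(2) classify each end from the fold of its upstream RNA; (3) assemble
transcription units (TUs) and TU clusters (TUCs) by integrating transcription
start sites (TSSs) and RNA-seq coverage; (4) compute downstream statistics
(read-through fractions, nucleotide enrichment, bidirectional ends, COG
enrichment, 3'-UTR lengths, small-protein screening, Poisson protein
distances). A synthetic-data module generates all inputs with a known truth
table so every stage is testable without external data.

All coordinates are 0-based half-open. Strand-aware windows are computed in
transcript orientation: on the minus strand "downstream" means decreasing
genomic coordinates, and windows are mapped back to genomic coordinates after
the arithmetic. GFF3 input is converted from 1-based closed coordinates on
read; BedGraph is treated as 0-based half-open with track lines ignored and
float values accepted.

## TEP calling

Term-seq 3'-end counts are used raw for calling (the count thresholds below
are defined on raw counts); only RNA-seq coverage is normalized. Per strand:

1. **Clustering.** Nonzero positions closer than `cluster_gap` (100 bp) join
   a single-linkage cluster.
2. **Sub-clustering.** Within a cluster, a greedy left-to-right pass extends
   the current sub-cluster while the *population* standard deviation of its
   member positions stays below `subcluster_sd` (25). The maximum-count
   position of each sub-cluster is its representative; count ties break
   toward the 5'-most position in transcript orientation (the tie rule and
   the greedy direction are implementation choices; the grouping criterion
   itself does not define them).
3. **Filters.** Representatives need a raw count of at least
   `min_peak_count` (4) in the calling replicate and any nonzero count
   within +/-2 nt in every other replicate (term-seq ends jitter by a
   nucleotide or two, so exact-position presence would be too strict).
4. **Z-score.** z = (x - mu) / max(sigma, 1) where mu and sigma are the mean
   and population standard deviation of counts at offsets -50..-1 and
   +1..+50. The sigma floor of 1 keeps z finite on sparse flanks. The
   intent is a measure of how far the peak rises above its own shadows.
5. **Classifier.** A K-nearest-neighbor classifier (k = 5, Euclidean
   distance on log1p-transformed counts) over the 21-value count profile at
   offsets -10..+10. Training positives are candidates with z > 6 whose
   RNA-seq read-through fraction is below 0.5 — an automated, deterministic
   stand-in for manual screening of "decreased RNA profile" sites; training
   negatives are the 20 offset positions of each positive (offsets that
   coincide with another positive are dropped). Reported accuracy is the
   mean over repeated random 50/50 train/test splits (default 1,000
   repetitions; the accuracy is a mean and is stable well before that, so
   tests and the acceptance run use 200). The final call set is the union
   over replicates of positively labeled candidates, merging calls within
   +/-2 nt (highest count wins).

Categories are assigned with the precedence Internal > P/S > Pre > A > N:
inside a same-strand CDS (Internal, excluded from class statistics); within
500 bp downstream of a same-strand gene's stop (highest count per gene is
primary P, others secondary S; a TEP between two genes associates with the
nearest stop); between 70 bp downstream of a primary TSS and that gene's
start codon (premature, Pre); inside an opposite-strand CDS (antisense, A);
otherwise intergenic (N). The precedence order is not intrinsic to the
definitions; it follows the order in which the categories are introduced.

## Structure classification

The 40-nt window upstream of the end (offsets -40..-1; the end base itself is
excluded — the window definition is ambiguous about offset 0 and excluding it
keeps the window disjoint from the downstream tract) is folded at 30 degC
with the ViennaRNA minimum-free-energy engine at default parameters (engine
and version are recorded in output metadata; whether dangling-end terms are
included is whatever the engine's default is). Ends with dG strictly below
`hs_threshold` (-23 kcal/mol) are highly structured (HS); a value exactly on
the threshold is LS, since "structured" is defined as *below* the split.

From the MFE dot-bracket structure the 3'-most hairpin is parsed: the
hairpin-closing pair nearest the 3' end, grown outward while consecutive
pairs are separated by interior bulges of at most 1 nt per side. Stem length
counts base pairs; loop length is the enclosed unpaired run; the stem end is
the helix's 3'-most paired base, as an offset from the end base. When
several hairpins exist, the 3'-most one is taken because termination
mechanics act at the transcript end. Uridines are counted over the 8 nt
downstream of the stem end; HS ends with >= 3 U are HS-U-rich (the intrinsic
terminator hairpin + U-tract signature), other HS ends HS-U-lack, and
everything else LS. When no pair exists at all, the U count falls back to
the 8 nt ending at the end base so the classification stays total.

`bimodal_split` is a diagnostic: a two-component Gaussian mixture fitted to a
dG sample, returning the intersection of the weighted component densities
between the means. It refuses (keeping the fixed threshold) when the means
are closer than 1 kcal/mol or when the mixture density at the intersection is
more than 70% of the smaller mode density — without the valley check a
unimodal sample is silently split into two overlapping halves.

Nucleotide enrichment at offsets -50..+50 is the per-offset base frequency
among ends divided by the position-averaged base frequency over 10,000
random genomic windows (uniform over positions and strands, seeded). The
interaction matrix folds each end's 100-nt upstream window and reports, for
every offset pair, the fraction of ends whose MFE structure pairs them.

## Coverage statistics

RNA-seq tracks are RPM-normalized (each position scaled by 1e6/total). The
read-through fraction at an end is the downstream-flank sum divided by the
upstream-flank sum, averaged over growth phases. Flanks are equal-length
(300 nt): upstream covers offsets -299..0 and downstream +1..+300, so the
end base belongs to the upstream sum only, a flat track gives exactly 1.0
and a clean step from depth a to b gives exactly b/a. Records whose upstream
sum is zero are flagged and excluded from distribution summaries, not
imputed. Distribution summaries discard the largest 5% of values before
reporting medians and quartiles.

Density profiles scale each end's -300..+300 coverage window to a maximum of
1, sum across ends, normalize each phase profile to sum to 1, and average
phases. RPKM is count-sum / (kb x millions of library reads). The premature
ratio reports per-phase RPKM(downstream CDS)/RPKM(premature TU), its minimum
over phases, and the population standard deviation of the log2 ratios.

## TU and TUC assembly

Every same-strand TSS x TEP combination with the end downstream of the start
is a candidate, bounded at a 20-kb span (an added tractability bound: the
all-combinations rule is quadratic in signal-dense genomes and spans beyond
20 kb are logged, not silently lost). The evaluation region runs from
TSS + 100 to TEP - 100 in transcript orientation; pairs closer than 200 bp
use the full span. Windows of 200 bp slide 1 bp at a time across the whole
region (not only the stretch nearest the end — the window rule's stopping
point is ambiguous and scanning everything is the stricter reading). A phase
passes when every window's RPM-normalized mean exceeds 5% of the region's
normalized mean *and* every window's raw mean is at least 5; the raw floor
applies to the candidate in that phase (a raw-coverage gap breaks
connectivity), with a config switch (`lenient_window_filter`) that instead
skips low-raw windows from the 5% test. A pair is a TU when at least one
phase passes.

TU categories count same-strand CDSs *fully contained* in the span
(containment is the stricter reading of "genes in the TU"): one gene is
monocistronic, two or more polycistronic; gene-free TUs are premature when
they end at a premature TEP and intergenic otherwise. TUCs are connected
components of the >= 1-bp interval-overlap graph (half-open intervals, so
abutting TUs do not merge). Members whose TEP equals the cluster's 3'-most
TEP are terminal, the rest nonterminal; ties share the terminal label, and
labels propagate to the TEPs.

## Downstream analyses

*Bidirectional ends.* For a plus-strand end at f and minus-strand end at r
on one contig the overlap is f - r + 1 nt (the two ends' final bases
inclusive); convergent pairs with 1 <= overlap < 60 are reported. Each end
joins at most one pair; candidates are matched greedily by smallest overlap
so dense regions are not double-counted. Both the pair count and the member
count (2x) are reported, since "how many bidirectional ends" is ambiguous
between the two units.

*COG enrichment.* The modal-category count divided by the count of genes
with any assigned category; unassigned genes are ignored entirely, and the
score is undefined when nothing is assigned. The worked example {L, L, C,
unassigned} gives 2/3.

*3'-UTR lengths.* For each gene with a primary end: distance from the first
base after the stop codon through the end base inclusive, binned at 10 nt.
Secondary ends are excluded.

*Small proteins.* A noncoding TU is a candidate when its mean RPF RPKM
exceeds the median over the supplied CDS set, its log2 RPF/RNA RPKM ratio
exceeds the CDS median, and an ORF (ATG/GTG/TTG start — GTG and TTG are
common starts in high-GC actinobacteria — with an in-frame stop) lies fully
within the TU on its strand. With no CDS set the configured defaults (18.75
and 0.74) apply.

*Poisson distance.* p is the mismatch fraction over aligned sites where
neither sequence has a gap (pairwise deletion); d = -ln(1 - p), infinite at
p = 1, zero iff p = 0.

## Synthetic data

The generator emulates the study conditions, not any particular genome: one
contig at 72% GC; genes of 134-300 codons alternating strands at random with
>= 700-nt spacers; ATG starts, proper stop codons, and a primary TSS 20-150
nt upstream of each start; a random COG letter per gene. Each gene's 3'
flank receives one planted end 48-120 nt past the stop, drawn from a class
mix of 0.40/0.35/0.25 (HS-U-rich / HS-U-lack / LS). The mix is a
simulation-scale choice: at 20 genes it reliably yields the >= 10 automated
training positives the caller requires, which a real genome provides in
abundance. HS cassettes are a 10-14 bp pure-GC inverted repeat around a
4-8 nt A-rich loop followed by an 8-nt tail (>= 5 T for U-rich, <= 2 T for
U-lack); each cassette is verified with the same fold/stem/U-count
definitions the classifier uses and resampled until the realized window
matches its intended class, so truth labels are self-consistent by
construction. LS windows are shuffled until unstructured, falling back to an
unpairable C/A sequence of matched GC content.

Term-seq tracks draw a Poisson main peak (mean 50) at each true position,
eight shadow counts at rounded-Normal(0, 3) offsets truncated to +/-10 nt
with per-shadow mean 5 (shadows flank both sides; the caller only assumes
the true peak has maximum intensity), and uniform Poisson background at 0.02
counts/nt. RNA-seq coverage is depth 100 over each planted TU, stepped down
by the class ratio (0.05 / 0.4 / 0.9) for 300 nt past its end, 1% of depth
elsewhere, with per-position Poisson noise across four phases that differ
only by noise. RPF coverage is a 3x boost of RNA coverage over CDSs and
designated small-ORF TUs. All generators are bit-reproducible given (seed,
parameters); sub-seeds are spawned with NumPy `SeedSequence`.

What the simulation does **not** model: read-level artifacts (sequencing
error, mapping bias, rRNA contamination), processed 3' ends that are not
termination sites, premature/antisense/intergenic truth ends, overlapping
TU isoforms, condition-dependent termination, or realistic base composition
inside LS windows (the C/A fallback is unpairable but compositionally
artificial). Passing tests therefore demonstrate that the rules are
implemented correctly and recover a clean planted signal — not that the
thresholds are optimal for any real data set.

## Problem sizes and numerical choices

The default test/acceptance simulation uses 20 genes (~31 kb, ~40 planted
features over both strands), two term-seq replicates and four RNA-seq
phases; the data-driven threshold diagnostic uses an 80-gene simulation.
These sizes give stable statistics in seconds while exercising every code
path; all sizes are parameters.

Tie-breaks and degenerate inputs are fixed as follows: sub-cluster count
ties go 5'-most; dG exactly at the threshold is LS; an all-zero term-seq
track yields an empty (not erroneous) call set; RPM normalization of an
all-zero track is an error; read-through with zero upstream signal is
undefined and flagged; `cv_reps = 0` disables cross-validation and reports
accuracy as undefined; pairs whose evaluation region is empty after the
100-bp offsets fall back to the short-pair rule.

## Known limitations

- The Z-score flank width (50 nt) and the KNN hyperparameters are
  conventional defaults, all configurable; nothing in the method pins them.
- The automated positive-training screen (z > 6, read-through < 0.5)
  replaces manual curation; on data where termination does not depress
  coverage (heavy processing, stable 3' ends) it will under-collect
  positives.
- `bimodal_split` assumes two roughly Gaussian components; skewed or
  three-way mixtures defeat the valley check.
- The small-protein screen uses single-track RPF/RNA ratios; it does not
  model codon-level periodicity or start-site signal.
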