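# termscape

Genome-wide mapping of bacterial transcript 3' ends and transcription-unit
architecture from term-seq data.

Term-seq ligates an adapter to RNA 3' termini, so read starts mark transcript
3'-end positions (**TEPs**) at single-nucleotide resolution. In GC-rich
actinobacteria (the *Streptomyces*-like genomes this package targets),
termination signals differ markedly from the *E. coli* textbook picture, and
the 3' end of a transcript is a regulatory element in its own right:
intrinsic terminators, Rho-dependent ends and RNase processing sites all
leave distinct sequence and coverage signatures. `termscape` is for
computational biologists who have per-strand 3'-end count tracks (replicate
BedGraphs), a TSS table and RNA-seq coverage, and want the complete 3'-end
analysis: called and categorized TEPs, structure classes, transcription units
(TUs) and TU clusters (TUCs), and the derived statistics.

## The method

**Calling.** Nonzero term-seq positions are clustered (< 100 bp),
sub-clustered (positional SD < 25), and represented by their maximum-count
peak, which resolves the positional "shadows" around true ends. Candidates
need >= 4 raw counts, presence in every replicate, and are labeled by a
K-nearest-neighbor classifier over the count profile at offsets -10..+10,
trained on automatically screened positives (flank Z-score > 6, RNA coverage
dropping at the site). Calls are categorized as primary (P), secondary (S),
premature (Pre), antisense (A), intergenic (N) or Internal relative to the
annotation.

**Classification.** The 40-nt upstream window is folded at 30 degC
(ViennaRNA MFE). Ends with ΔG < -23 kcal/mol are highly structured (HS) and
split by the uridine count *u* in the 8-nt tract downstream of the stem:

- **HS-U-rich** (ΔG < -23, u >= 3) — hairpin + U-tract, the intrinsic
  terminator signature;
- **HS-U-lack** (ΔG < -23, u < 3) — stable hairpin without a U-tract;
- **LS** (ΔG >= -23) — little structure, Rho-dependent or processing ends.

**Assembly.** Every TSS x TEP pair on a strand is accepted as a TU when, in
at least one growth phase, every 200-bp window slid 1 bp across the region
keeps an RPM-normalized mean above 5% of the region mean and a raw mean
>= 5. Overlapping TUs (>= 1 bp) form TUCs; members ending at the cluster's
3'-most end are terminal.

**Statistics.** Read-through fraction (downstream/upstream 300-nt flank
sums, averaged over phases), per-offset nucleotide enrichment against random
genomic background, bidirectional TEP pairs (convergent overlap < 60 bp),
COG functional enrichment (modal category over assigned genes), 3'-UTR
lengths from primary ends, a small-protein screen over noncoding TUs
(RPF level, RPF/RNA ratio, ORF presence), and Poisson-corrected protein
distances d = -ln(1 - p).

A first-class synthetic-data module (`termscape.simulate`) generates a
GC-rich genome with planted terminators of all three classes, replicate
term-seq tracks with peak shadows and noise, phase-wise RNA-seq with
class-specific step-downs, and RPF coverage — with a truth table, so the
whole pipeline is exercised and scored without downloads.

## Worked example

```sh
python examples/simulate_and_call.py
```

prints

```
genome: 31,257 nt, 20 genes, 20 planted 3' ends
called 20 TEPs (KNN cross-validation accuracy 0.992)
precision 1.00  recall 1.00 (match tolerance +/-2 nt)
categories: {'P': 20}
```

— the caller recovered every planted end, no false positives, and since each
planted end sits just downstream of a gene, every call is a primary TEP.
`examples/classify_ends.py` shows the per-end detail:

```
 position strand      dG stem loop  U  class        planted
     1167      +   -29.7   11    7  7  HS-U-rich    HS-U-rich
     5398      +   -21.4    5    8  1  LS           LS
     6419      -   -26.7   10    7  0  HS-U-lack    HS-U-lack
```

ΔG is the folding free energy of the 40-nt upstream window (kcal/mol), stem
and loop the parsed hairpin geometry, U the uridine count in the downstream
tract; the planted column confirms the recovered class. And
`examples/downstream_stats.py` reproduces the class-dependent termination
efficiency:

```
median read-through by class (fraction of coverage surviving the end):
  HS-U-lack  0.400 (n=3)
  HS-U-rich  0.050 (n=10)
  LS         0.898 (n=7)
```

hairpin + U-tract ends terminate hardest (5% read-through), unstructured
ends barely terminate at all.

There is also a thin CLI: `termscape simulate`, `termscape run`,
`termscape call-teps`, `termscape classify`, `termscape assemble-tus`,
`termscape report` (see `termscape --help`).

## Layout

```
src/termscape/      io, config, simulate, calling, classify, coverage,
                    tu, analysis, pipeline, evaluation, cli
examples/           one narrative script per capability
tests/              pytest suite (unit, property and acceptance tests)
scripts/            acceptance.py
docs/methods.md     model, assumptions, parameter rationale, limitations
```
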