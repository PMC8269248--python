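"""Derived analyses: bidirectional 3' ends, COG enrichment, 3'-UTR lengths,
small-protein screening, Poisson protein distances, and summary reporting."""

from __future__ import annotations

import math
from collections import Counter
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .config import PipelineConfig
from .coverage import feature_rpkm, trimmed_distribution_summary
from .model import (
    BiTepPair,
    GeneModel,
    Genome,
    PoissonDistance,
    Tep,
    Track,
    Tu,
    Tuc,
    revcomp,
)

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TGA", "TAG", "TAA")


def detect_biteps(teps: Sequence[Tep],
                  config: PipelineConfig) -> List[BiTepPair]:
    """Convergent opposite-strand 3'-end pairs with short overlaps.

    For a plus-strand end at f and a minus-strand end at r on the same
    contig the overlap is f - r + 1 nt; a pair is reported when
    1 <= overlap < ``bitep_max_overlap``. Each end joins at most one pair —
    the nearest partner (smallest overlap) wins.
    """
    plus = [t for t in teps if t.strand == "+"]
    minus = [t for t in teps if t.strand == "-"]
    candidates: List[Tuple[int, Tep, Tep]] = []
    for f in plus:
        for r in minus:
            if f.contig != r.contig:
                continue
            overlap = f.position - r.position + 1
            if 1 <= overlap < config.bitep_max_overlap:
                candidates.append((overlap, f, r))
    candidates.sort(key=lambda c: (c[0], c[1].position, c[2].position))
    used = set()
    pairs: List[BiTepPair] = []
    for overlap, f, r in candidates:
        if id(f) in used or id(r) in used:
            continue
        used.update((id(f), id(r)))
        pairs.append(BiTepPair(f, r, overlap))
    return pairs


def cog_enrichment(categories: Sequence[Optional[str]]) -> Optional[float]:
    """Modal-category fraction among genes with an assigned category.

    Genes without a category are ignored; with no assigned gene at all the
    score is undefined (None). The same statistic applies to smBGC
    functional categories.
    """
    assigned = [c for c in categories if c]
    if not assigned:
        return None
    counts = Counter(assigned)
    return counts.most_common(1)[0][1] / len(assigned)


def utr3_lengths(genes: Sequence[GeneModel], teps: Sequence[Tep],
                 bin_width: int = 10) -> Tuple[Dict[str, int], Dict[int, int]]:
    """3'-UTR length per gene with a primary (P) TEP, plus a histogram.

    Length runs from the first base after the stop codon through the TEP base
    inclusive, in transcript orientation; only primary TEPs count. Histogram
    keys are bin starts (0, 10, 20, ...).
    """
    genes_by_id = {g.gene_id: g for g in genes}
    lengths: Dict[str, int] = {}
    for tep in teps:
        if tep.category != "P" or tep.gene_id not in genes_by_id:
            continue
        gene = genes_by_id[tep.gene_id]
        if gene.strand == "+":
            length = tep.position - gene.cds_end + 1
        else:
            length = gene.cds_start - tep.position
        if length >= 1:
            lengths[gene.gene_id] = length
    hist: Dict[int, int] = {}
    for length in lengths.values():
        b = (length // bin_width) * bin_width
        hist[b] = hist.get(b, 0) + 1
    return lengths, hist


def _has_orf(genome: Genome, contig: str, strand: str, start: int,
             end: int) -> bool:
    """Start codon with an in-frame stop, fully inside [start, end)."""
    seq = genome.subseq(contig, start, end, strand)
    for i in range(len(seq) - 5):
        if seq[i: i + 3] not in START_CODONS:
            continue
        for j in range(i + 3, len(seq) - 2, 3):
            if seq[j: j + 3] in STOP_CODONS:
                return True
    return False


def screen_small_proteins(
    intergenic_tus: Sequence[Tu],
    rna_track: Track,
    rpf_track: Track,
    cds_set: Sequence[GeneModel],
    genome: Genome,
    config: PipelineConfig,
) -> List[Tu]:
    """Noncoding TUs that look translated.

    A candidate needs (i) mean RPF RPKM above the median over the supplied
    CDS set, (ii) log2 RPF/RNA RPKM ratio above the CDS median, and (iii) a
    potential ORF (ATG/GTG/TTG start, in-frame stop) fully within the TU on
    its strand. With an empty CDS set the configured default medians are
    used.
    """
    rna_total = rna_track.total()
    rpf_total = rpf_track.total()

    def metrics(contig, strand, start, end):
        rpf = feature_rpkm(rpf_track, contig, strand, start, end, rpf_total)
        rna = feature_rpkm(rna_track, contig, strand, start, end, rna_total)
        ratio = math.log2(rpf / rna) if rpf > 0 and rna > 0 else None
        return rpf, ratio

    cds_rpf, cds_ratio = [], []
    for g in cds_set:
        rpf, ratio = metrics(g.contig, g.strand, g.cds_start, g.cds_end)
        cds_rpf.append(rpf)
        if ratio is not None:
            cds_ratio.append(ratio)
    rpf_cut = (float(np.median(cds_rpf)) if cds_rpf
               else config.rpf_median_default)
    ratio_cut = (float(np.median(cds_ratio)) if cds_ratio
                 else config.rpf_rna_log_ratio_default)

    out: List[Tu] = []
    for tu in intergenic_tus:
        rpf, ratio = metrics(tu.contig, tu.strand, tu.start, tu.end)
        if rpf <= rpf_cut or ratio is None or ratio <= ratio_cut:
            continue
        if not _has_orf(genome, tu.contig, tu.strand, tu.start, tu.end):
            continue
        out.append(tu)
    return out


def poisson_distance(aligned_a: str, aligned_b: str) -> PoissonDistance:
    """Poisson-corrected protein distance d = -ln(1 - p).

    p is the fraction of differing residues over sites where neither sequence
    has a gap (pairwise deletion). Identical sequences give d = 0; p = 1
    gives an infinite distance.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    compared = 0
    mismatches = 0
    for a, b in zip(aligned_a.upper(), aligned_b.upper()):
        if a in "-." or b in "-.":
            continue
        compared += 1
        if a != b:
            mismatches += 1
    if compared == 0:
        raise ValueError("no comparable sites (all-gap columns)")
    p = mismatches / compared
    d = math.inf if p >= 1 else -math.log(1 - p)
    return PoissonDistance(p, d)


def partition_counts(labels: Sequence[str]) -> Dict[str, object]:
    """Category counts plus their total — a partition consistency helper."""
    counts = Counter(labels)
    return {"counts": dict(counts), "total": sum(counts.values())}


def report(teps: Sequence[Tep], tus: Sequence[Tu], tucs: Sequence[Tuc],
           bitep_pairs: Sequence[BiTepPair] = ()) -> Dict[str, object]:
    """Summary tables: category/class counts, TUC sizes, read-through
    distributions per class with rank-sum comparisons."""
    tep_part = partition_counts([t.category or "NA" for t in teps])
    non_internal = [t for t in teps if t.category != "Internal"]
    class_part = partition_counts([t.tep_class or "NA" for t in non_internal])
    tu_part = partition_counts([tu.category or "NA" for tu in tus])
    sizes = [len(tuc.members) for tuc in tucs]
    singleton = sum(1 for s in sizes if s == 1)

    rt_by_class: Dict[str, List[float]] = {}
    for t in non_internal:
        if t.tep_class and t.readthrough is not None:
            rt_by_class.setdefault(t.tep_class, []).append(t.readthrough)
    rt_summary = {cls: trimmed_distribution_summary(vals)
                  for cls, vals in rt_by_class.items() if vals}
    pvals = {}
    names = sorted(rt_by_class)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if len(rt_by_class[a]) and len(rt_by_class[b]):
                stat = stats.mannwhitneyu(rt_by_class[a], rt_by_class[b],
                                          alternative="two-sided")
                pvals[f"{a}_vs_{b}"] = float(stat.pvalue)

    return {
        "tep_total": tep_part["total"],
        "tep_by_category": tep_part["counts"],
        "tep_non_internal": len(non_internal),
        "tep_by_class": class_part["counts"],
        "tu_total": tu_part["total"],
        "tu_by_category": tu_part["counts"],
        "tuc_total": len(tucs),
        "tuc_singleton": singleton,
        "tuc_multi": len(tucs) - singleton,
        "tuc_singleton_fraction": (singleton / len(tucs)) if tucs else None,
        "tuc_sizes": sorted(Counter(sizes).items()),
        "bitep_pairs": len(bitep_pairs),
        "bitep_members": 2 * len(bitep_pairs),
        "readthrough_by_class": rt_summary,
        "readthrough_ranksum_p": pvals,
    }
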