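"""Synthetic genome, annotation and sequencing-track generator with ground truth.

Emulates the data a term-seq / RNA-seq study of a GC-rich actinobacterium
produces: a single high-GC contig with non-overlapping genes on both strands,
a primary transcription start site per gene, a planted 3'-end position (TEP)
in each gene's 3' flank drawn from three classes (hairpin + U-tract,
hairpin without U-tract, unstructured), replicate term-seq tracks with
Poisson main peaks, positional "shadow" counts and uniform background noise,
and RNA-seq coverage with class-specific step-downs at each planted TEP
across four growth phases. Every generator is bit-reproducible given
(seed, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .classify import classify_tep, fold_mfe, parse_stem_loop
from .model import GeneModel, Genome, Tep, Track, Tss, revcomp

COG_LETTERS = "JKLMNOCEGHIPQTU"
STOP_CODONS = ("TGA", "TAG", "TAA")
DEFAULT_CLASS_MIX = (0.4, 0.35, 0.25)  # HS-U-rich, HS-U-lack, LS
DEFAULT_READTHROUGH = {"HS-U-rich": 0.05, "HS-U-lack": 0.4, "LS": 0.9}
DEFAULT_PHASES = ("early", "transition", "late", "stationary")


class SizingError(ValueError):
    pass


class PlacementError(ValueError):
    pass


@dataclass
class PlantedTep:
    contig: str
    position: int
    strand: str
    tep_class: str
    category: str
    gene_id: str


@dataclass
class PlantedTu:
    contig: str
    tss: int
    tep: int
    strand: str
    gene_ids: List[str]


@dataclass
class TruthTable:
    teps: List[PlantedTep] = field(default_factory=list)
    tus: List[PlantedTu] = field(default_factory=list)
    params: Dict[str, object] = field(default_factory=dict)

    def validate(self, genome: Genome) -> None:
        for t in self.teps:
            if not 0 <= t.position < len(genome.contigs[t.contig]):
                raise PlacementError(f"planted TEP at {t.position} outside genome")
        for tu in self.tus:
            ahead = tu.tep > tu.tss if tu.strand == "+" else tu.tep < tu.tss
            if not ahead:
                raise PlacementError("planted TU has TEP upstream of its TSS")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


def _random_codon(rng: np.random.Generator, gc: float) -> str:
    while True:
        codon = _random_bases(rng, 3, gc)
        if codon not in STOP_CODONS:
            return codon


def generate_genome(
    n_genes: int = 20,
    gc: float = 0.72,
    seed: int = 0,
    contig: str = "chr",
    cds_codons: Tuple[int, int] = (134, 300),
    spacer_range: Tuple[int, int] = (700, 1200),
    tss_offset_range: Tuple[int, int] = (20, 150),
    contig_length: Optional[int] = None,
) -> Tuple[Genome, List[GeneModel], List[Tss]]:
    """Build a toy GC-rich genome with genes, start codons and primary TSSs.

    Genes alternate strands at random, every CDS starts with ATG and ends with
    a stop codon, intergenic spacers are at least 700 nt, and each gene gets a
    primary TSS 20-150 nt upstream of its start codon plus a random COG
    letter. A requested ``contig_length`` too small for the genes raises
    :class:`SizingError`.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    pieces: List[str] = []
    genes: List[GeneModel] = []
    tss_set: List[Tss] = []
    cursor = 0

    lead = int(rng.integers(*spacer_range))
    pieces.append(_random_bases(rng, lead, gc))
    cursor += lead
    for i in range(n_genes):
        n_codons = int(rng.integers(cds_codons[0], cds_codons[1] + 1))
        body = "".join(_random_codon(rng, gc) for _ in range(n_codons - 2))
        cds = "ATG" + body + str(rng.choice(STOP_CODONS))
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"gene{i:04d}"
        start, end = cursor, cursor + len(cds)
        pieces.append(cds if strand == "+" else revcomp(cds))
        genes.append(GeneModel(gene_id, contig, strand, start, end,
                               cog=str(rng.choice(list(COG_LETTERS)))))
        offset = int(rng.integers(*tss_offset_range))
        tss_pos = start - offset if strand == "+" else end - 1 + offset
        tss_set.append(Tss(contig, tss_pos, strand, "primary", gene_id))
        cursor = end
        spacer = int(rng.integers(*spacer_range))
        pieces.append(_random_bases(rng, spacer, gc))
        cursor += spacer

    seq = "".join(pieces)
    if contig_length is not None:
        if len(seq) > contig_length:
            raise SizingError(
                f"{n_genes} genes need {len(seq)} nt but contig_length is "
                f"{contig_length}"
            )
        seq += _random_bases(rng, contig_length - len(seq), gc)
    return Genome({contig: seq}), genes, tss_set


def _hairpin_cassette(rng: np.random.Generator, u_rich: bool) -> str:
    """Coding-strand DNA: GC stem, short loop, inverted repeat, 8-nt tail."""
    loop_len = int(rng.integers(4, 9))
    stem_max = (32 - loop_len) // 2
    stem_len = int(rng.integers(10, stem_max + 1))
    stem = "".join(rng.choice(["G", "C"], size=stem_len))
    loop = "".join(rng.choice(list("AAAG"), size=loop_len))
    if u_rich:
        n_t = int(rng.integers(5, 9))
        tail = "T" * n_t + "".join(rng.choice(["G", "C"], size=8 - n_t))
    else:
        tail = list("".join(rng.choice(["G", "C"], size=8)))
        for k in rng.choice(8, size=int(rng.integers(0, 3)), replace=False):
            tail[k] = "T"
        tail = "".join(tail)
    return stem + loop + revcomp(stem) + tail


def _write_coding(seq: List[str], strand: str, end_pos: int, cassette: str) -> None:
    """Place a coding-strand cassette so its last base sits at ``end_pos``."""
    if strand == "+":
        start = end_pos - len(cassette) + 1
        seq[start: end_pos + 1] = list(cassette)
    else:
        seq[end_pos: end_pos + len(cassette)] = list(revcomp(cassette))


def _upstream_window(seq: List[str], strand: str, pos: int, window: int) -> str:
    if strand == "+":
        return "".join(seq[pos - window: pos])
    return revcomp("".join(seq[pos + 1: pos + 1 + window]))


def _count_u(seq: List[str], strand: str, tep_pos: int, end_off: int,
             window: int = 8) -> int:
    """Transcript-strand T count over offsets end_off+1..end_off+window."""
    count = 0
    for off in range(end_off + 1, end_off + 1 + window):
        pos = tep_pos + off if strand == "+" else tep_pos - off
        if not 0 <= pos < len(seq):
            continue
        base = seq[pos] if strand == "+" else revcomp(seq[pos])
        if base == "T":
            count += 1
    return count


def plant_terminators(
    genome: Genome,
    genes: Sequence[GeneModel],
    tss_set: Sequence[Tss],
    class_mix: Tuple[float, float, float] = DEFAULT_CLASS_MIX,
    seed: int = 0,
    hs_threshold: float = -23.0,
    fold_window: int = 40,
    fold_temperature: float = 30.0,
    tep_distance: Tuple[int, int] = (48, 120),
    max_tries: int = 60,
) -> Tuple[Genome, TruthTable]:
    """Write one 3'-end cassette per gene into its 3' flank.

    HS cassettes are verified against the folding engine (window free energy
    below ``hs_threshold``) and resampled on failure; LS positions are made
    unstructured by shuffling the upstream window, falling back to an
    unpairable C/A sequence of matched GC content. Flanks too short for a
    cassette raise :class:`PlacementError`.
    """
    if abs(sum(class_mix) - 1) > 1e-9:
        raise ValueError("class_mix proportions must sum to 1")
    rng = np.random.default_rng(seed)
    tss_by_gene = {t.gene_id: t for t in tss_set}
    seqs = {c: list(s) for c, s in genome.contigs.items()}
    truth = TruthTable(params={
        "seed": seed, "class_mix": tuple(class_mix),
        "hs_threshold": hs_threshold, "fold_window": fold_window,
    })
    classes = ("HS-U-rich", "HS-U-lack", "LS")

    for gene in genes:
        seq = seqs[gene.contig]
        d = int(rng.integers(tep_distance[0], tep_distance[1] + 1))
        if gene.strand == "+":
            tep_pos = gene.cds_end - 1 + d
            if tep_pos + 1 > len(seq):
                raise PlacementError(f"flank of {gene.gene_id} too short")
        else:
            tep_pos = gene.cds_start - d
            if tep_pos - fold_window < 0:
                raise PlacementError(f"flank of {gene.gene_id} too short")
        tep_class = classes[int(rng.choice(3, p=class_mix))]

        if tep_class in ("HS-U-rich", "HS-U-lack"):
            for attempt in range(max_tries):
                cassette = _hairpin_cassette(rng, tep_class == "HS-U-rich")
                _write_coding(seq, gene.strand, tep_pos, cassette)
                if tep_class == "HS-U-lack" and attempt >= max_tries // 2:
                    # the realized fold kept drifting U-rich: pin the bases
                    # just past the 3' end to G/C so the tract stays U-poor
                    guard = "".join(rng.choice(["G", "C"], size=8))
                    if gene.strand == "+":
                        seq[tep_pos + 1: tep_pos + 9] = list(guard)
                    else:
                        seq[tep_pos - 8: tep_pos] = list(revcomp(guard))
                window = _upstream_window(seq, gene.strand, tep_pos, fold_window)
                dg, structure = fold_mfe(window, fold_temperature)
                if dg >= hs_threshold:
                    continue
                # verify the realized window classifies as intended
                stem = parse_stem_loop(structure)
                end_off = stem.stem_end_offset if stem is not None else -8
                u_count = _count_u(seq, gene.strand, tep_pos, end_off)
                if classify_tep(dg, u_count, hs_threshold) == tep_class:
                    break
            else:
                raise PlacementError(
                    f"could not build a structured cassette for {gene.gene_id}")
        else:
            window = _upstream_window(seq, gene.strand, tep_pos, fold_window)
            placed = False
            for attempt in range(40):
                shuffled = "".join(rng.permutation(list(window)))
                dg, _ = fold_mfe(shuffled, fold_temperature)
                if dg > hs_threshold:
                    window = shuffled
                    placed = True
                    break
            if not placed:
                # unpairable fallback: C/A alphabet at the window's GC content
                n_c = sum(b in "GC" for b in window)
                letters = ["C"] * n_c + ["A"] * (fold_window - n_c)
                window = "".join(rng.permutation(letters))
            if gene.strand == "+":
                seq[tep_pos - fold_window: tep_pos] = list(window)
            else:
                seq[tep_pos + 1: tep_pos + 1 + fold_window] = list(revcomp(window))

        truth.teps.append(PlantedTep(gene.contig, tep_pos, gene.strand,
                                     tep_class, "P", gene.gene_id))
        tss = tss_by_gene.get(gene.gene_id)
        if tss is not None:
            truth.tus.append(PlantedTu(gene.contig, tss.position, tep_pos,
                                       gene.strand, [gene.gene_id]))

    new_genome = Genome({c: "".join(s) for c, s in seqs.items()})
    truth.validate(new_genome)
    return new_genome, truth


def simulate_termseq(
    truth: TruthTable,
    lengths: Dict[str, int],
    replicates: int = 2,
    peak_height: float = 50.0,
    shadow_sd: float = 3.0,
    n_shadows: int = 8,
    noise_rate: float = 0.02,
    seed: int = 0,
) -> List[Track]:
    """Replicate term-seq 3'-end count tracks for the planted truth.

    Each replicate draws a Poisson main peak (mean ``peak_height``) at every
    true position plus ``n_shadows`` shadow counts at rounded-Normal offsets
    truncated to +/-10 nt (per-shadow mean ``peak_height / 10``), over uniform
    Poisson background noise at ``noise_rate`` counts/nt.
    """
    if replicates < 2:
        raise ValueError("term-seq simulation needs >= 2 replicates")
    if peak_height < 1:
        raise ValueError("peak_height must be >= 1")
    children = np.random.SeedSequence(seed).spawn(replicates)
    tracks = []
    for child in children:
        rng = np.random.default_rng(child)
        track = Track(lengths)
        if noise_rate > 0:
            for key in track.iter_keys():
                track.data[key] = rng.poisson(
                    noise_rate, lengths[key[0]]).astype(float)
        for tep in truth.teps:
            arr = track[(tep.contig, tep.strand)]
            arr[tep.position] += rng.poisson(peak_height)
            if n_shadows > 0:
                offs = np.clip(np.rint(rng.normal(0, shadow_sd, n_shadows)),
                               -10, 10).astype(int)
                counts = rng.poisson(peak_height / 10.0, n_shadows)
                for off, c in zip(offs, counts):
                    pos = tep.position + off
                    if 0 <= pos < len(arr):
                        arr[pos] += c
        tracks.append(track)
    return tracks


def simulate_rnaseq(
    truth: TruthTable,
    lengths: Dict[str, int],
    phases: Sequence[str] = DEFAULT_PHASES,
    depth: float = 100.0,
    readthrough_by_class: Optional[Dict[str, float]] = None,
    readthrough_len: int = 300,
    background_frac: float = 0.01,
    noise: bool = True,
    seed: int = 0,
) -> Dict[str, Track]:
    """RNA-seq coverage with a class-specific step-down after each planted TEP.

    Expected coverage is ``depth`` over every planted TU span,
    ``depth * class ratio`` for ``readthrough_len`` nt downstream of its TEP,
    and ``background_frac * depth`` elsewhere; per-position Poisson noise is
    added unless ``noise`` is False.
    """
    ratios = dict(DEFAULT_READTHROUGH if readthrough_by_class is None
                  else readthrough_by_class)
    for cls, r in ratios.items():
        if not 0 <= r <= 1.5:
            raise ValueError(f"read-through ratio for {cls} outside [0, 1.5]")

    expected = Track(lengths)
    for key in expected.iter_keys():
        expected.data[key] += background_frac * depth
    for tu in truth.tus:
        lo, hi = min(tu.tss, tu.tep), max(tu.tss, tu.tep) + 1
        expected[(tu.contig, tu.strand)][lo:hi] = depth
    for tep in truth.teps:
        arr = expected[(tep.contig, tep.strand)]
        if tep.strand == "+":
            lo, hi = tep.position + 1, min(tep.position + 1 + readthrough_len, len(arr))
        else:
            lo, hi = max(tep.position - readthrough_len, 0), tep.position
        arr[lo:hi] = depth * ratios[tep.tep_class]

    children = np.random.SeedSequence(seed).spawn(len(phases))
    out: Dict[str, Track] = {}
    for phase, child in zip(phases, children):
        rng = np.random.default_rng(child)
        track = Track(lengths)
        for key in track.iter_keys():
            mu = expected[key]
            track.data[key] = rng.poisson(mu).astype(float) if noise else mu.copy()
        out[phase] = track
    return out


def simulate_rpf(
    truth: TruthTable,
    genes: Sequence[GeneModel],
    rna: Dict[str, Track],
    lengths: Dict[str, int],
    coding_boost: float = 3.0,
    small_protein_tus: Optional[Sequence[Tuple[str, str, int, int]]] = None,
    background: float = 0.2,
    noise: bool = True,
    seed: int = 0,
) -> Track:
    """Ribosome-profiling coverage: boosted over CDSs and designated small-ORF
    transcription units, background elsewhere."""
    if coding_boost <= 1:
        raise ValueError("coding_boost must be > 1")
    mean_rna = Track(lengths)
    for key in mean_rna.iter_keys():
        mean_rna.data[key] = np.mean([t[key] for t in rna.values()], axis=0)

    expected = Track(lengths)
    for key in expected.iter_keys():
        expected.data[key] += background
    spans = [(g.contig, g.strand, g.cds_start, g.cds_end) for g in genes]
    spans.extend(small_protein_tus or [])
    for contig, strand, start, end in spans:
        key = (contig, strand)
        expected[key][start:end] = coding_boost * mean_rna[key][start:end]

    rng = np.random.default_rng(seed)
    track = Track(lengths)
    for key in track.iter_keys():
        mu = expected[key]
        track.data[key] = rng.poisson(mu).astype(float) if noise else mu.copy()
    return track


def default_simulation(seed: int = 0, n_genes: int = 20, gc: float = 0.72,
                       replicates: int = 2, peak_height: float = 50.0,
                       noise_rate: float = 0.02, depth: float = 100.0,
                       class_mix: Tuple[float, float, float] = DEFAULT_CLASS_MIX):
    """The standard study-condition bundle used by tests and examples."""
    ss = np.random.SeedSequence(seed)
    s_gen, s_plant, s_term, s_rna = [int(c.generate_state(1)[0] % (2**31))
                                     for c in ss.spawn(4)]
    genome, genes, tss_set = generate_genome(n_genes=n_genes, gc=gc, seed=s_gen)
    genome, truth = plant_terminators(genome, genes, tss_set,
                                      class_mix=class_mix, seed=s_plant)
    lengths = genome.lengths
    termseq = simulate_termseq(truth, lengths, replicates=replicates,
                               peak_height=peak_height, noise_rate=noise_rate,
                               seed=s_term)
    rnaseq = simulate_rnaseq(truth, lengths, depth=depth, seed=s_rna)
    return genome, genes, tss_set, truth, termseq, rnaseq
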