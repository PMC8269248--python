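"""Transcription-unit assembly from TSS x TEP pairs and RNA-seq coverage.

A candidate TSS-TEP pair becomes a transcription unit (TU) when, in at least
one growth phase, every 200-bp window slid 1 bp at a time across the
evaluation region (TSS + 100 bp through TEP - 100 bp, or the full span for
pairs closer than 200 bp) has an RPM-normalized mean above 5% of the region
mean and a raw mean of at least 5. Overlapping TUs (>= 1 bp, half-open
intervals) form transcription-unit clusters (TUCs); members ending at the
cluster's 3'-most TEP are terminal, all others nonterminal.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import PipelineConfig
from .coverage import normalize_rpm
from .model import GeneModel, Tep, Track, Tss, Tu, Tuc

log = logging.getLogger(__name__)


def candidate_pairs(tss_set: Sequence[Tss], teps: Sequence[Tep],
                    max_span: int = 20000) -> List[Tuple[Tss, Tep]]:
    """All same-contig, same-strand pairs with the TEP downstream of the TSS
    and a span of at most ``max_span`` (larger spans are logged and skipped)."""
    pairs = []
    skipped = 0
    for tss in tss_set:
        for tep in teps:
            if tep.contig != tss.contig or tep.strand != tss.strand:
                continue
            span = (tep.position - tss.position if tss.strand == "+"
                    else tss.position - tep.position)
            if span <= 0:
                continue
            if span > max_span:
                skipped += 1
                continue
            pairs.append((tss, tep))
    if skipped:
        log.info("skipped %d TSS-TEP pairs above the %d-bp span bound",
                 skipped, max_span)
    return pairs


def _sliding_means(arr: np.ndarray, width: int) -> np.ndarray:
    cums = np.concatenate([[0.0], np.cumsum(arr)])
    return (cums[width:] - cums[:-width]) / width


def evaluate_pair(
    tss: Tss,
    tep: Tep,
    raw_by_phase: Dict[str, Track],
    rpm_by_phase: Dict[str, Track],
    config: PipelineConfig,
) -> Tuple[bool, List[str]]:
    """Sliding-window connectivity test for one TSS-TEP pair.

    A phase passes when every window's normalized mean exceeds
    ``tu_frac`` x the region's normalized mean and every window's raw mean is
    at least ``tu_min_raw`` (with ``lenient_window_filter`` the low-raw
    windows are merely skipped from the 5% test instead of failing the
    phase). The pair is a TU when at least one phase passes.
    """
    strand = tss.strand
    key = (tss.contig, strand)
    if strand == "+":
        full_lo, full_hi = tss.position, tep.position + 1
        eval_lo = tss.position + config.tss_offset
        eval_hi = tep.position - config.tep_offset + 1
    else:
        full_lo, full_hi = tep.position, tss.position + 1
        eval_lo = tep.position + config.tep_offset
        eval_hi = tss.position - config.tss_offset + 1
    span = full_hi - full_lo
    if span < config.short_pair_cutoff or eval_hi <= eval_lo:
        eval_lo, eval_hi = full_lo, full_hi

    passing: List[str] = []
    for phase in raw_by_phase:
        raw = raw_by_phase[phase][key][eval_lo:eval_hi]
        rpm = rpm_by_phase[phase][key][eval_lo:eval_hi]
        width = min(config.tu_window, len(raw))
        if width == 0:
            continue
        raw_means = _sliding_means(raw, width)
        rpm_means = _sliding_means(rpm, width)
        region_mean = rpm.mean()
        frac_ok = rpm_means > config.tu_frac * region_mean
        raw_ok = raw_means >= config.tu_min_raw
        if config.lenient_window_filter:
            considered = frac_ok[raw_ok]
            ok = considered.size > 0 and bool(considered.all())
        else:
            ok = bool(raw_ok.all() and frac_ok.all())
        if ok:
            passing.append(phase)
    return bool(passing), passing


def categorize_tu(tu: Tu, genes: Sequence[GeneModel]) -> str:
    """Mono / Poly / Pre / Inter from fully contained same-strand CDS count."""
    contained = [g.gene_id for g in genes
                 if g.contig == tu.contig and g.strand == tu.strand
                 and g.cds_start >= tu.start and g.cds_end <= tu.end]
    tu.gene_ids = contained
    if len(contained) == 1:
        return "Mono"
    if len(contained) >= 2:
        return "Poly"
    return "Pre" if tu.tep.category == "Pre" else "Inter"


def build_tucs(tus: Sequence[Tu]) -> List[Tuc]:
    """Connected components of the >= 1-bp interval-overlap graph, per
    contig and strand. Every TU lands in exactly one TUC."""
    by_key: Dict[Tuple[str, str], List[Tu]] = {}
    for tu in tus:
        by_key.setdefault((tu.contig, tu.strand), []).append(tu)
    tucs: List[Tuc] = []
    for (contig, strand), group in sorted(by_key.items()):
        group.sort(key=lambda t: (t.start, t.end))
        current: List[Tu] = []
        cur_end = None
        for tu in group:
            if current and tu.start >= cur_end:
                tucs.append(Tuc(current, contig, strand,
                                min(t.start for t in current), cur_end))
                current, cur_end = [], None
            current.append(tu)
            cur_end = tu.end if cur_end is None else max(cur_end, tu.end)
        if current:
            tucs.append(Tuc(current, contig, strand,
                            min(t.start for t in current), cur_end))
    return tucs


def assign_terminality(tuc: Tuc) -> None:
    """Members whose TEP is the cluster's 3'-most TEP are terminal; labels
    propagate to the TEPs themselves. Ties share the terminal label."""
    if not tuc.members:
        return
    positions = [tu.tep.position for tu in tuc.members]
    terminal_pos = max(positions) if tuc.strand == "+" else min(positions)
    for tu in tuc.members:
        tu.terminality = ("terminal" if tu.tep.position == terminal_pos
                          else "nonterminal")
        tu.tep.terminality = tu.terminality


def assemble_tus(
    tss_set: Sequence[Tss],
    teps: Sequence[Tep],
    raw_by_phase: Dict[str, Track],
    genes: Sequence[GeneModel],
    config: PipelineConfig,
    rpm_by_phase: Optional[Dict[str, Track]] = None,
) -> Tuple[List[Tu], List[Tuc]]:
    """Evaluate all candidate pairs and cluster the resulting TUs."""
    if rpm_by_phase is None:
        rpm_by_phase = {phase: normalize_rpm(t) for phase, t in raw_by_phase.items()}
    usable = [t for t in teps if t.category != "Internal"]
    tus: List[Tu] = []
    for tss, tep in candidate_pairs(tss_set, usable, config.max_tu_span):
        is_tu, phases = evaluate_pair(tss, tep, raw_by_phase, rpm_by_phase, config)
        if not is_tu:
            continue
        lo = min(tss.position, tep.position)
        hi = max(tss.position, tep.position) + 1
        tu = Tu(tss, tep, tss.contig, tss.strand, lo, hi, passing_phases=phases)
        tu.category = categorize_tu(tu, genes)
        tus.append(tu)
    tucs = build_tucs(tus)
    for tuc in tucs:
        assign_terminality(tuc)
    return tus, tucs
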