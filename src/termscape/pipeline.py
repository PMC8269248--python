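"""End-to-end orchestration: tracks in, annotated TEPs/TUs/TUCs and a
summary report out."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .analysis import detect_biteps, report
from .calling import call_teps, categorize_teps
from .classify import annotate_structure
from .config import PipelineConfig
from .coverage import normalize_rpm, readthrough_fraction
from .model import BiTepPair, GeneModel, Genome, Tep, Track, Tss, Tu, Tuc
from .tu import assemble_tus


@dataclass
class PipelineResult:
    teps: List[Tep]
    tus: List[Tu]
    tucs: List[Tuc]
    biteps: List[BiTepPair]
    summary: Dict[str, object]
    cv_accuracy: Optional[float]
    training_sizes: Dict[str, int] = field(default_factory=dict)


def run_pipeline(
    genome: Genome,
    genes: Sequence[GeneModel],
    tss_set: Sequence[Tss],
    termseq_tracks: Sequence[Track],
    rnaseq_tracks: Dict[str, Track],
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Call, categorize and classify 3' ends, then assemble TUs and TUCs.

    ``termseq_tracks`` holds raw 3'-end counts per replicate; term-seq counts
    stay raw for calling while ``rnaseq_tracks`` (raw depth per growth phase)
    are RPM-normalized for every coverage statistic.
    """
    config = config or PipelineConfig()
    rpm = {phase: normalize_rpm(t) for phase, t in rnaseq_tracks.items()}

    teps, cv_accuracy, sizes = call_teps(termseq_tracks, rpm, config)
    categorize_teps(teps, genes, tss_set, config)
    annotate_structure(teps, genome, config)
    for tep in teps:
        tep.readthrough = readthrough_fraction(tep, rpm, config.readthrough_flank)

    tus, tucs = assemble_tus(tss_set, teps, rnaseq_tracks, genes, config,
                             rpm_by_phase=rpm)
    biteps = detect_biteps([t for t in teps if t.category != "Internal"], config)
    summary = report(teps, tus, tucs, biteps)
    return PipelineResult(teps, tus, tucs, biteps, summary, cv_accuracy, sizes)
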