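"""Recovery metrics against a simulation truth table.

Matches called 3'-end positions to planted ones within a positional
tolerance (term-seq ends jitter by a nucleotide or two) and scores
precision, recall, class-label agreement and planted-TU recall.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

from .model import Tep, Tu
from .simulate import PlantedTep, TruthTable


def match_teps(called: Sequence[Tep], truth: TruthTable,
               tolerance: int = 2) -> List[Tuple[Tep, PlantedTep]]:
    """Greedy nearest-position matching of called to planted ends."""
    by_key = {(t.contig, t.strand, t.position): t for t in truth.teps}
    matches: List[Tuple[Tep, PlantedTep]] = []
    for tep in called:
        for off in sorted(range(-tolerance, tolerance + 1), key=abs):
            planted = by_key.get((tep.contig, tep.strand, tep.position + off))
            if planted is not None:
                matches.append((tep, planted))
                break
    return matches


def recovery_metrics(called: Sequence[Tep], tus: Sequence[Tu],
                     truth: TruthTable, tolerance: int = 2) -> Dict[str, float]:
    matches = match_teps(called, truth, tolerance)
    n_called = len(called)
    n_truth = len(truth.teps)
    recovered = {id(p) for _, p in matches}
    agreement = [tep.tep_class == planted.tep_class
                 for tep, planted in matches]

    tu_keys = {(tu.tss.position, tu.tep.position, tu.strand, tu.contig)
               for tu in tus}

    def tu_found(planted) -> bool:
        return any(
            tss == planted.tss and strand == planted.strand
            and contig == planted.contig and abs(tep - planted.tep) <= tolerance
            for tss, tep, strand, contig in tu_keys
        )

    tu_hits = [tu_found(p) for p in truth.tus]
    return {
        "precision": len(matches) / n_called if n_called else 0.0,
        "recall": len(recovered) / n_truth if n_truth else 0.0,
        "class_agreement": (sum(agreement) / len(agreement)) if agreement else 0.0,
        "tu_recall": (sum(tu_hits) / len(tu_hits)) if tu_hits else 0.0,
        "n_called": float(n_called),
        "n_planted": float(n_truth),
    }
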