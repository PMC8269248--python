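"""Core domain types shared by every pipeline stage.

Coordinates are 0-based half-open genomic throughout the package. All
strand-aware windows ("upstream", "downstream") are computed in transcript
orientation: on the minus strand, downstream means decreasing genomic
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

TEP_CATEGORIES = ("P", "S", "Pre", "A", "N", "Internal")
TEP_CLASSES = ("HS-U-rich", "HS-U-lack", "LS")
TU_CATEGORIES = ("Mono", "Poly", "Pre", "Inter")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Malformed or out-of-bounds on-disk input."""


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class Genome:
    """Genome sequence: contig id -> uppercase nucleotide string."""

    contigs: Dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise FormatError(f"contig {name!r} is empty")
            bad = set(seq) - ALPHABET
            if bad:
                raise FormatError(
                    f"contig {name!r} contains non-ACGTN symbols: {sorted(bad)}"
                )

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def subseq(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end); reverse-complemented on the minus strand."""
        seq = self.contigs[contig][max(start, 0) : end]
        return revcomp(seq) if strand == "-" else seq


@dataclass
class GeneModel:
    gene_id: str
    contig: str
    strand: str
    cds_start: int  # 0-based
    cds_end: int  # half-open
    cog: Optional[str] = None
    smbgc: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not self.cds_start < self.cds_end:
            raise FormatError(f"gene {self.gene_id}: cds_start must be < cds_end")

    @property
    def stop_end(self) -> int:
        """First genomic base past the stop codon, transcript orientation."""
        return self.cds_end if self.strand == "+" else self.cds_start - 1


@dataclass
class Tss:
    contig: str
    position: int
    strand: str
    category: str = "primary"
    gene_id: Optional[str] = None


@dataclass
class StemLoop:
    stem_length: int
    loop_length: int
    stem_end_offset: int  # relative to the 3'-end base (offset 0)
    dot_bracket: str


@dataclass
class Tep:
    """A called transcript 3'-end position."""

    contig: str
    position: int
    strand: str
    count: float = 0.0
    category: Optional[str] = None
    gene_id: Optional[str] = None
    tep_class: Optional[str] = None
    delta_g: Optional[float] = None
    stem: Optional[StemLoop] = None
    u_count: Optional[int] = None
    readthrough: Optional[float] = None
    zscore: Optional[float] = None
    terminality: Optional[str] = None
    flagged: bool = False

    @property
    def key(self) -> Tuple[str, str, int]:
        return (self.contig, self.strand, self.position)


@dataclass
class Tu:
    tss: Tss
    tep: Tep
    contig: str
    strand: str
    start: int  # half-open genomic span covering TSS..TEP
    end: int
    gene_ids: List[str] = field(default_factory=list)
    category: Optional[str] = None
    terminality: Optional[str] = None
    passing_phases: List[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Tuc:
    members: List[Tu]
    contig: str
    strand: str
    start: int
    end: int

    @property
    def gene_ids(self) -> List[str]:
        seen: List[str] = []
        for tu in self.members:
            for g in tu.gene_ids:
                if g not in seen:
                    seen.append(g)
        return seen


@dataclass
class BiTepPair:
    forward_tep: Tep
    reverse_tep: Tep
    overlap: int


@dataclass
class PoissonDistance:
    p: float
    d: float


class Track:
    """Dense per-position signal, one float array per (contig, strand).

    Used for term-seq 3'-end counts, RNA-seq depth and ribosome-profiling
    depth alike.
    """

    def __init__(self, lengths: Mapping[str, int]) -> None:
        self.lengths = dict(lengths)
        self.data: Dict[Tuple[str, str], np.ndarray] = {
            (contig, strand): np.zeros(n, dtype=float)
            for contig, n in self.lengths.items()
            for strand in "+-"
        }

    def __getitem__(self, key: Tuple[str, str]) -> np.ndarray:
        return self.data[key]

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    def copy(self) -> "Track":
        new = Track(self.lengths)
        for key, arr in self.data.items():
            new.data[key] = arr.copy()
        return new

    def scaled(self, factor: float) -> "Track":
        new = self.copy()
        for arr in new.data.values():
            arr *= factor
        return new

    def iter_keys(self) -> Iterable[Tuple[str, str]]:
        return self.data.keys()


def tx_offset_to_genomic(position: int, strand: str, offset: int) -> int:
    """Genomic coordinate of a transcript-orientation offset from ``position``."""
    return position + offset if strand == "+" else position - offset


def coding_base(genome: Genome, contig: str, strand: str, position: int) -> str:
    """Transcript-strand base at a genomic position (complemented on minus)."""
    base = genome.contigs[contig][position]
    return base.translate(_COMPLEMENT) if strand == "-" else base
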