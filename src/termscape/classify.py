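"""RNA-structure classification of transcript 3' ends.

Each 3'-end position (TEP) is classified from the minimum-free-energy fold of
its 40-nt upstream window (computed at 30 degC): ends whose window folds below
-23 kcal/mol are "highly structured" (HS) and are split by the uridine count
in the 8-nt tract downstream of the stem into HS-U-rich (>= 3 U; the classic
intrinsic-terminator hairpin + U-tract signature) and HS-U-lack; everything
else is "less structured" (LS). Sequence-context statistics (per-offset
nucleotide enrichment and base-pairing interaction frequencies) are computed
against random genomic backgrounds.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import RNA
from scipy.optimize import brentq
from sklearn.mixture import GaussianMixture

from .config import PipelineConfig
from .model import Genome, StemLoop, Tep, coding_base, revcomp

log = logging.getLogger(__name__)

FOLD_ENGINE = f"ViennaRNA {RNA.__version__}"


class StructureError(ValueError):
    """Unbalanced or otherwise invalid dot-bracket string."""


def upstream_rna(genome: Genome, tep: Tep, window: int) -> str:
    """Transcript-orientation RNA covering offsets -window..-1 from the TEP.

    The TEP base itself (offset 0) is excluded. Windows clipped at a contig
    edge to fewer than 10 nt return "" and the record should be skipped.
    """
    n = len(genome.contigs[tep.contig])
    if tep.strand == "+":
        start, end = max(tep.position - window, 0), tep.position
        seq = genome.contigs[tep.contig][start:end]
    else:
        start, end = tep.position + 1, min(tep.position + 1 + window, n)
        seq = revcomp(genome.contigs[tep.contig][start:end])
    if len(seq) < window:
        tep.flagged = True
        if len(seq) < 10:
            log.warning("TEP %s:%d%s: upstream window clipped to %d nt; skipped",
                        tep.contig, tep.position, tep.strand, len(seq))
            return ""
    return seq.replace("T", "U")


def fold_mfe(rna: str, temperature: float = 30.0) -> Tuple[float, str]:
    """Minimum-free-energy fold under the nearest-neighbor model.

    Returns (delta-G in kcal/mol, dot-bracket structure). Delegates to the
    ViennaRNA fold engine with default parameters apart from temperature.
    """
    if not rna:
        raise ValueError("empty RNA sequence")
    seq = rna.upper().replace("T", "U")
    if set(seq) - set("ACGU"):
        raise ValueError(f"non-ACGU symbols in RNA: {sorted(set(seq) - set('ACGU'))}")
    md = RNA.md()
    md.temperature = temperature
    fc = RNA.fold_compound(seq, md)
    structure, dg = fc.mfe()
    return float(dg), structure


def _pair_table(dot_bracket: str) -> Dict[int, int]:
    pairs: Dict[int, int] = {}
    stack: List[int] = []
    for i, ch in enumerate(dot_bracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced structure at position {i}")
            j = stack.pop()
            pairs[i] = j
            pairs[j] = i
        elif ch != ".":
            raise StructureError(f"unexpected symbol {ch!r} in dot-bracket")
    if stack:
        raise StructureError("unbalanced structure: unclosed '('")
    return pairs


def parse_stem_loop(dot_bracket: str) -> Optional[StemLoop]:
    """Extract the 3'-most hairpin (stem/loop closest to the 3' end).

    The stem is grown outward from the hairpin-closing pair, tolerating
    interior bulges of at most 1 nt on either side; stem length counts base
    pairs. Offsets are reported relative to the 3'-end base at offset 0, with
    the structure string covering offsets -len..-1. Returns ``None`` for
    structures without any base pair.
    """
    pairs = _pair_table(dot_bracket)
    if not pairs:
        return None
    n = len(dot_bracket)

    # hairpin-closing pairs: no paired base strictly inside
    hairpins = []
    for i, j in pairs.items():
        if i < j and all(k not in pairs for k in range(i + 1, j)):
            hairpins.append((i, j))
    inner_i, inner_j = max(hairpins, key=lambda ij: ij[1])
    loop_length = inner_j - inner_i - 1

    stem = 1
    i, j = inner_i, inner_j
    while True:
        found = None
        for gi in (1, 2):  # positions skipped on the 5' side (bulge <= 1 nt)
            for gj in (1, 2):
                i2, j2 = i - gi, j + gj
                if i2 < 0 or j2 >= n:
                    continue
                if pairs.get(i2) == j2 and all(
                    k not in pairs for k in list(range(i2 + 1, i)) + list(range(j + 1, j2))
                ):
                    found = (i2, j2)
                    break
            if found:
                break
        if not found:
            break
        i, j = found
        stem += 1
    stem_end_offset = j - n  # 3'-most paired base of the helix
    return StemLoop(stem, loop_length, stem_end_offset, dot_bracket)


def count_u_tract(genome: Genome, tep: Tep, stem: Optional[StemLoop],
                  window: int = 8) -> int:
    """Uridine count in the ``window``-nt tract downstream of the stem end.

    Offsets are transcript-orientation, relative to the TEP base at 0. When no
    stem exists the window is the ``window`` nt ending at the TEP, keeping the
    classification total.
    """
    n = len(genome.contigs[tep.contig])
    end_off = stem.stem_end_offset if stem is not None else -window
    offsets = range(end_off + 1, end_off + 1 + window)
    count = 0
    for off in offsets:
        pos = tep.position + off if tep.strand == "+" else tep.position - off
        if 0 <= pos < n and coding_base(genome, tep.contig, tep.strand, pos) == "T":
            count += 1
    return count


def classify_tep(delta_g: float, u_count: int, hs_threshold: float = -23.0,
                 utract_min_u: int = 3) -> str:
    """HS-U-rich / HS-U-lack / LS from folding energy and uridine count.

    Structured means strictly below the threshold; a value exactly on the
    threshold is LS.
    """
    if delta_g < hs_threshold:
        return "HS-U-rich" if u_count >= utract_min_u else "HS-U-lack"
    return "LS"


def annotate_structure(teps: Sequence[Tep], genome: Genome,
                       config: PipelineConfig) -> None:
    """Fill delta_g, stem, u_count and class for every non-internal TEP."""
    for tep in teps:
        if tep.category == "Internal":
            continue
        rna = upstream_rna(genome, tep, config.fold_window)
        if not rna:
            continue
        dg, structure = fold_mfe(rna, config.fold_temperature)
        tep.delta_g = dg
        tep.stem = parse_stem_loop(structure)
        tep.u_count = count_u_tract(genome, tep, tep.stem, config.utract_window)
        tep.tep_class = classify_tep(dg, tep.u_count, config.hs_threshold,
                                     config.utract_min_u)


def bimodal_split(values: Sequence[float], seed: int = 0,
                  min_separation: float = 1.0) -> float:
    """Diagnostic data-driven structured/unstructured threshold.

    Fits a two-component Gaussian mixture and returns the intersection point
    of the weighted component densities between the two means. Raises
    ``ValueError`` when the sample is too small or the mixture is degenerate
    (component means closer than ``min_separation`` kcal/mol); the pipeline
    then keeps its fixed configured threshold.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 50:
        raise ValueError("bimodal_split needs >= 50 values")
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=3)
    gm.fit(x.reshape(-1, 1))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    m1, m2 = means[order]
    s1, s2 = sds[order]
    w1, w2 = weights[order]
    if m2 - m1 < min_separation:
        raise ValueError("degenerate mixture: component means too close")

    def log_ratio(t: float) -> float:
        return (np.log(w1) - np.log(s1) - 0.5 * ((t - m1) / s1) ** 2) - (
            np.log(w2) - np.log(s2) - 0.5 * ((t - m2) / s2) ** 2
        )

    def mixture_pdf(t: float) -> float:
        return (w1 / s1 * np.exp(-0.5 * ((t - m1) / s1) ** 2)
                + w2 / s2 * np.exp(-0.5 * ((t - m2) / s2) ** 2))

    try:
        threshold = float(brentq(log_ratio, m1, m2))
    except ValueError:
        # densities do not cross between the means (strongly unequal weights)
        grid = np.linspace(m1, m2, 1000)
        threshold = float(grid[np.argmin(np.abs([log_ratio(t) for t in grid]))])

    # a genuine bimodal sample has a valley between the component modes; a
    # unimodal sample split in two by the fit does not
    if mixture_pdf(threshold) > 0.7 * min(mixture_pdf(m1), mixture_pdf(m2)):
        raise ValueError("degenerate mixture: no density valley between "
                         "components (sample looks unimodal)")
    return threshold


def _window_bases(genome: Genome, contig: str, strand: str, position: int,
                  halfwidth: int) -> Optional[str]:
    n = len(genome.contigs[contig])
    if position - halfwidth < 0 or position + halfwidth >= n:
        return None
    if strand == "+":
        seq = genome.contigs[contig][position - halfwidth: position + halfwidth + 1]
    else:
        seq = revcomp(genome.contigs[contig][position - halfwidth: position + halfwidth + 1])
    return seq.replace("T", "U")


def _random_positions(genome: Genome, n: int, halfwidth: int,
                      rng: np.random.Generator):
    contigs = list(genome.contigs)
    lens = np.array([len(genome.contigs[c]) for c in contigs], dtype=float)
    probs = lens / lens.sum()
    out = []
    while len(out) < n:
        c = contigs[rng.choice(len(contigs), p=probs)]
        pos = int(rng.integers(halfwidth, len(genome.contigs[c]) - halfwidth))
        strand = "+" if rng.random() < 0.5 else "-"
        out.append((c, strand, pos))
    return out


def nucleotide_enrichment(teps: Sequence[Tep], genome: Genome,
                          random_n: int = 10000, seed: int = 0,
                          halfwidth: int = 50) -> pd.DataFrame:
    """Per-offset base-frequency fold change against a random background.

    Rows are offsets -halfwidth..+halfwidth (transcript orientation, TEP base
    at 0); columns A/C/G/U. The background is the position-averaged base
    frequency over ``random_n`` random genomic windows.
    """
    if not teps:
        raise ValueError("nucleotide_enrichment needs a nonempty TEP set")
    rng = np.random.default_rng(seed)
    bases = "ACGU"
    width = 2 * halfwidth + 1

    def freq_matrix(windows: List[str]) -> np.ndarray:
        counts = np.zeros((width, 4))
        for w in windows:
            for k, ch in enumerate(w):
                if ch in bases:
                    counts[k, bases.index(ch)] += 1
        totals = counts.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1
        return counts / totals

    tep_windows = [
        w for t in teps
        if (w := _window_bases(genome, t.contig, t.strand, t.position, halfwidth))
    ]
    bg_windows = [
        w for c, s, p in _random_positions(genome, random_n, halfwidth, rng)
        if (w := _window_bases(genome, c, s, p, halfwidth))
    ]
    tep_freq = freq_matrix(tep_windows)
    background = freq_matrix(bg_windows).mean(axis=0)  # one frequency per base
    background[background == 0] = 1e-12
    fold = tep_freq / background
    offsets = np.arange(-halfwidth, halfwidth + 1)
    df = pd.DataFrame(fold, index=offsets, columns=list(bases))
    df.attrs["background"] = dict(zip(bases, background))
    df.attrs["fold_engine"] = FOLD_ENGINE
    return df


def interaction_matrix(teps: Sequence[Tep], genome: Genome, window: int = 100,
                       temperature: float = 30.0) -> np.ndarray:
    """Base-pairing frequency between upstream-window positions.

    Entry (i, j) is the fraction of TEPs whose MFE structure of the
    ``window``-nt upstream region pairs offsets -window+i and -window+j.
    Symmetric, entries in [0, 1].
    """
    if not teps:
        raise ValueError("interaction_matrix needs a nonempty TEP set")
    mat = np.zeros((window, window))
    used = 0
    for tep in teps:
        rna = upstream_rna(genome, tep, window)
        if len(rna) < window:
            continue
        _, structure = fold_mfe(rna, temperature)
        pairs = _pair_table(structure)
        for i, j in pairs.items():
            if i < j:
                mat[i, j] += 1
                mat[j, i] += 1
        used += 1
    if used:
        mat /= used
    return mat
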