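"""Transcript 3'-end calling from replicate term-seq count tracks.

The caller resolves "peak shadows" (positional jitter around a true 3' end)
by single-linkage clustering of nonzero positions (< 100 bp apart), greedy
sub-clustering while the positional standard deviation stays below 25,
maximum-intensity representative selection, raw-count and replicate-presence
filters, a flank Z-score, and a K-nearest-neighbor classifier over the 21-nt
count profile around each candidate. Training examples are screened
automatically: candidates with Z > 6 whose RNA coverage drops at the site
(read-through < 0.5) are positives; the 20 offset positions around each
positive are negatives. The final call set is the union over replicates of
positively labeled candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.neighbors import KNeighborsClassifier

from .config import PipelineConfig
from .coverage import readthrough_fraction
from .model import GeneModel, Genome, Tep, Track, Tss

log = logging.getLogger(__name__)


class TrainingError(ValueError):
    pass


@dataclass
class PeakCandidate:
    contig: str
    strand: str
    position: int
    replicate: int
    count: float
    zscore: Optional[float] = None
    readthrough: Optional[float] = None
    features: Optional[np.ndarray] = None
    label: Optional[bool] = None
    flagged: bool = False

    @property
    def key(self) -> Tuple[str, str, int]:
        return (self.contig, self.strand, self.position)


# ---------------------------------------------------------------------------
# clustering


def cluster_peaks(counts: np.ndarray, cluster_gap: int = 100) -> List[np.ndarray]:
    """Single-linkage clusters of nonzero positions: gaps < ``cluster_gap``
    join, gaps >= ``cluster_gap`` split. An all-zero track yields []."""
    positions = np.flatnonzero(counts)
    if positions.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(positions) >= cluster_gap)
    return np.split(positions, breaks + 1)


def subcluster_peaks(positions: Sequence[int], counts: np.ndarray,
                     subcluster_sd: float = 25.0,
                     strand: str = "+") -> List[Tuple[np.ndarray, int]]:
    """Greedy left-to-right sub-clustering within one cluster.

    The current sub-cluster is extended while the population standard
    deviation of its member positions stays below ``subcluster_sd``. Each
    sub-cluster's representative is its maximum-count position; count ties
    break toward the 5'-most position in transcript orientation.
    """
    positions = np.asarray(positions)
    if positions.size == 0:
        return []
    groups: List[List[int]] = [[int(positions[0])]]
    for pos in positions[1:]:
        candidate = groups[-1] + [int(pos)]
        if np.std(candidate) < subcluster_sd:
            groups[-1] = candidate
        else:
            groups.append([int(pos)])

    out = []
    for group in groups:
        arr = np.array(group)
        vals = counts[arr]
        best = vals.max()
        winners = arr[vals == best]
        rep = int(winners.min() if strand == "+" else winners.max())
        out.append((arr, rep))
    return out


def filter_candidates(representatives: Sequence[Tuple[int, float]],
                      tracks: Sequence[np.ndarray], calling_rep: int,
                      min_peak_count: float = 4.0,
                      tolerance: int = 2) -> List[Tuple[int, float]]:
    """Raw-count and replicate-presence filters.

    A representative survives when its count in the calling replicate is at
    least ``min_peak_count`` and every other replicate carries signal within
    ``tolerance`` nt of the same position.
    """
    kept = []
    for pos, count in representatives:
        if count < min_peak_count:
            continue
        present = True
        for r, arr in enumerate(tracks):
            if r == calling_rep:
                continue
            lo, hi = max(pos - tolerance, 0), min(pos + tolerance + 1, len(arr))
            if arr[lo:hi].sum() < 1:
                present = False
                break
        if present:
            kept.append((pos, count))
    return kept


def peak_zscore(counts: np.ndarray, position: int,
                flank_halfwidth: int = 50) -> Tuple[float, bool]:
    """z = (x - mu) / max(sigma, 1) over the +/-flank window excluding the peak.

    mu and sigma are the mean and population standard deviation of counts at
    offsets -flank..-1 and +1..+flank; the sigma floor avoids division by zero
    on sparse flanks. Windows clipped at a contig edge are computed on the
    available positions and flagged.
    """
    n = len(counts)
    lo, hi = position - flank_halfwidth, position + flank_halfwidth + 1
    clipped = lo < 0 or hi > n
    lo, hi = max(lo, 0), min(hi, n)
    flank = np.concatenate([counts[lo:position], counts[position + 1: hi]])
    if flank.size == 0:
        return float(counts[position]), True
    mu = flank.mean()
    sigma = max(flank.std(), 1.0)
    return float((counts[position] - mu) / sigma), clipped


def feature_vector(counts: np.ndarray, position: int,
                   halfwidth: int = 10) -> np.ndarray:
    """Counts at offsets -halfwidth..+halfwidth, zero-padded at contig edges."""
    vec = np.zeros(2 * halfwidth + 1)
    lo, hi = max(position - halfwidth, 0), min(position + halfwidth + 1, len(counts))
    vec[lo - (position - halfwidth): hi - (position - halfwidth)] = counts[lo:hi]
    return vec


# ---------------------------------------------------------------------------
# training and classification


def build_training_sets(candidates: Sequence[PeakCandidate],
                        tracks: Sequence[Track],
                        config: PipelineConfig) -> Tuple[np.ndarray, np.ndarray]:
    """Positive/negative 21-nt count-profile training vectors.

    Positives: candidates with Z above ``zscore_min`` whose read-through
    fraction is below ``readthrough_cutoff`` (an automated stand-in for
    manual "decreased RNA profile" screening). Negatives: the 20 offset
    positions -10..+10 (excluding 0) of each positive, dropping offsets that
    coincide with another positive.
    """
    hw = config.knn_window_halfwidth
    positives = [c for c in candidates
                 if c.zscore is not None and c.zscore > config.zscore_min
                 and c.readthrough is not None
                 and c.readthrough < config.readthrough_cutoff]
    if len(positives) < 10:
        raise TrainingError(
            f"only {len(positives)} positive training peaks; simulate or load "
            "a larger data set")
    positive_keys = {c.key for c in positives}

    X: List[np.ndarray] = []
    y: List[int] = []
    for cand in positives:
        arr = tracks[cand.replicate][(cand.contig, cand.strand)]
        X.append(feature_vector(arr, cand.position, hw))
        y.append(1)
    for cand in positives:
        arr = tracks[cand.replicate][(cand.contig, cand.strand)]
        for off in range(-hw, hw + 1):
            if off == 0:
                continue
            pos = cand.position + off
            if pos < 0 or pos >= len(arr):
                continue
            if (cand.contig, cand.strand, pos) in positive_keys:
                continue
            X.append(feature_vector(arr, pos, hw))
            y.append(0)
    return np.array(X), np.array(y)


def train_and_call(
    training: Tuple[np.ndarray, np.ndarray],
    candidate_features: np.ndarray,
    k: int = 5,
    cv_fraction: float = 0.5,
    cv_reps: int = 1000,
    seed: int = 0,
) -> Tuple[np.ndarray, Optional[float]]:
    """KNN classification of candidate count profiles.

    Distances are Euclidean on log1p-transformed counts. Held-out accuracy is
    the mean over ``cv_reps`` random ``cv_fraction`` splits (None when
    ``cv_reps`` is 0). Returns (boolean labels, cv accuracy).
    """
    X, y = training
    if X.size == 0 or len(set(y.tolist())) < 2:
        raise TrainingError("training set must contain both classes")
    Xl = np.log1p(X)
    rng = np.random.default_rng(seed)

    accuracy = None
    if cv_reps > 0:
        n = len(y)
        n_train = max(int(round(n * cv_fraction)), 1)
        scores = []
        for _ in range(cv_reps):
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
            if len(set(y[tr].tolist())) < 2 or te.size == 0:
                continue
            model = KNeighborsClassifier(n_neighbors=min(k, len(tr)))
            model.fit(Xl[tr], y[tr])
            scores.append(model.score(Xl[te], y[te]))
        accuracy = float(np.mean(scores)) if scores else None

    model = KNeighborsClassifier(n_neighbors=min(k, len(y)))
    model.fit(Xl, y)
    labels = model.predict(np.log1p(candidate_features)).astype(bool)
    return labels, accuracy


# ---------------------------------------------------------------------------
# orchestration


def collect_candidates(tracks: Sequence[Track],
                       config: PipelineConfig) -> List[PeakCandidate]:
    """Cluster/sub-cluster/filter every replicate track into peak candidates."""
    candidates: List[PeakCandidate] = []
    for rep, track in enumerate(tracks):
        for (contig, strand), arr in track.data.items():
            others = [t[(contig, strand)] for t in tracks]
            reps: List[Tuple[int, float]] = []
            for cluster in cluster_peaks(arr, config.cluster_gap):
                for _, rep_pos in subcluster_peaks(cluster, arr,
                                                   config.subcluster_sd, strand):
                    reps.append((rep_pos, float(arr[rep_pos])))
            for pos, count in filter_candidates(reps, others, rep,
                                                config.min_peak_count,
                                                config.replicate_tolerance):
                z, clipped = peak_zscore(arr, pos, config.zscore_flank)
                candidates.append(PeakCandidate(contig, strand, pos, rep, count,
                                                zscore=z, flagged=clipped))
    return candidates


def _merge_union(called: List[PeakCandidate], tolerance: int) -> List[Tep]:
    """Union over replicates, merging calls within ``tolerance`` nt."""
    teps: List[Tep] = []
    by_key: Dict[Tuple[str, str], List[PeakCandidate]] = {}
    for cand in called:
        by_key.setdefault((cand.contig, cand.strand), []).append(cand)
    for (contig, strand), group in sorted(by_key.items()):
        group.sort(key=lambda c: c.position)
        block: List[PeakCandidate] = []
        for cand in group + [None]:
            if block and (cand is None
                          or cand.position - block[-1].position > tolerance):
                best = max(block, key=lambda c: (c.count, -c.position))
                teps.append(Tep(contig, best.position, strand, count=best.count,
                                zscore=best.zscore,
                                readthrough=best.readthrough))
                block = []
            if cand is not None:
                block.append(cand)
    return teps


def call_teps(termseq_tracks: Sequence[Track], rpm_coverage: Dict[str, Track],
              config: PipelineConfig) -> Tuple[List[Tep], Optional[float], Dict[str, int]]:
    """Full calling pass: candidates -> training screen -> KNN -> union.

    ``rpm_coverage`` maps growth-phase name to an RPM-normalized RNA-seq
    track (used only for the automated positive-training screen). Returns the
    called TEPs, the KNN cross-validation accuracy, and training-set sizes.
    """
    candidates = collect_candidates(termseq_tracks, config)
    if not candidates:
        return [], None, {"positives": 0, "negatives": 0, "candidates": 0}
    for cand in candidates:
        probe = Tep(cand.contig, cand.position, cand.strand)
        cand.readthrough = readthrough_fraction(probe, rpm_coverage,
                                                config.readthrough_flank)
        arr = termseq_tracks[cand.replicate][(cand.contig, cand.strand)]
        cand.features = feature_vector(arr, cand.position,
                                       config.knn_window_halfwidth)

    X, y = build_training_sets(candidates, termseq_tracks, config)
    labels, accuracy = train_and_call(
        (X, y), np.array([c.features for c in candidates]),
        k=config.knn_k, cv_fraction=config.cv_fraction,
        cv_reps=config.cv_reps, seed=config.rng_seed)
    for cand, label in zip(candidates, labels):
        cand.label = bool(label)
    called = [c for c in candidates if c.label]
    teps = _merge_union(called, config.replicate_tolerance)
    sizes = {"positives": int(y.sum()), "negatives": int((y == 0).sum()),
             "candidates": len(candidates)}
    log.info("called %d TEPs from %d candidates (cv accuracy %s)",
             len(teps), len(candidates), accuracy)
    return teps, accuracy, sizes


# ---------------------------------------------------------------------------
# categorization


def categorize_teps(teps: Sequence[Tep], genes: Sequence[GeneModel],
                    tss_set: Sequence[Tss], config: PipelineConfig) -> None:
    """Assign P/S/Pre/A/N/Internal categories in precedence order.

    Internal (inside a same-strand CDS) takes precedence, then association
    with the nearest same-strand gene whose stop lies within the downstream
    window (highest count per gene is P, the rest S), then premature (between
    primary TSS + offset and the start codon), then antisense (inside an
    opposite-strand CDS), then intergenic.
    """
    W = config.downstream_assoc_window
    by_cs: Dict[Tuple[str, str], List[GeneModel]] = {}
    for g in genes:
        by_cs.setdefault((g.contig, g.strand), []).append(g)
    primary_tss = [t for t in tss_set if t.category == "primary" and t.gene_id]
    genes_by_id = {g.gene_id: g for g in genes}

    def inside_cds(contig: str, strand: str, pos: int) -> bool:
        return any(g.cds_start <= pos < g.cds_end
                   for g in by_cs.get((contig, strand), []))

    def downstream_gene(tep: Tep) -> Optional[GeneModel]:
        best, best_d = None, None
        for g in by_cs.get((tep.contig, tep.strand), []):
            if g.strand == "+":
                d = tep.position - g.cds_end
            else:
                d = g.cds_start - 1 - tep.position
            if 0 <= d < W and (best_d is None or d < best_d):
                best, best_d = g, d
        return best

    def is_premature(tep: Tep) -> bool:
        for tss in primary_tss:
            gene = genes_by_id.get(tss.gene_id)
            if gene is None or tss.contig != tep.contig or tss.strand != tep.strand:
                continue
            off = (tep.position - tss.position if tep.strand == "+"
                   else tss.position - tep.position)
            if off < config.premature_offset:
                continue
            before_start = (tep.position < gene.cds_start if tep.strand == "+"
                            else tep.position >= gene.cds_end)
            if before_start:
                return True
        return False

    per_gene: Dict[str, List[Tep]] = {}
    for tep in teps:
        if tep.contig not in {g.contig for g in genes} | {t.contig for t in tss_set}:
            raise ValueError(f"TEP on unknown contig {tep.contig!r}")
        if inside_cds(tep.contig, tep.strand, tep.position):
            tep.category = "Internal"
            continue
        gene = downstream_gene(tep)
        if gene is not None:
            tep.gene_id = gene.gene_id
            per_gene.setdefault(gene.gene_id, []).append(tep)
            continue
        if is_premature(tep):
            tep.category = "Pre"
        elif inside_cds(tep.contig, "-" if tep.strand == "+" else "+",
                        tep.position):
            tep.category = "A"
        else:
            tep.category = "N"

    for gene_id, group in per_gene.items():
        best = max(group, key=lambda t: (t.count,
                                         -t.position if t.strand == "+" else t.position))
        for tep in group:
            tep.category = "P" if tep is best else "S"
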