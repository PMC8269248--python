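"""Normalized coverage statistics around 3'-end positions.

Read-through fraction uses equal-length 300-nt flanks in transcript
orientation: the upstream flank is offsets -(flank-1)..0 (the TEP base belongs
to the upstream sum only) and the downstream flank is offsets +1..+flank, so a
flat track yields exactly 1.0 and a clean step from depth a to depth b yields
exactly b/a. Per-phase fractions are averaged arithmetically; records with
zero upstream signal are flagged and excluded from distribution summaries.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import GeneModel, Tep, Track, Tu


class NormalizationError(ValueError):
    pass


def normalize_rpm(track: Track) -> Track:
    """Scale every position by 1e6 / total signal (reads per million)."""
    total = track.total()
    if total <= 0:
        raise NormalizationError("cannot RPM-normalize an all-zero track")
    return track.scaled(1e6 / total)


def _flanks(arr: np.ndarray, position: int, strand: str,
            flank: int) -> Tuple[np.ndarray, np.ndarray, bool]:
    """Upstream/downstream flank slices in transcript orientation.

    Windows clipped at a contig edge are shortened symmetrically so both
    flanks keep equal length; the caller flags such records.
    """
    n = len(arr)
    if strand == "+":
        avail = min(flank, position + 1, n - 1 - position)
    else:
        avail = min(flank, n - position, position)
    clipped = avail < flank
    f = max(avail, 0)
    if f == 0:
        return np.zeros(0), np.zeros(0), True
    if strand == "+":
        up = arr[position - f + 1: position + 1]
        down = arr[position + 1: position + 1 + f]
    else:
        up = arr[position: position + f]
        down = arr[position - f: position]
    return up, down, clipped


def readthrough_fraction(tep: Tep, coverage: Dict[str, Track],
                         flank: int = 300) -> Optional[float]:
    """Mean over growth phases of downstream-flank / upstream-flank sums.

    Returns ``None`` (and flags the record) when the upstream sum is zero in
    every phase.
    """
    fractions = []
    for track in coverage.values():
        arr = track[(tep.contig, tep.strand)]
        up, down, clipped = _flanks(arr, tep.position, tep.strand, flank)
        if clipped:
            tep.flagged = True
        up_sum = float(up.sum())
        if up_sum <= 0:
            tep.flagged = True
            continue
        fractions.append(float(down.sum()) / up_sum)
    if not fractions:
        tep.flagged = True
        return None
    return float(np.mean(fractions))


def density_profile(teps: Sequence[Tep], coverage: Dict[str, Track],
                    flank: int = 300) -> np.ndarray:
    """Max-normalized mean coverage profile over offsets -flank..+flank.

    Per TEP and phase the window is scaled so its maximum is 1; windows are
    summed across TEPs, each phase profile is normalized to sum to 1, and the
    phase profiles are averaged (so the result also sums to 1). TEP windows
    with all-zero coverage are skipped.
    """
    if not teps:
        raise ValueError("density_profile needs a nonempty TEP set")
    width = 2 * flank + 1
    phase_profiles = []
    skipped = 0
    for track in coverage.values():
        acc = np.zeros(width)
        for tep in teps:
            arr = track[(tep.contig, tep.strand)]
            lo, hi = tep.position - flank, tep.position + flank + 1
            if lo < 0 or hi > len(arr):
                skipped += 1
                continue
            win = arr[lo:hi]
            if tep.strand == "-":
                win = win[::-1]
            m = win.max()
            if m <= 0:
                skipped += 1
                continue
            acc += win / m
        total = acc.sum()
        if total > 0:
            phase_profiles.append(acc / total)
    if not phase_profiles:
        raise ValueError("no usable TEP windows for density profile")
    return np.mean(phase_profiles, axis=0)


def rpkm(count_sum: float, length: int, library_total: float) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if length <= 0:
        raise ValueError("feature length must be positive")
    if library_total <= 0:
        raise ValueError("library total must be positive")
    return count_sum / ((length / 1e3) * (library_total / 1e6))


def feature_rpkm(track: Track, contig: str, strand: str, start: int, end: int,
                 library_total: Optional[float] = None) -> float:
    arr = track[(contig, strand)]
    total = library_total if library_total is not None else track.total()
    return rpkm(float(arr[start:end].sum()), end - start, total)


def premature_ratio(premature_tu: Tu, cds: GeneModel,
                    tracks: Dict[str, Track]) -> Dict[str, object]:
    """Per-phase RPKM(downstream CDS) / RPKM(premature TU), with summaries.

    Reports the minimum ratio over phases and the population standard
    deviation of the log2 ratios; phases where the premature TU has zero
    signal are skipped and flagged.
    """
    ratios: Dict[str, float] = {}
    skipped: List[str] = []
    for phase, track in tracks.items():
        total = track.total()
        tu_val = feature_rpkm(track, premature_tu.contig, premature_tu.strand,
                              premature_tu.start, premature_tu.end, total)
        cds_val = feature_rpkm(track, cds.contig, cds.strand,
                               cds.cds_start, cds.cds_end, total)
        if tu_val <= 0:
            skipped.append(phase)
            continue
        ratios[phase] = cds_val / tu_val
    logs = np.log2(np.array([r for r in ratios.values() if r > 0]))
    return {
        "ratios": ratios,
        "min_ratio": min(ratios.values()) if ratios else None,
        "log2_sd": float(np.std(logs)) if logs.size else None,
        "skipped_phases": skipped,
    }


def trimmed_distribution_summary(values: Sequence[float],
                                 trim: float = 0.05) -> Dict[str, float]:
    """Median/quartile summary after discarding the largest ``trim`` fraction."""
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0:
        raise ValueError("empty value set")
    k = int(np.floor(x.size * trim))
    kept = x[: x.size - k] if k else x
    q1, med, q3 = np.percentile(kept, [25, 50, 75])
    return {"n": int(kept.size), "n_discarded": int(k), "median": float(med),
            "q1": float(q1), "q3": float(q3), "mean": float(kept.mean())}
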