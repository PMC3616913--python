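"""Peak calling on processed tracks and between-experiment comparison.

A peak is a local maximum of the smoothed signal above a calling threshold;
experiments are compared by one-to-one summit matching (common-peak counts)
and by the Pearson correlation of their processed profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .track import FeatureSet, ProbeTrack

__all__ = [
    "Peak",
    "OverlapReport",
    "call_peaks",
    "match_peaks",
    "profile_correlation",
    "distance_to_nearest",
]


@dataclass(frozen=True)
class Peak:
    """A called local enrichment: summit probe position, height, strength rank."""

    chrom: str
    summit: int
    height: float
    rank: int = 0


@dataclass(frozen=True)
class OverlapReport:
    """Common-peak counts and profile correlation between two experiments."""

    n_a: int
    n_b: int
    n_common: int
    pcorr: float | None = None

    @property
    def fraction_of_a(self) -> float:
        return self.n_common / self.n_a if self.n_a else float("nan")


def _plateau_maxima(pos: np.ndarray, val: np.ndarray) -> list[tuple[int, float]]:
    """Local maxima with plateau tie-break: one summit at each maximal run's
    midpoint probe. A run spanning the whole chromosome (flat signal) yields
    no peak; a run at a chromosome end counts if it beats its one neighbor."""
    n = val.size
    if n == 0:
        return []
    out = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and val[j + 1] == val[i]:
            j += 1
        left_lower = i > 0 and val[i - 1] < val[i]
        right_lower = j < n - 1 and val[j + 1] < val[i]
        interior = i > 0 and j < n - 1
        if (interior and left_lower and right_lower) or (
            not interior
            and (i > 0 or j < n - 1)  # not the whole chromosome
            and (left_lower or i == 0)
            and (right_lower or j == n - 1)
        ):
            mid = (i + j) // 2
            out.append((int(pos[mid]), float(val[mid])))
        i = j + 1
    return out


def call_peaks(
    track: ProbeTrack, threshold: float = 2.0, min_separation: float = 2000
) -> list[Peak]:
    """All local maxima with height >= *threshold*, merged within *min_separation*.

    Maxima closer than ``min_separation`` bp on the same chromosome are
    merged keeping the higher summit. The default threshold of 2.0 sits well
    above the ~1 background of a decile-normalized track. Output is ranked
    1..k by descending height; height ties break by chromosome order then
    position, so ranking is deterministic.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not track.has_flag("smoothed"):
        warnings.warn("calling peaks on an unsmoothed track", stacklevel=2)
    chrom_order = {c: k for k, c in enumerate(track.chromosomes)}
    candidates: list[Peak] = []
    for chrom, (pos, val) in track.data.items():
        for summit, height in _plateau_maxima(pos, val):
            if height >= threshold:
                candidates.append(Peak(chrom, summit, height))
    # merge: strongest first; drop any candidate within min_separation of a keeper
    candidates.sort(key=lambda p: (-p.height, chrom_order[p.chrom], p.summit))
    kept: list[Peak] = []
    kept_by_chrom: dict[str, list[int]] = {}
    for p in candidates:
        near = kept_by_chrom.get(p.chrom, [])
        if all(abs(p.summit - s) >= min_separation for s in near):
            kept.append(p)
            kept_by_chrom.setdefault(p.chrom, []).append(p.summit)
    return [
        Peak(p.chrom, p.summit, p.height, rank=i + 1) for i, p in enumerate(kept)
    ]


def match_peaks(
    a: list[Peak], b: list[Peak], match_dist: float = 2000
) -> tuple[list[tuple[Peak, Peak]], OverlapReport]:
    """Greedy nearest-first one-to-one matching of summits within *match_dist* bp.

    Candidate same-chromosome pairs are taken closest-first; each peak can be
    used once. The common count is symmetric: swapping the lists changes the
    pair order, never the number of matches.
    """
    if match_dist <= 0:
        raise ValueError("match_dist must be positive")
    cands = [
        (abs(pa.summit - pb.summit), pa.chrom, pa.summit, pb.summit, i, j)
        for i, pa in enumerate(a)
        for j, pb in enumerate(b)
        if pa.chrom == pb.chrom and abs(pa.summit - pb.summit) <= match_dist
    ]
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[Peak, Peak]] = []
    for _, _, _, _, i, j in cands:
        if i not in used_a and j not in used_b:
            used_a.add(i)
            used_b.add(j)
            pairs.append((a[i], b[j]))
    return pairs, OverlapReport(n_a=len(a), n_b=len(b), n_common=len(pairs))


def profile_correlation(a: ProbeTrack, b: ProbeTrack) -> float:
    """Pearson r between two processed tracks on their common probe grid."""
    xs, ys = [], []
    for chrom in a.chromosomes:
        if chrom not in b.data:
            continue
        pa, va = a.data[chrom]
        pb, vb = b.data[chrom]
        common, ia, ib = np.intersect1d(pa, pb, return_indices=True)
        if common.size:
            xs.append(va[ia])
            ys.append(vb[ib])
    if not xs or sum(x.size for x in xs) < 3:
        raise ValueError("fewer than 3 common probes between tracks")
    r = stats.pearsonr(np.concatenate(xs), np.concatenate(ys)).statistic
    return float(r)


def distance_to_nearest(peaks: list[Peak], features: FeatureSet) -> np.ndarray:
    """Per peak, the distance (bp) to the nearest same-chromosome feature.

    Peaks on chromosomes carrying no feature get ``inf``.
    """
    by_chrom = {c: np.sort(features.positions(c)) for c in features.chromosomes}
    out = np.full(len(peaks), np.inf)
    for k, p in enumerate(peaks):
        fpos = by_chrom.get(p.chrom)
        if fpos is None or fpos.size == 0:
            continue
        i = np.searchsorted(fpos, p.summit)
        cands = fpos[max(0, i - 1) : i + 1]
        out[k] = np.min(np.abs(cands - p.summit))
    return out
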