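"""Abundance (EPM) and size-distribution statistics.

Plasma eccDNA shows a bimodal size law with peak clusters near 200 bp and
350 bp.  The two statistics defined on a 1-bp size profile are the area
under the profile within each cluster window (AUC, in percent of all
molecules) and the AUC ratio (second cluster / first cluster) — a single
scalar summarising how long the circles are overall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .model import EccDNARecord

__all__ = [
    "SizeProfile",
    "ClusterAUC",
    "CLUSTER1_WINDOW",
    "CLUSTER2_WINDOW",
    "compute_epm",
    "size_profile",
    "size_profile_from_sizes",
    "pool_profiles",
    "cluster_auc",
    "auc_ratio_from_aucs",
]

CLUSTER1_WINDOW: Tuple[int, int] = (150, 250)  # bp, inclusive on both ends
CLUSTER2_WINDOW: Tuple[int, int] = (300, 450)


@dataclass
class SizeProfile:
    """Per-1-bp size frequency distribution.

    ``counts[i]`` is the number of molecules of size ``lo + i``;
    frequencies are percentages of ``n_molecules``.  Pooling samples is
    adding their count vectors.
    """

    lo: int
    hi: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != self.hi - self.lo + 1:
            raise ValueError("counts length must equal hi - lo + 1")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def n_molecules(self) -> int:
        return int(self.counts.sum())

    @property
    def freq(self) -> np.ndarray:
        """Percent of molecules at each size; all-zero when empty."""
        n = self.n_molecules
        if n == 0:
            return np.zeros_like(self.counts, dtype=float)
        return 100.0 * self.counts / n

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(self.lo, self.hi + 1)

    def freq_at(self, size: int) -> float:
        if not (self.lo <= size <= self.hi):
            return 0.0
        return float(self.freq[size - self.lo])

    def window_auc(self, window: Tuple[int, int]) -> float:
        """Percent of molecules with size in the inclusive window."""
        a = max(window[0], self.lo) - self.lo
        b = min(window[1], self.hi) - self.lo
        if b < a:
            return 0.0
        return float(self.freq[a : b + 1].sum())


@dataclass
class ClusterAUC:
    auc1: float
    auc2: float
    auc_ratio: Optional[float]
    cluster1_window: Tuple[int, int] = CLUSTER1_WINDOW
    cluster2_window: Tuple[int, int] = CLUSTER2_WINDOW

    def __post_init__(self) -> None:
        for v in (self.auc1, self.auc2):
            if not (0.0 <= v <= 100.0 + 1e-9):
                raise ValueError(f"AUC out of [0, 100]: {v}")


def compute_epm(n_eccdna: int, mappable_reads: int) -> float:
    """eccDNA loci per million mappable read pairs."""
    if mappable_reads <= 0:
        raise ValueError("mappable_reads must be positive for EPM")
    return n_eccdna / mappable_reads * 1e6


def size_profile_from_sizes(
    sizes: Sequence[int], lo: int = 0, hi: int = 1000
) -> SizeProfile:
    sizes = np.asarray(sizes, dtype=np.int64)
    in_range = sizes[(sizes >= lo) & (sizes <= hi)]
    counts = np.bincount(in_range - lo, minlength=hi - lo + 1)
    return SizeProfile(lo=lo, hi=hi, counts=counts)


def size_profile(
    records: Iterable[EccDNARecord], lo: int = 0, hi: int = 1000
) -> SizeProfile:
    """Profile of record sizes; molecules outside [lo, hi] are excluded
    from numerator and denominator alike."""
    return size_profile_from_sizes([r.size for r in records], lo=lo, hi=hi)


def pool_profiles(profiles: Sequence[SizeProfile]) -> SizeProfile:
    if not profiles:
        raise ValueError("no profiles to pool")
    lo, hi = profiles[0].lo, profiles[0].hi
    if any(p.lo != lo or p.hi != hi for p in profiles):
        raise ValueError("profiles must share a size range to pool")
    return SizeProfile(lo=lo, hi=hi, counts=sum(p.counts for p in profiles))


def auc_ratio_from_aucs(auc1: float, auc2: float) -> Optional[float]:
    """Second-cluster AUC over first-cluster AUC; None when undefined."""
    if auc1 <= 0:
        return None
    return auc2 / auc1


def cluster_auc(
    profile: SizeProfile,
    cluster1_window: Tuple[int, int] = CLUSTER1_WINDOW,
    cluster2_window: Tuple[int, int] = CLUSTER2_WINDOW,
) -> ClusterAUC:
    """AUC of the two peak-cluster windows and their ratio.

    Windows are inclusive on both ends; the gap between them belongs to
    neither, so auc1 + auc2 < 100 in general.  An empty first cluster makes
    the ratio undefined (None), never infinity.
    """
    auc1 = profile.window_auc(cluster1_window)
    auc2 = profile.window_auc(cluster2_window)
    return ClusterAUC(
        auc1=auc1,
        auc2=auc2,
        auc_ratio=auc_ratio_from_aucs(auc1, auc2),
        cluster1_window=cluster1_window,
        cluster2_window=cluster2_window,
    )
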