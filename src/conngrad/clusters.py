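"""Hard-cluster extraction from the ends of the reordered matrix.

The original method picks cluster extents by eye; here the extents are an
explicit, logged input (``extract_cluster_range``) with a deterministic
advisory helper (``suggest_end_clusters``) for locating coherent blocks at
the matrix ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grids import BinaryMask, SeedROI
from .roi_geometry import FingerprintSet
from .spectral import ReorderingResult

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Cluster:
    label: str
    start: int  # 1-based inclusive rank range on the reordered axis
    stop: int
    member_rows: np.ndarray  # original seed indices (rows of the unordered matrix)
    member_voxels: np.ndarray  # (k, 3) voxel indices


@dataclass(frozen=True)
class ClusterSet:
    roi: SeedROI
    clusters: tuple[Cluster, ...]

    def __iter__(self):
        return iter(self.clusters)

    def __len__(self) -> int:
        return len(self.clusters)

    def mask(self, label: str) -> BinaryMask:
        """0/1 mask volume for one cluster."""
        for c in self.clusters:
            if c.label == label:
                vol = np.zeros(self.roi.grid.shape, dtype=bool)
                vol[tuple(c.member_voxels.T)] = True
                return BinaryMask(self.roi.grid, vol)
        raise KeyError(f"no cluster labelled {label!r}")


def extract_cluster_range(
    res: ReorderingResult,
    roi: SeedROI,
    ranges: list[tuple[str, int, int]],
) -> ClusterSet:
    """Seeds whose reordered rank falls in each [a, b] range (1-based, inclusive)."""
    n = res.n
    if len(roi) != n:
        raise ValueError(f"ROI has {len(roi)} seeds but result has {n}")
    seen: list[tuple[int, int]] = []
    clusters = []
    for label, a, b in ranges:
        a, b = int(a), int(b)
        if not (1 <= a <= b <= n):
            raise ValueError(f"range {label!r}=[{a},{b}] invalid for n={n} (empty or out of bounds)")
        for pa, pb in seen:
            if a <= pb and pa <= b:
                raise ValueError(f"range {label!r}=[{a},{b}] overlaps [{pa},{pb}]")
        seen.append((a, b))
        member_rows = np.flatnonzero((res.permutation >= a) & (res.permutation <= b))
        logger.info("cluster %r: ranks %d-%d, %d voxels", label, a, b, len(member_rows))
        clusters.append(
            Cluster(
                label=label,
                start=a,
                stop=b,
                member_rows=member_rows,
                member_voxels=roi.voxels[member_rows],
            )
        )
    return ClusterSet(roi=roi, clusters=tuple(clusters))


def suggest_end_clusters(
    sim_reordered: np.ndarray,
    min_size: int = 5,
    coherence_quantile: float = 0.75,
) -> list[tuple[str, int, int]]:
    """Advisory candidate ranges at the two matrix ends.

    Returns the largest prefix [1, k] and suffix [m, n] that are coherent
    against the ``coherence_quantile`` quantile of all off-diagonal values:
    the seed block of ``min_size`` must beat the threshold in mean, and the
    range grows while each added rank's mean similarity to the range stays
    above it.  Advisory only; never applied without confirmation.
    """
    s = np.asarray(sim_reordered, dtype=float)
    n = s.shape[0]
    if min_size < 2 or min_size > n:
        return []
    off = ~np.eye(n, dtype=bool)
    thresh = np.quantile(s[off], coherence_quantile)

    def block_mean(a: int, b: int) -> float:  # 0-based half-open
        blk = s[a:b, a:b]
        m = ~np.eye(b - a, dtype=bool)
        return float(blk[m].mean())

    def grow_prefix() -> int:
        if block_mean(0, min_size) <= thresh:
            return 0
        k = min_size
        while k < n and s[k, :k].mean() > thresh:
            k += 1
        return k

    def grow_suffix() -> int:
        if block_mean(n - min_size, n) <= thresh:
            return 0
        m = n - min_size
        while m > 0 and s[m - 1, m:].mean() > thresh:
            m -= 1
        return n - m

    out: list[tuple[str, int, int]] = []
    k = grow_prefix()
    if k:
        out.append(("prefix", 1, k))
    ksuf = grow_suffix()
    if ksuf:
        m0 = n - ksuf + 1
        if not (out and m0 <= out[0][2]):  # avoid overlapping the prefix
            out.append(("suffix", m0, n))
    return out


def cluster_structural_map(
    cluster: Cluster, fp: FingerprintSet, floor: float = 5.0
) -> np.ndarray:
    """Mean of the member seeds' count profiles, floored at ``floor`` streamlines.

    ``fp`` must be a group_mean_counts fingerprint set; values below the
    floor (>= comparator) are zeroed.  Returns a flat target-space vector;
    reshape with ``fp.row_volume`` semantics or the attached target grid.
    """
    if fp.kind != "group_mean_counts":
        raise ValueError(f"fingerprints must be group_mean_counts, got {fp.kind!r}")
    if cluster.member_rows.max(initial=-1) >= fp.n_seeds or len(cluster.member_rows) == 0:
        missing = [int(r) for r in cluster.member_rows if r >= fp.n_seeds]
        raise ValueError(f"cluster members missing from fingerprint rows: {missing}")
    mean_map = fp.values[cluster.member_rows].mean(axis=0)
    mean_map = np.where(mean_map >= floor, mean_map, 0.0)
    return mean_map
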