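"""Seed-ROI construction and group fingerprint assembly.

The seed region is the gray/white interface: white-matter voxels with at
least one non-white neighbor, away from (dilated) CSF.  Per-participant
streamline-count maps are thresholded, downsampled, binarized and averaged
into group fingerprint rows, one per seed voxel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import BinaryMask, SeedROI, VolumeGrid, check_same_grid

logger = logging.getLogger(__name__)

#: map connectivity (face / face+edge / face+edge+corner) to ndimage structure rank
_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}

FINGERPRINT_KINDS = ("native_counts", "group_proportion", "group_mean_counts")


@dataclass(frozen=True)
class FingerprintSet:
    """seeds x targets nonnegative connectivity profiles.

    ``targets`` records flattened target-voxel indices (C order) on the
    target grid so rows can be rebuilt into volumes.
    """

    roi: SeedROI
    targets: np.ndarray  # (t,) flat indices into the target grid
    values: np.ndarray  # (n_seeds, t)
    kind: str
    target_grid: VolumeGrid | None = field(default=None)

    def __post_init__(self) -> None:
        if self.kind not in FINGERPRINT_KINDS:
            raise ValueError(f"kind must be one of {FINGERPRINT_KINDS}, got {self.kind!r}")
        values = np.asarray(self.values, dtype=float)
        targets = np.asarray(self.targets, dtype=np.int64)
        if values.ndim != 2:
            raise ValueError("values must be 2D (seeds x targets)")
        if values.shape[0] != len(self.roi):
            raise ValueError(
                f"row count {values.shape[0]} != number of seeds {len(self.roi)}"
            )
        if values.shape[1] != len(targets):
            raise ValueError("values column count != number of targets")
        if not np.isfinite(values).all():
            raise ValueError("fingerprint values must be finite")
        if (values < 0).any():
            raise ValueError("fingerprint values must be nonnegative")
        if self.kind == "group_proportion" and (values > 1 + 1e-12).any():
            raise ValueError("group_proportion values must be <= 1")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "targets", targets)

    @property
    def n_seeds(self) -> int:
        return self.values.shape[0]

    @property
    def n_targets(self) -> int:
        return self.values.shape[1]

    def row_volume(self, row: int) -> np.ndarray:
        """Rebuild one seed's profile as a dense volume on the target grid."""
        if self.target_grid is None:
            raise ValueError("FingerprintSet has no target grid attached")
        vol = np.zeros(int(np.prod(self.target_grid.shape)))
        vol[self.targets] = self.values[row]
        return vol.reshape(self.target_grid.shape)


def _structure(connectivity: int) -> np.ndarray:
    try:
        rank = _CONNECTIVITY_RANK[connectivity]
    except KeyError:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}") from None
    return ndimage.generate_binary_structure(3, rank)


def extract_gw_interface(
    white: BinaryMask,
    csf: BinaryMask,
    dilation_radius_voxels: int = 1,
    connectivity: int = 6,
) -> BinaryMask:
    """White-matter voxels bordering non-white tissue, excluding dilated CSF.

    Out-of-volume neighbors count as non-white, so voxels on the volume
    faces can be interface.  The CSF mask is dilated by
    ``dilation_radius_voxels`` (same connectivity) and any overlap removed.
    """
    check_same_grid(white.grid, csf.grid, "white and CSF masks")
    if dilation_radius_voxels < 0:
        raise ValueError("dilation_radius_voxels must be >= 0")
    struct = _structure(connectivity)

    if not white.values.any():
        warnings.warn("white-matter mask is empty; interface is empty", stacklevel=2)
        return BinaryMask(white.grid, np.zeros(white.grid.shape, dtype=bool))

    # border_value=0: voxels touching the volume edge survive as interface
    eroded = ndimage.binary_erosion(white.values, structure=struct, border_value=0)
    interface = white.values & ~eroded

    if dilation_radius_voxels > 0 and csf.values.any():
        dilated = ndimage.binary_dilation(
            csf.values, structure=struct, iterations=dilation_radius_voxels
        )
        interface &= ~dilated
    return BinaryMask(white.grid, interface)


def build_seed_roi(roi_mask: BinaryMask, interface: BinaryMask) -> SeedROI:
    """Intersect the region mask with the interface; order lexicographically."""
    check_same_grid(roi_mask.grid, interface.grid, "ROI mask and interface")
    both = roi_mask.values & interface.values
    if not both.any():
        raise ValueError("ROI mask and gray/white interface do not intersect")
    return SeedROI(roi_mask.grid, np.argwhere(both))


def prepare_native_map(
    counts: np.ndarray,
    native_threshold: float = 5,
    downsample_factor: int = 2,
    binarize_threshold: float = 5,
) -> np.ndarray:
    """Threshold, block-downsample and binarize one streamline-count map.

    Stage 1 zeroes voxels with count <= ``native_threshold`` (strict >).
    Stage 2 block-averages each ``downsample_factor``^3 block (zero-padding
    dimensions that do not divide evenly).  Stage 3 binarizes block means at
    >= ``binarize_threshold``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 3:
        raise ValueError("counts must be a 3D volume")
    if not np.isfinite(counts).all() or (counts < 0).any():
        raise ValueError("counts must be finite and nonnegative")
    if downsample_factor < 1:
        raise ValueError("downsample_factor must be >= 1")

    kept = np.where(counts > native_threshold, counts, 0.0)

    f = int(downsample_factor)
    if f > 1:
        pads = [(0, (-s) % f) for s in kept.shape]
        if any(p[1] for p in pads):
            logger.info("padding volume %s with zeros to divide by %d", kept.shape, f)
            kept = np.pad(kept, pads)
        s = kept.shape
        blocks = kept.reshape(s[0] // f, f, s[1] // f, f, s[2] // f, f)
        kept = blocks.mean(axis=(1, 3, 5))

    return (kept >= binarize_threshold).astype(np.uint8)


def downsample_roi(roi: SeedROI, factor: int = 2) -> VolumeGrid:
    """Grid of the downsampled target space matching :func:`prepare_native_map`."""
    f = int(factor)
    shape = tuple(-(-s // f) for s in roi.grid.shape)
    affine = roi.grid.affine.copy()
    affine[:3, :3] *= f
    return VolumeGrid(shape, affine)


def build_group_fingerprints(
    per_participant: list[tuple[SeedROI, np.ndarray]],
    template: SeedROI,
    mode: str = "group_proportion",
    max_distance_mm: float = np.inf,
    target_grid: VolumeGrid | None = None,
    targets: np.ndarray | None = None,
) -> FingerprintSet:
    """Project individual seed maps onto the template ROI and average.

    Each participant supplies ``(roi, values)`` with one map row per own
    seed voxel.  Every template seed is matched to that participant's
    nearest seed in mm; several own seeds tying for (or mapping to) one
    template seed have their rows averaged first, so each participant
    contributes exactly one row per template seed.

    ``group_proportion`` expects binarized rows (averaging gives the
    proportion of participants with the connection); ``group_mean_counts``
    averages raw count rows.  Template seeds with no individual seed within
    ``max_distance_mm`` for some participant are dropped (logged).
    """
    if mode not in ("group_proportion", "group_mean_counts"):
        raise ValueError(f"mode must be group_proportion or group_mean_counts, got {mode!r}")
    if not per_participant:
        raise ValueError("need at least one participant")

    n_template = len(template)
    tmpl_mm = template.mm_coordinates()
    n_targets = per_participant[0][1].shape[1]

    accum = np.zeros((n_template, n_targets))
    valid = np.ones(n_template, dtype=bool)

    for p_idx, (roi, values) in enumerate(per_participant):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(roi), n_targets):
            raise ValueError(
                f"participant {p_idx}: values shape {values.shape} != "
                f"({len(roi)}, {n_targets})"
            )
        own_mm = roi.mm_coordinates()
        # (template, own) pairwise distances; template seeds are few enough
        # that the dense matrix is fine
        d = np.linalg.norm(tmpl_mm[:, None, :] - own_mm[None, :, :], axis=2)
        contrib = np.zeros((n_template, n_targets))
        for t in range(n_template):
            dmin = d[t].min()
            if dmin > max_distance_mm:
                if valid[t]:
                    logger.warning(
                        "template seed %d has no seed within %.1f mm for "
                        "participant %d; row dropped",
                        t,
                        max_distance_mm,
                        p_idx,
                    )
                valid[t] = False
                continue
            ties = np.flatnonzero(np.isclose(d[t], dmin))
            contrib[t] = values[ties].mean(axis=0)
        accum += contrib

    if not valid.all():
        kept = np.flatnonzero(valid)
        logger.warning("%d template seeds dropped (no match)", n_template - len(kept))
        roi_out = SeedROI(template.grid, template.voxels[kept])
        accum = accum[kept]
    else:
        roi_out = template

    group = accum / len(per_participant)
    if targets is None:
        targets = np.arange(n_targets)
    return FingerprintSet(roi_out, targets, group, kind=mode, target_grid=target_grid)
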