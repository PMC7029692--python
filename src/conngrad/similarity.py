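"""Voxel-by-voxel similarity matrices.

Structural profiles use plain cosine similarity (nonnegative fingerprints
give entries in [0, 1]).  fMRI time series use cosine + 1 so every entry is
nonnegative (range [0, 2]), as spectral reordering requires.  Individual
matrices are pooled by moment-standardizing the off-diagonal entries, averaging,
and mapping back to the similarity scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .grids import SeedROI
from .roi_geometry import FingerprintSet

logger = logging.getLogger(__name__)

SIMILARITY_MODES = ("structural_cosine", "functional_shifted_cosine", "group_averaged")

#: diagonal self-similarity per construction recipe
SELF_SIMILARITY = {"structural_cosine": 1.0, "functional_shifted_cosine": 2.0}


@dataclass(frozen=True)
class TimeSeriesSet:
    """voxels x timepoints series for the seed ROI."""

    roi: SeedROI
    series: np.ndarray
    tr_seconds: float = 2.8
    censor: np.ndarray | None = None

    def __post_init__(self) -> None:
        series = np.asarray(self.series, dtype=float)
        if series.ndim != 2:
            raise ValueError("series must be 2D (voxels x timepoints)")
        if series.shape[0] != len(self.roi):
            raise ValueError(
                f"series row count {series.shape[0]} != number of seeds {len(self.roi)}"
            )
        if not np.isfinite(series).all():
            raise ValueError("series contain non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.censor is not None:
            censor = np.asarray(self.censor, dtype=bool)
            if censor.shape != (series.shape[1],):
                raise ValueError("censor length must equal number of timepoints")
            object.__setattr__(self, "censor", censor)
        object.__setattr__(self, "series", series)

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[1]


@dataclass(frozen=True)
class SimilarityMatrix:
    roi: SeedROI
    values: np.ndarray
    mode: str
    self_similarity: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mode not in SIMILARITY_MODES:
            raise ValueError(f"mode must be one of {SIMILARITY_MODES}, got {self.mode!r}")
        values = np.asarray(self.values, dtype=float)
        n = len(self.roi)
        if values.shape != (n, n):
            raise ValueError(f"values must be {n}x{n}, got {values.shape}")
        if not np.isfinite(values).all():
            raise ValueError("similarity values must be finite")
        if np.abs(values - values.T).max() > 1e-10:
            raise ValueError("similarity matrix is not symmetric (tol 1e-10)")
        values = (values + values.T) / 2.0
        values.flags.writeable = False
        object.__setattr__(self, "values", values)
        if self.self_similarity is None:
            object.__setattr__(
                self, "self_similarity", SELF_SIMILARITY.get(self.mode, float(values[0, 0]))
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _cosine_rows(rows: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(rows, axis=1)
    unit = rows / norms[:, None]
    cos = unit @ unit.T
    np.fill_diagonal(cos, 1.0)
    return np.clip(cos, -1.0, 1.0)


def cosine_similarity_matrix(fp: FingerprintSet) -> SimilarityMatrix:
    """Cosine of the angle between each pair of fingerprint rows.

    Zero-norm rows (seeds with no surviving connections) are dropped with a
    warning; the returned ROI reflects the retained seeds.
    """
    rows = fp.values
    norms = np.linalg.norm(rows, axis=1)
    keep = norms > 0
    roi = fp.roi
    if not keep.all():
        dropped = np.flatnonzero(~keep)
        warnings.warn(
            f"dropping {len(dropped)} zero-norm fingerprint rows (seeds {dropped.tolist()})",
            stacklevel=2,
        )
        if not keep.any():
            raise ValueError("all fingerprint rows have zero norm")
        roi = SeedROI(roi.grid, roi.voxels[keep])
        rows = rows[keep]
    cos = _cosine_rows(rows)
    # nonnegative profiles -> nonnegative cosines; clamp numerical dust
    cos = np.clip(cos, 0.0, 1.0)
    return SimilarityMatrix(roi, cos, mode="structural_cosine")


def shifted_time_series_similarity(ts: TimeSeriesSet, demean: bool = False) -> SimilarityMatrix:
    """Cosine similarity of voxel time series plus one (entries in [0, 2]).

    With ``demean`` the cosine equals the Pearson correlation.  Constant-zero
    series are dropped with a warning.
    """
    series = ts.series
    if ts.censor is not None:
        series = series[:, ~ts.censor]
    if demean:
        series = series - series.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(series, axis=1)
    keep = norms > 0
    roi = ts.roi
    if not keep.all():
        dropped = np.flatnonzero(~keep)
        warnings.warn(
            f"dropping {len(dropped)} constant/zero time series (seeds {dropped.tolist()})",
            stacklevel=2,
        )
        if not keep.any():
            raise ValueError("all series are constant zero")
        roi = SeedROI(roi.grid, roi.voxels[keep])
        series = series[keep]
    shifted = _cosine_rows(series) + 1.0
    return SimilarityMatrix(roi, shifted, mode="functional_shifted_cosine")


def _offdiag_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


def group_average_similarity(mats: list[SimilarityMatrix]) -> SimilarityMatrix:
    """Pool individual similarity matrices into one group matrix.

    Off-diagonal entries of each matrix are standardized (subtract that
    matrix's off-diagonal mean, divide by its off-diagonal SD), the
    standardized matrices are averaged, and the average is mapped back to
    the similarity scale with the mean of the participant SDs and means.
    Participants with zero off-diagonal SD are excluded (logged).
    """
    if len(mats) < 1:
        raise ValueError("need at least one similarity matrix")
    ref = mats[0]
    for m in mats[1:]:
        if not m.roi.same_as(ref.roi):
            raise ValueError("all matrices must share one SeedROI")
        if m.mode != ref.mode:
            raise ValueError(f"mixed similarity modes: {ref.mode!r} vs {m.mode!r}")

    n = ref.n
    off = _offdiag_mask(n)
    zs, means, sds = [], [], []
    for idx, m in enumerate(mats):
        vals = m.values[off]
        mu, sd = vals.mean(), vals.std()
        if sd == 0:
            logger.warning("participant %d has zero off-diagonal SD; excluded", idx)
            continue
        zs.append((m.values - mu) / sd)
        means.append(mu)
        sds.append(sd)
    if not zs:
        raise ValueError("no participant matrix has nonzero off-diagonal variance")

    avg_z = np.mean(zs, axis=0)
    out = avg_z * np.mean(sds) + np.mean(means)
    np.fill_diagonal(out, ref.self_similarity)
    return SimilarityMatrix(
        ref.roi, out, mode="group_averaged", self_similarity=ref.self_similarity
    )
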