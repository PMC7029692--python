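"""Resting-state QC, nuisance regression, seed maps and group statistics.

QC rules: a timepoint is an artifact if the framewise translation change
exceeds 1 mm (any axis) or the global signal deviates by more than 2.5 SD;
a run is excluded if fewer than 300 s survive scrubbing or any single
translation exceeds 3 mm.  Scrubbed timepoints are regressed out via spike
indicator covariates rather than deleted.

Cluster-level family-wise error is controlled by sign-flipping permutation
with a max-cluster-size statistic (replacing parametric random-field
correction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .grids import BinaryMask
from .similarity import TimeSeriesSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MotionParams:
    """timepoints x 6: three translations (mm) then three rotations (degrees)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] != 6:
            raise ValueError(f"motion parameters must be (t, 6), got {values.shape}")
        if not np.isfinite(values).all():
            raise ValueError("motion parameters contain non-finite values")
        object.__setattr__(self, "values", values)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.values[:, :3]

    @classmethod
    def from_file(cls, path) -> "MotionParams":
        return cls(np.loadtxt(path, ndmin=2))


@dataclass(frozen=True)
class StatMap:
    """Voxelwise t statistics with permutation cluster inference."""

    t_values: np.ndarray  # 3D
    df: int
    voxel_p_threshold: float
    cluster_sig_mask: np.ndarray  # 3D bool
    method: str  # one_sample | paired_difference
    n_permutations: int
    cluster_p_values: tuple[float, ...] = ()


def friston24_expand(mp: MotionParams) -> np.ndarray:
    """Volterra expansion of the six rigid-body parameters to 24 regressors.

    For each parameter p the columns are [p(t), p(t)^2, p(t-1), p(t-1)^2];
    the lagged rows at t=0 are zero.
    """
    p = mp.values
    if p.shape[0] < 2:
        raise ValueError("need at least two timepoints for the lagged terms")
    lag = np.vstack([np.zeros((1, p.shape[1])), p[:-1]])
    cols = []
    for j in range(p.shape[1]):
        cols += [p[:, j], p[:, j] ** 2, lag[:, j], lag[:, j] ** 2]
    return np.column_stack(cols)


def flag_artifact_timepoints(
    mp: MotionParams,
    global_signal: np.ndarray,
    trans_mm: float = 1.0,
    z_thresh: float = 2.5,
    absolute: bool = False,
) -> np.ndarray:
    """Boolean censor vector (True = artifact).

    A timepoint is flagged when its framewise translation change (max
    absolute consecutive difference over the three axes) exceeds
    ``trans_mm``, or the z-scored global signal exceeds ``z_thresh`` in
    magnitude.  ``absolute`` switches the motion criterion to absolute
    translation rather than framewise change.
    """
    g = np.asarray(global_signal, dtype=float)
    if g.shape != (mp.n_timepoints,):
        raise ValueError(
            f"global signal length {g.shape} != motion length {mp.n_timepoints}"
        )
    trans = mp.translations
    if absolute:
        motion_metric = np.abs(trans).max(axis=1)
    else:
        d = np.abs(np.diff(trans, axis=0)).max(axis=1)
        motion_metric = np.concatenate([[0.0], d])
    sd = g.std()
    z = np.zeros_like(g) if sd == 0 else (g - g.mean()) / sd
    return (motion_metric > trans_mm) | (np.abs(z) > z_thresh)


@dataclass(frozen=True)
class ExclusionDecision:
    exclude: bool
    reason: str
    retained_seconds: float


def apply_exclusion_rules(
    censor: np.ndarray,
    tr_seconds: float,
    mp: MotionParams,
    min_seconds: float = 300.0,
    max_single_translation_mm: float = 3.0,
) -> ExclusionDecision:
    """Keep/exclude a run given its censor vector and motion trace."""
    censor = np.asarray(censor, dtype=bool)
    if censor.shape != (mp.n_timepoints,):
        raise ValueError("censor length != motion length")
    retained = float((~censor).sum() * tr_seconds)
    max_trans = float(np.abs(mp.translations).max())
    if max_trans > max_single_translation_mm:
        return ExclusionDecision(
            True,
            f"single translation {max_trans:.2f} mm > {max_single_translation_mm} mm",
            retained,
        )
    if retained < min_seconds:
        return ExclusionDecision(
            True, f"only {retained:.1f} s retained < {min_seconds} s", retained
        )
    return ExclusionDecision(False, "ok", retained)


def build_nuisance_design(
    mp: MotionParams,
    censor: np.ndarray | None = None,
    tissue_signals: np.ndarray | None = None,
    intercept: bool = True,
) -> np.ndarray:
    """Assemble the standard nuisance design: Friston-24 motion, spike
    indicators for censored timepoints, tissue/global signals, intercept."""
    cols = [friston24_expand(mp)]
    if censor is not None:
        censor = np.asarray(censor, dtype=bool)
        for t in np.flatnonzero(censor):
            spike = np.zeros(mp.n_timepoints)
            spike[t] = 1.0
            cols.append(spike[:, None])
    if tissue_signals is not None:
        ts = np.atleast_2d(np.asarray(tissue_signals, float))
        if ts.shape[0] != mp.n_timepoints:
            ts = ts.T
        cols.append(ts)
    if intercept:
        cols.append(np.ones((mp.n_timepoints, 1)))
    return np.column_stack(cols)


def regress_nuisance(ts: TimeSeriesSet, regressors: np.ndarray) -> TimeSeriesSet:
    """OLS residuals of every voxel series against the nuisance design.

    Residuals are orthogonal to every design column to <= 1e-8.  Raises on a
    rank-deficient design, naming the collinear columns.
    """
    X = np.asarray(regressors, dtype=float)
    if X.ndim != 2 or X.shape[0] != ts.n_timepoints:
        raise ValueError(
            f"design shape {X.shape} does not match {ts.n_timepoints} timepoints"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns in the (near-)null space via QR pivoting
        from scipy.linalg import qr

        _, r, piv = qr(X, pivoting=True, mode="economic")
        diag = np.abs(np.diag(r))
        bad = sorted(int(c) for c in piv[diag < diag.max() * 1e-10])
        raise ValueError(f"nuisance design is rank deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, ts.series.T, rcond=None)
    resid = ts.series.T - X @ beta
    return TimeSeriesSet(ts.roi, resid.T, tr_seconds=ts.tr_seconds, censor=ts.censor)


def seed_connectivity_map(
    brain_ts: np.ndarray, cluster_mask: BinaryMask
) -> np.ndarray:
    """Fisher-z map of the mean cluster time series against every voxel.

    ``brain_ts`` is a 4D (x, y, z, t) array on the cluster grid.  r is
    clipped to 1 - 1e-7 in magnitude before atanh; constant voxel series
    get z = 0 (flagged in the log).
    """
    brain_ts = np.asarray(brain_ts, dtype=float)
    if brain_ts.ndim != 4:
        raise ValueError("brain_ts must be 4D (x, y, z, t)")
    if brain_ts.shape[:3] != cluster_mask.grid.shape:
        raise ValueError("brain_ts spatial shape does not match cluster mask grid")
    if not cluster_mask.values.any():
        raise ValueError("cluster mask is empty")

    seed = brain_ts[cluster_mask.values].mean(axis=0)
    seed_c = seed - seed.mean()
    seed_norm = np.linalg.norm(seed_c)
    if seed_norm == 0:
        raise ValueError("cluster mean time series is constant")

    flat = brain_ts.reshape(-1, brain_ts.shape[3])
    flat_c = flat - flat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(flat_c, axis=1)
    constant = norms == 0
    if constant.any():
        logger.warning("%d constant voxel series set to z=0", int(constant.sum()))
    norms[constant] = 1.0
    r = flat_c @ seed_c / (norms * seed_norm)
    r[constant] = 0.0
    r = np.clip(r, -1 + 1e-7, 1 - 1e-7)
    return np.arctanh(r).reshape(brain_ts.shape[:3])


def _t_one_sample(maps: np.ndarray) -> np.ndarray:
    """Vectorized one-sample t over axis 0; zero-variance voxels get t=0."""
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t


def _suprathreshold_clusters(
    t_map: np.ndarray, t_crit: float, structure: np.ndarray
) -> tuple[np.ndarray, list[int]]:
    """Label suprathreshold clusters (positive and negative separately)."""
    labels = np.zeros(t_map.shape, dtype=np.int32)
    sizes: list[int] = []
    next_label = 0
    for signed in (t_map > t_crit, t_map < -t_crit):
        lab, k = ndimage.label(signed, structure=structure)
        for c in range(1, k + 1):
            next_label += 1
            sel = lab == c
            labels[sel] = next_label
            sizes.append(int(sel.sum()))
    return labels, sizes


def _max_cluster_size(t_map: np.ndarray, t_crit: float, structure: np.ndarray) -> int:
    best = 0
    for signed in (t_map > t_crit, t_map < -t_crit):
        lab, k = ndimage.label(signed, structure=structure)
        if k:
            best = max(best, int(np.bincount(lab.ravel())[1:].max()))
    return best


def group_cluster_stats(
    maps_a: np.ndarray,
    maps_b: np.ndarray | None = None,
    voxel_p: float = 0.001,
    cluster_alpha: float = 0.05,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    connectivity: int = 1,
) -> StatMap:
    """One-sample (or paired-difference) t-map with permutation cluster FWE.

    ``maps_a`` (and optionally ``maps_b`` from the same participants) are
    (participants, x, y, z) Fisher-z maps.  Suprathreshold clustering uses a
    two-sided voxel threshold at ``voxel_p``; cluster-level family-wise
    error is controlled by sign-flipping the participant maps ``n_perm``
    times and recording the max cluster size over both signs.
    """
    A = np.asarray(maps_a, dtype=float)
    if A.ndim != 4:
        raise ValueError("maps must be (participants, x, y, z)")
    if maps_b is not None:
        B = np.asarray(maps_b, dtype=float)
        if B.shape != A.shape:
            raise ValueError(
                f"paired test requires equal participant sets/shapes: {A.shape} vs {B.shape}"
            )
        data = A - B
        method = "paired_difference"
    else:
        data = A
        method = "one_sample"
    n = data.shape[0]
    if n < 2:
        raise ValueError("need at least two participants")
    df = n - 1
    t_crit = float(stats.t.ppf(1 - voxel_p / 2, df))
    structure = ndimage.generate_binary_structure(3, connectivity)

    t_obs = _t_one_sample(data)
    labels, sizes = _suprathreshold_clusters(t_obs, t_crit, structure)

    rng = np.random.default_rng(rng)
    flat = data.reshape(n, -1)
    sumsq = (flat**2).sum(axis=0)
    shape3 = data.shape[1:]
    null_max = np.empty(n_perm, dtype=np.int64)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    means = signs @ flat / n
    with np.errstate(divide="ignore", invalid="ignore"):
        var = (sumsq[None, :] - n * means**2) / df
        t_perm = np.where(var > 0, means / np.sqrt(var / n), 0.0)
    for i in range(n_perm):
        null_max[i] = _max_cluster_size(t_perm[i].reshape(shape3), t_crit, structure)

    sig = np.zeros(shape3, dtype=bool)
    p_values = []
    for c, size in enumerate(sizes, start=1):
        p = (1 + int((null_max >= size).sum())) / (n_perm + 1)
        p_values.append(p)
        if p <= cluster_alpha:
            sig |= labels == c
    return StatMap(
        t_values=t_obs,
        df=df,
        voxel_p_threshold=voxel_p,
        cluster_sig_mask=sig,
        method=method,
        n_permutations=n_perm,
        cluster_p_values=tuple(p_values),
    )


def mask_between_by_within(between: StatMap, within: StatMap) -> np.ndarray:
    """Keep between-map significant clusters only where the within-map is
    significant; returns the constrained boolean mask."""
    if between.t_values.shape != within.t_values.shape:
        raise ValueError("stat maps have different shapes")
    return between.cluster_sig_mask & within.cluster_sig_mask
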