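"""Phantom generators with the statistical structure the pipeline assumes.

Each seed voxel carries a planted mixing weight w in [0, 1]; its profile is
a w-weighted blend of two endmember connectivity patterns.  ``graded``
truths ramp w linearly along the seed axis, ``clustered`` truths use a hard
0/1 step, and ``intermediate`` truths interpolate between the two via a
sharpness parameter (s -> 0 step, s = 1 full ramp).  Count maps add Poisson
noise, time series add Gaussian noise; everything is deterministic given
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grids import BinaryMask, SeedROI, VolumeGrid
from .roi_geometry import FingerprintSet
from .similarity import TimeSeriesSet

_JITTER_SD = 0.05  # per-participant jitter of w, truncated to [0, 1]


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth for one synthetic family."""

    n_seeds: int
    mode: str  # graded | clustered | intermediate
    sharpness: float = 1.0  # used by mode=intermediate; 0 -> step, 1 -> ramp
    noise_sd: float = 0.1
    rng_seed: int = 0
    endmember_a: np.ndarray | None = field(default=None)
    endmember_b: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.mode not in ("graded", "clustered", "intermediate"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_seeds < 2:
            raise ValueError("need at least two seeds")
        if not 0 <= self.sharpness <= 1:
            raise ValueError("sharpness must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def weights(self) -> np.ndarray:
        """Mixing weight per seed, sorted along the planted axis."""
        n = self.n_seeds
        x = np.arange(n) / (n - 1)
        if self.mode == "graded":
            return x
        if self.mode == "clustered":
            return (x >= 0.5).astype(float)
        s = self.sharpness
        if s == 0:
            return (x >= 0.5).astype(float)
        return np.clip(0.5 + (x - 0.5) / s, 0.0, 1.0)


def default_endmembers(
    n_targets: int, rng: np.random.Generator, shared_fraction: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Two sparse nonnegative target patterns with mostly disjoint support.

    Each endmember occupies one half of the target space plus a small shared
    band, mimicking two distinct connection territories.
    """
    half = n_targets // 2
    shared = int(round(shared_fraction * half))
    a = np.zeros(n_targets)
    b = np.zeros(n_targets)
    a[: half + shared] = rng.uniform(0.5, 1.5, half + shared)
    b[half - shared :] = rng.uniform(0.5, 1.5, n_targets - half + shared)
    return a, b


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))


def _resolve_endmembers(
    truth: SyntheticTruth, n_targets: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    if truth.endmember_a is not None and truth.endmember_b is not None:
        a = np.asarray(truth.endmember_a, float)
        b = np.asarray(truth.endmember_b, float)
    else:
        a, b = default_endmembers(n_targets, rng)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("endmembers must be nonnegative")
    if _cosine(a, b) >= 0.5:
        raise ValueError(f"endmembers too similar: cosine {_cosine(a, b):.2f} >= 0.5")
    return a, b


def make_phantom_segmentation(
    shape: tuple[int, int, int] = (12, 12, 12), rng_seed: int = 0
) -> dict[str, BinaryMask]:
    """Nested WM core / GM shell / CSF pockets plus an ROI mask.

    Deterministic given the seed.  Raises for shapes smaller than 8 in any
    dimension.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 8:
        raise ValueError(f"phantom shape must be >= 8 in every dimension, got {shape}")
    rng = np.random.default_rng(rng_seed)
    grid = VolumeGrid(shape, np.diag([2.0, 2.0, 2.0, 1.0]))

    center = (np.asarray(shape) - 1) / 2
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    r = np.sqrt(
        ((ii - center[0]) / (shape[0] / 2)) ** 2
        + ((jj - center[1]) / (shape[1] / 2)) ** 2
        + ((kk - center[2]) / (shape[2] / 2)) ** 2
    )
    wm = r < 0.45
    gm = (r >= 0.45) & (r < 0.75)

    # CSF pockets: a few random blobs in the outer shell, dilated once
    csf = np.zeros(shape, dtype=bool)
    outer = (r >= 0.75) & (r < 0.95)
    candidates = np.argwhere(outer)
    if len(candidates):
        picks = candidates[rng.choice(len(candidates), size=min(4, len(candidates)), replace=False)]
        csf[tuple(picks.T)] = True
        csf = ndimage.binary_dilation(csf) & ~wm
    gm &= ~csf

    # ROI: one hemisphere of the phantom (i below center), covering the interface
    roi = np.zeros(shape, dtype=bool)
    roi[: shape[0] // 2 + 1] = True
    roi &= r < 0.8

    return {
        "grid": grid,
        "wm": BinaryMask(grid, wm),
        "gm": BinaryMask(grid, gm),
        "csf": BinaryMask(grid, csf),
        "roi": BinaryMask(grid, roi),
    }


def _line_roi(n_seeds: int) -> SeedROI:
    """A straight line of seed voxels; lexicographic order == planted axis."""
    grid = VolumeGrid((n_seeds, 3, 3), np.diag([2.0, 2.0, 2.0, 1.0]))
    voxels = np.column_stack(
        [np.arange(n_seeds), np.ones(n_seeds, int), np.ones(n_seeds, int)]
    )
    return SeedROI(grid, voxels)


def make_fingerprints(
    n_seeds: int,
    n_targets: int,
    truth: SyntheticTruth,
    n_participants: int = 1,
    count_scale: float | None = None,
) -> tuple[list[FingerprintSet], SyntheticTruth]:
    """Per-participant streamline-count fingerprints mixing two endmembers.

    Seed i of participant p draws counts ~ Poisson(scale * (w_i A + (1-w_i) B))
    with Gaussian jitter (sd 0.05, truncated to [0, 1]) on w per participant.
    ``noise_sd`` sets the relative count noise: scale = noise_sd**-2, so
    sd/mean of a unit-rate target is noise_sd.  noise_sd = 0 returns the
    exact expected profiles (no sampling, no jitter).
    """
    truth = replace(truth, n_seeds=n_seeds)
    rng = np.random.default_rng(truth.rng_seed)
    a, b = _resolve_endmembers(truth, n_targets, rng)
    truth = replace(truth, endmember_a=a, endmember_b=b)
    w = truth.weights
    roi = _line_roi(n_seeds)
    targets = np.arange(n_targets)

    if count_scale is None:
        count_scale = 1.0 if truth.noise_sd == 0 else truth.noise_sd**-2

    out = []
    for _ in range(n_participants):
        if truth.noise_sd == 0:
            wp = w
            values = count_scale * (wp[:, None] * a + (1 - wp[:, None]) * b)
        else:
            wp = np.clip(w + rng.normal(0, _JITTER_SD, n_seeds), 0.0, 1.0)
            lam = count_scale * (wp[:, None] * a + (1 - wp[:, None]) * b)
            values = rng.poisson(lam).astype(float)
        out.append(FingerprintSet(roi, targets, values, kind="native_counts"))
    return out, truth


def _smooth_signal(rng: np.random.Generator, n: int, width: float = 3.0) -> np.ndarray:
    s = ndimage.gaussian_filter1d(rng.standard_normal(n), width)
    return s / np.linalg.norm(s)


def make_timeseries(
    n_voxels: int,
    n_timepoints: int,
    truth: SyntheticTruth,
    n_participants: int = 1,
    tr_seconds: float = 2.8,
) -> tuple[list[TimeSeriesSet], SyntheticTruth]:
    """Voxel time series mixing two weakly-correlated network signals.

    Two smoothed-Gaussian signals s_A, s_B are generated per participant
    with |corr| < 0.2 by Gram-Schmidt construction; voxel i's series is
    w_i s_A + (1 - w_i) s_B + Gaussian(0, noise_sd).
    """
    if n_timepoints < 50:
        raise ValueError("need at least 50 timepoints")
    truth = replace(truth, n_seeds=n_voxels)
    rng = np.random.default_rng(truth.rng_seed)
    w = truth.weights
    roi = _line_roi(n_voxels)

    out = []
    for _ in range(n_participants):
        s_a = _smooth_signal(rng, n_timepoints)
        raw_b = _smooth_signal(rng, n_timepoints)
        s_b = raw_b - (raw_b @ s_a) * s_a  # orthogonalize: corr ~ 0 < 0.2
        s_b /= np.linalg.norm(s_b)
        series = w[:, None] * s_a + (1 - w[:, None]) * s_b
        if truth.noise_sd > 0:
            series = series + rng.normal(0, truth.noise_sd / np.sqrt(n_timepoints),
                                         size=series.shape)
        out.append(TimeSeriesSet(roi, series, tr_seconds=tr_seconds))
    return out, truth


def make_motion_trace(
    n_timepoints: int,
    rng: np.random.Generator,
    n_spikes: int = 0,
    big_violation: bool = False,
    drift_sd: float = 0.01,
) -> np.ndarray:
    """(t, 6) motion trace: slow drift plus planted >1 mm framewise spikes
    and optionally one >3 mm absolute violation."""
    mp = np.cumsum(rng.normal(0, drift_sd, size=(n_timepoints, 6)), axis=0)
    mp = np.clip(mp, -0.4, 0.4)
    if n_spikes:
        ts = rng.choice(np.arange(5, n_timepoints - 5), size=n_spikes, replace=False)
        for t in ts:
            mp[t, rng.integers(0, 3)] += rng.uniform(1.2, 2.0)
    if big_violation:
        mp[n_timepoints // 2, 0] = 3.5
    return mp


@dataclass(frozen=True)
class GroupDatasetConfig:
    n_participants: int = 6
    n_seeds: int = 40
    n_targets: int = 120
    n_timepoints: int = 100
    mode: str = "graded"
    sharpness: float = 1.0
    noise_sd: float = 0.1
    tr_seconds: float = 2.8
    phantom_shape: tuple[int, int, int] = (12, 12, 12)
    n_motion_spikes: int = 2
    participant_with_violation: int | None = None  # index gets a >3 mm jump
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_participants < 1:
            problems.append("n_participants must be >= 1")
        if self.n_seeds < 2:
            problems.append("n_seeds must be >= 2")
        if self.n_timepoints < 50:
            problems.append("n_timepoints must be >= 50")
        if self.mode not in ("graded", "clustered", "intermediate"):
            problems.append(f"unknown mode {self.mode!r}")
        if not 0 <= self.sharpness <= 1:
            problems.append("sharpness must be in [0, 1]")
        if self.participant_with_violation is not None and not (
            0 <= self.participant_with_violation < self.n_participants
        ):
            problems.append("participant_with_violation out of range")
        if problems:
            raise ValueError("; ".join(problems))


@dataclass(frozen=True)
class GroupDataset:
    config: GroupDatasetConfig
    truth: SyntheticTruth
    segmentation: dict
    fingerprints: list[FingerprintSet]
    timeseries: list[TimeSeriesSet]
    motion: list[np.ndarray]
    manifest: str


def make_group_dataset(config: GroupDatasetConfig) -> GroupDataset:
    """Self-consistent fixture bundle: segmentation phantom, fingerprints,
    time series and motion traces, plus a TSV manifest of the contents."""
    config.validate()
    truth = SyntheticTruth(
        n_seeds=config.n_seeds,
        mode=config.mode,
        sharpness=config.sharpness,
        noise_sd=config.noise_sd,
        rng_seed=config.seed,
    )
    seg = make_phantom_segmentation(config.phantom_shape, rng_seed=config.seed)
    fps, truth = make_fingerprints(
        config.n_seeds, config.n_targets, truth, config.n_participants
    )
    tss, _ = make_timeseries(
        config.n_seeds,
        config.n_timepoints,
        truth,
        config.n_participants,
        tr_seconds=config.tr_seconds,
    )
    rng = np.random.default_rng(config.seed + 1)
    motion = [
        make_motion_trace(
            config.n_timepoints,
            rng,
            n_spikes=config.n_motion_spikes,
            big_violation=(p == config.participant_with_violation),
        )
        for p in range(config.n_participants)
    ]
    lines = ["item\tparticipant\tkind\tn_rows"]
    for p in range(config.n_participants):
        lines.append(f"fingerprints_{p:02d}\t{p}\tnative_counts\t{config.n_seeds}")
        lines.append(f"timeseries_{p:02d}\t{p}\ttimeseries\t{config.n_seeds}")
        lines.append(f"motion_{p:02d}\t{p}\tmotion\t{config.n_timepoints}")
    for name in ("wm", "gm", "csf", "roi"):
        lines.append(f"{name}\t-\tmask\t{seg[name].count}")
    return GroupDataset(
        config=config,
        truth=truth,
        segmentation=seg,
        fingerprints=fps,
        timeseries=tss,
        motion=motion,
        manifest="\n".join(lines) + "\n",
    )
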