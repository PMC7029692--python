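import numpy as np
import pytest

from conngrad.grids import BinaryMask, SeedROI, VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def grid3():
    return VolumeGrid((3, 3, 3))


@pytest.fixture
def line_roi():
    def make(n):
        grid = VolumeGrid((n, 3, 3), np.diag([2.0, 2.0, 2.0, 1.0]))
        voxels = np.column_stack([np.arange(n), np.ones(n, int), np.ones(n, int)])
        return SeedROI(grid, voxels)

    return make


def random_masks(rng, shape=(12, 12, 12), p_white=0.4, p_csf=0.1):
    """Random white/CSF masks on one grid for brute-force comparisons."""
    grid = VolumeGrid(shape)
    white = rng.random(shape) < p_white
    csf = (rng.random(shape) < p_csf) & ~white
    return BinaryMask(grid, white), BinaryMask(grid, csf)


NEIGHBOR_OFFSETS = {
    6: [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
    26: [
        (di, dj, dk)
        for di in (-1, 0, 1)
        for dj in (-1, 0, 1)
        for dk in (-1, 0, 1)
        if (di, dj, dk) != (0, 0, 0)
    ],
}
NEIGHBOR_OFFSETS[18] = [
    o for o in NEIGHBOR_OFFSETS[26] if sum(abs(x) for x in o) <= 2
]


def brute_force_interface(white, csf, dilation_radius, connectivity=6):
    """Independent triple-loop reimplementation of the interface rule."""
    shape = white.grid.shape
    offsets = NEIGHBOR_OFFSETS[connectivity]
    w = white.values
    out = np.zeros(shape, dtype=bool)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if not w[i, j, k]:
                    continue
                for di, dj, dk in offsets:
                    ni, nj, nk = i + di, j + dj, k + dk
                    outside = not (
                        0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]
                    )
                    if outside or not w[ni, nj, nk]:
                        out[i, j, k] = True
                        break
    # iterative dilation of CSF by the same offsets
    dil = csf.values.copy()
    for _ in range(dilation_radius):
        nxt = dil.copy()
        for i in range(shape[0]):
            for j in range(shape[1]):
                for k in range(shape[2]):
                    if not dil[i, j, k]:
                        continue
                    for di, dj, dk in offsets:
                        ni, nj, nk = i + di, j + dj, k + dk
                        if 0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]:
                            nxt[ni, nj, nk] = True
        dil = nxt
    if dilation_radius > 0:
        out &= ~dil
    return out


def brute_force_censor(mp_values, global_signal, trans_mm=1.0, z_thresh=2.5):
    """Per-timepoint scalar re-check of the artifact-flagging rule."""
    t_n = mp_values.shape[0]
    g = np.asarray(global_signal, float)
    mu, sd = g.mean(), g.std()
    flags = np.zeros(t_n, dtype=bool)
    for t in range(t_n):
        if t > 0:
            for axis in range(3):
                if abs(mp_values[t, axis] - mp_values[t - 1, axis]) > trans_mm:
                    flags[t] = True
        if sd > 0 and abs((g[t] - mu) / sd) > z_thresh:
            flags[t] = True
    return flags


def brute_force_cosine(rows):
    """Double-loop scalar cosine oracle."""
    n = rows.shape[0]
    out = np.empty((n, n))
    for a in range(n):
        for b in range(n):
            num = sum(float(x) * float(y) for x, y in zip(rows[a], rows[b]))
            na = sum(float(x) ** 2 for x in rows[a]) ** 0.5
            nb = sum(float(y) ** 2 for y in rows[b]) ** 0.5
            out[a, b] = num / (na * nb)
    return out


def normalized_laplacian_spectrum(adjacency):
    """Oracle: eigenvalues of D^(-1/2) (D - A) D^(-1/2)."""
    deg = adjacency.sum(axis=1)
    d_inv_sqrt = np.diag(1.0 / np.sqrt(deg))
    lap = np.diag(deg) - adjacency
    sym = d_inv_sqrt @ lap @ d_inv_sqrt
    return np.sort(np.linalg.eigvalsh(sym))


def random_similarity(rng, n, mode="structural_cosine"):
    """A valid random similarity matrix built from random fingerprints."""
    from conngrad.grids import SeedROI, VolumeGrid
    from conngrad.roi_geometry import FingerprintSet
    from conngrad.similarity import cosine_similarity_matrix

    grid = VolumeGrid((n, 3, 3))
    roi = SeedROI(grid, np.column_stack([np.arange(n), np.ones(n, int), np.ones(n, int)]))
    rows = rng.random((n, 2 * n)) + 0.05
    fp = FingerprintSet(roi, np.arange(2 * n), rows, kind="native_counts")
    return cosine_similarity_matrix(fp)
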