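"""Difference-series correlation matrix and its SVD embedding.

Each pair of data sets (m, n) is compared through *difference series*:
over the observations recorded in both data sets, the deviations from the
multi-data-set average (F_i - F-bar_i for amplitudes; the x, y, z
components of c_j - c-bar_j for C-alpha positions). The Pearson
correlation of the two series, clamped to [0, 1], fills a symmetric N x N
matrix M with a zero diagonal. SVD of M = U W V^T yields orthogonal axes
ordered by weight; rows of U restricted to three chosen axes place every
data set in a 3D embedding where concerted deviations from the average
appear as clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .averaging import AverageAmplitudes, AverageCoordinates
from .formats import CoordinateModel, MultiDataSet, ReflectionSet

logger = logging.getLogger(__name__)

__all__ = [
    "ValueSeries",
    "CorrelationMatrix",
    "SVDResult",
    "AxisProjection",
    "diff_series_reciprocal",
    "diff_series_realspace",
    "pearson_bounded",
    "build_matrix",
    "svd_decompose",
    "project_axes",
    "reorder_matrix",
    "render_matrix",
]

DEFAULT_MIN_COMMON = 10  # shared observations below which a pair scores 0


@dataclass
class ValueSeries:
    """Ordered difference values plus the keys they correspond to."""

    values: np.ndarray
    index_keys: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).reshape(-1)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CorrelationMatrix:
    """Symmetric N x N matrix of bounded coefficients, zero diagonal."""

    matrix: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.labels = list(self.labels)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class SVDResult:
    """M = U diag(W) V^T with W sorted descending, U/V column-sign canonical."""

    u: np.ndarray
    w: np.ndarray
    v: np.ndarray


@dataclass
class AxisProjection:
    """N x 3 embedding: rows of U restricted to the chosen axes."""

    axes: tuple[int, int, int]
    s: np.ndarray
    labels: list[str]


def diff_series_reciprocal(
    rs_m: ReflectionSet,
    rs_n: ReflectionSet,
    avg: AverageAmplitudes,
) -> tuple[ValueSeries, ValueSeries]:
    """Amplitude deviations from the average over the common reflections.

    Only Miller indices recorded in both data sets (and present in the
    average) contribute; entries are F_i,m - F-bar_i and F_i,n - F-bar_i in
    lexicographic index order.
    """
    pos_m = avg.positions_of(rs_m.hkl)
    pos_n = avg.positions_of(rs_n.hkl)
    map_m = {p: f for p, f in zip(pos_m, rs_m.f) if p >= 0}
    map_n = {p: f for p, f in zip(pos_n, rs_n.f) if p >= 0}
    common = sorted(map_m.keys() & map_n.keys())
    keys = [tuple(int(x) for x in avg.hkl[p]) for p in common]
    vm = np.array([map_m[p] - avg.fbar[p] for p in common])
    vn = np.array([map_n[p] - avg.fbar[p] for p in common])
    return ValueSeries(vm, keys), ValueSeries(vn, keys)


def diff_series_realspace(
    cm_m: CoordinateModel,
    cm_n: CoordinateModel,
    avg: AverageCoordinates,
) -> tuple[ValueSeries, ValueSeries]:
    """Coordinate deviations from the average over the common atoms.

    Each atom modelled in both contributes its three components of
    c_j - c-bar_j consecutively (x, y, z), giving series of length
    3 * J_common in matching key order.
    """
    idx_m = {k: i for i, k in enumerate(cm_m.atom_keys)}
    idx_n = {k: i for i, k in enumerate(cm_n.atom_keys)}
    common = sorted((idx_m.keys() & idx_n.keys()) & set(avg.atom_keys))
    pos = avg.positions_of(common)
    keys = [f"{k}/{c}" for k in common for c in "xyz"]
    if not common:
        return ValueSeries(np.empty(0), []), ValueSeries(np.empty(0), [])
    rows_m = np.array([cm_m.coords[idx_m[k]] for k in common])
    rows_n = np.array([cm_n.coords[idx_n[k]] for k in common])
    cbar = avg.cbar[pos]
    return (
        ValueSeries((rows_m - cbar).ravel(), keys),
        ValueSeries((rows_n - cbar).ravel(), keys),
    )


def _pearson_clamped(x: np.ndarray, y: np.ndarray, min_common: int = DEFAULT_MIN_COMMON,
                     context: str = "") -> float:
    """Pearson r clamped to [0, 1]; degenerate pairs score 0 with a warning."""
    if len(x) != len(y):
        raise ValueError("series length mismatch")
    if len(x) < max(2, min_common):
        logger.warning("pair %s: only %d shared observations (< %d); coefficient set to 0",
                       context, len(x), max(2, min_common))
        return 0.0
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt(np.dot(dx, dx))
    sy = np.sqrt(np.dot(dy, dy))
    if sx == 0.0 or sy == 0.0:
        logger.warning("pair %s: zero-variance difference series; coefficient set to 0",
                       context)
        return 0.0
    r = float(np.dot(dx, dy) / (sx * sy))
    return max(0.0, r)


def pearson_bounded(v_m: ValueSeries | np.ndarray, v_n: ValueSeries | np.ndarray,
                    min_common: int = DEFAULT_MIN_COMMON) -> float:
    """Pearson correlation of two equal-length series, bounded to [0, 1].

    Anticorrelation clamps to 0 rather than being remapped: a pair with no
    net positive correlation carries no evidence of shared deviation from
    the average. Series shorter than ``min_common`` or with zero variance
    return 0 with a logged warning.
    """
    x = v_m.values if isinstance(v_m, ValueSeries) else np.asarray(v_m, dtype=np.float64)
    y = v_n.values if isinstance(v_n, ValueSeries) else np.asarray(v_n, dtype=np.float64)
    return _pearson_clamped(x, y, min_common=min_common)


def _aligned_reciprocal(mds: MultiDataSet, avg: AverageAmplitudes) -> np.ndarray:
    """(N, M) deviations from the average, NaN where a reflection is missing."""
    out = np.full((mds.n, len(avg)), np.nan)
    for i, rs in enumerate(mds.reflection_sets):
        pos = avg.positions_of(rs.hkl)
        ok = pos >= 0
        out[i, pos[ok]] = rs.f[ok] - avg.fbar[pos[ok]]
    return out


def _aligned_realspace(mds: MultiDataSet, avg: AverageCoordinates) -> np.ndarray:
    """(N, 3J) coordinate deviations, NaN triplets where an atom is missing."""
    out = np.full((mds.n, len(avg), 3), np.nan)
    for i, cm in enumerate(mds.models):
        pos = avg.positions_of(cm.atom_keys)
        ok = pos >= 0
        out[i, pos[ok]] = cm.coords[ok] - avg.cbar[pos[ok]]
    return out.reshape(mds.n, -1)


def build_matrix(
    mds: MultiDataSet,
    mode: str = "reciprocal",
    avg: AverageAmplitudes | AverageCoordinates | None = None,
    min_common: int = DEFAULT_MIN_COMMON,
) -> CorrelationMatrix:
    """Bounded-coefficient matrix over all data-set pairs.

    ``mode`` selects reciprocal-space (amplitude) or real-space (C-alpha)
    difference series. All N(N-1)/2 pairs are computed once and mirrored;
    the diagonal is exactly zero. For reciprocal mode the sets should
    already be shell-scaled.
    """
    if mds.n < 2:
        raise ValueError("N >= 2 data sets required for a correlation matrix")
    if mode == "reciprocal":
        if avg is None:
            from .averaging import average_amplitudes
            avg = average_amplitudes(mds.reflection_sets)
        aligned = _aligned_reciprocal(mds, avg)
        min_len = min_common
    elif mode == "realspace":
        if avg is None:
            from .averaging import average_coordinates
            avg = average_coordinates(mds.models)
        aligned = _aligned_realspace(mds, avg)
        # min_common counts shared observations; one atom contributes three
        min_len = 3 * int(np.ceil(min_common / 3))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n = mds.n
    labels = mds.dataset_ids
    finite = np.isfinite(aligned)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = finite[i] & finite[j]
            a = _pearson_clamped(aligned[i, mask], aligned[j, mask],
                                 min_common=min_len,
                                 context=f"{labels[i]}/{labels[j]}")
            m[i, j] = m[j, i] = a
    return CorrelationMatrix(m, labels)


def svd_decompose(cm: CorrelationMatrix) -> SVDResult:
    """SVD of the correlation matrix with canonical column signs.

    Weights come back sorted descending (numpy's convention); each column
    of U is flipped, together with the matching column of V, so that its
    largest-magnitude entry is positive — making repeated decompositions
    and downstream plots reproducible.
    """
    if not np.all(np.isfinite(cm.matrix)):
        raise ValueError("correlation matrix contains non-finite entries")
    u, w, vh = np.linalg.svd(cm.matrix)
    v = vh.T
    for j in range(u.shape[1]):
        i = int(np.argmax(np.abs(u[:, j])))
        if u[i, j] < 0:
            u[:, j] = -u[:, j]
            v[:, j] = -v[:, j]
    return SVDResult(u, w, v)


def project_axes(
    svd: SVDResult,
    labels: list[str],
    axes: tuple[int, int, int] | None = None,
    weight: bool = False,
) -> AxisProjection:
    """Restrict U to three chosen axes (default: the three largest weights).

    With ``weight=True`` each column is additionally multiplied by its
    singular value, emphasising axes that carry more of the variation.
    """
    if axes is None:
        axes = (0, 1, 2)
    axes = tuple(int(a) for a in axes)
    if len(set(axes)) != 3:
        raise ValueError(f"axes must be three distinct indices, got {axes}")
    n = svd.u.shape[0]
    if any(a < 0 or a >= n for a in axes):
        raise ValueError(f"axis index out of range for N={n}: {axes}")
    s = svd.u[:, list(axes)].copy()
    if weight:
        s = s * svd.w[list(axes)]
    return AxisProjection(axes, s, list(labels))


def reorder_matrix(cm: CorrelationMatrix, tree) -> CorrelationMatrix:
    """Permute rows/columns so each terminal cluster is contiguous, in tree order."""
    order: list[str] = []
    for leaf in tree.leaves():
        order.extend(sorted(leaf.members))
    if set(order) != set(cm.labels) or len(order) != len(cm.labels):
        raise ValueError("cluster tree members do not match matrix labels")
    idx = [cm.labels.index(d) for d in order]
    perm = cm.matrix[np.ix_(idx, idx)]
    return CorrelationMatrix(perm, order)


def render_matrix(cm: CorrelationMatrix, path, tree=None, dpi: int = 150) -> None:
    """Raster plot of the matrix: blue at 0 through white at 0.5 to red at 1.

    If a cluster tree is given the matrix is first reordered by cluster and
    alternating boundary bars mark cluster extents along both edges.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sizes = None
    if tree is not None:
        cm = reorder_matrix(cm, tree)
        sizes = [len(leaf.members) for leaf in tree.leaves() if leaf.members]
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(cm.matrix, cmap="bwr", vmin=0.0, vmax=1.0, interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    if sizes:
        start = 0
        for ci, size in enumerate(sizes):
            colour = "black" if ci % 2 == 0 else "0.6"
            ax.plot([start - 0.5, start + size - 0.5], [-1.5, -1.5],
                    color=colour, lw=4, clip_on=False)
            ax.plot([-1.5, -1.5], [start - 0.5, start + size - 0.5],
                    color=colour, lw=4, clip_on=False)
            start += size
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
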