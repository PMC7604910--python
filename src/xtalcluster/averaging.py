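"""Average-set construction and equal-volume resolution-shell scaling.

An *average set* summarises a multi-data set: for every Miller index
recorded anywhere, the mean amplitude F-bar over the data sets that recorded
it (with the recording count), and likewise the componentwise mean C-alpha
position per atom key.

Scaling removes per-data-set global isotropic B-factor damping
exp(-B s^2 / 4): reciprocal space is divided into ``n_bins`` (default 20)
concentric shells of equal volume, and within each shell every amplitude of
a data set is multiplied by k = sum(F-bar_i) / sum(F_i,n) over the
reflections recorded in both the data set and the average, which makes the
shell sums (hence shell means) of the scaled set match the average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .formats import CoordinateModel, ReflectionSet

logger = logging.getLogger(__name__)

__all__ = [
    "AverageAmplitudes",
    "AverageCoordinates",
    "ShellBinning",
    "apply_resolution_cutoff",
    "average_amplitudes",
    "average_coordinates",
    "build_shells",
    "scale_dataset",
    "scale_all",
]

DEFAULT_D_MIN = 3.5  # Angstrom; balances speed against clustering quality
DEFAULT_N_BINS = 20


@dataclass
class AverageAmplitudes:
    """Mean amplitude and recording count per Miller index.

    ``hkl`` is lexicographically sorted; ``counts[i]`` is the number of data
    sets recording ``hkl[i]`` (1 <= counts <= N).
    """

    hkl: np.ndarray
    fbar: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=np.int64).reshape(-1, 3)
        self.fbar = np.asarray(self.fbar, dtype=np.float64).reshape(-1)
        self.counts = np.asarray(self.counts, dtype=np.int64).reshape(-1)
        self._index = {tuple(row): i for i, row in enumerate(map(tuple, self.hkl.tolist()))}

    def __len__(self) -> int:
        return len(self.fbar)

    def positions_of(self, hkl: np.ndarray) -> np.ndarray:
        """Row positions of the given indices in this average (-1 if absent)."""
        return np.array(
            [self._index.get(tuple(row), -1) for row in np.asarray(hkl).tolist()],
            dtype=np.int64,
        )


@dataclass
class AverageCoordinates:
    """Mean position and modelling count per atom key (sorted by key)."""

    atom_keys: list[str]
    cbar: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.atom_keys = list(self.atom_keys)
        self.cbar = np.asarray(self.cbar, dtype=np.float64).reshape(-1, 3)
        self.counts = np.asarray(self.counts, dtype=np.int64).reshape(-1)
        self._index = {k: i for i, k in enumerate(self.atom_keys)}

    def __len__(self) -> int:
        return len(self.atom_keys)

    def positions_of(self, keys) -> np.ndarray:
        return np.array([self._index.get(k, -1) for k in keys], dtype=np.int64)


@dataclass
class ShellBinning:
    """Equal-volume concentric shells in reciprocal space.

    Boundaries follow the cube-root law r_b = r_max (b / n_bins)^(1/3),
    b = 0..n_bins, so each shell has volume (4 pi / 3) r_max^3 / n_bins.
    Shells are half-open [r_{b-1}, r_b); the outermost is closed at r_max.
    """

    n_bins: int
    r_max: float
    boundaries: np.ndarray

    def assign(self, s: np.ndarray) -> np.ndarray:
        """Shell index per reciprocal radius; radii at r_max go in the last shell."""
        s = np.asarray(s, dtype=np.float64)
        idx = np.searchsorted(self.boundaries[1:], s, side="right")
        return np.minimum(idx, self.n_bins - 1)

    def shell_volumes(self) -> np.ndarray:
        r = self.boundaries
        return 4.0 * np.pi / 3.0 * (r[1:] ** 3 - r[:-1] ** 3)


def apply_resolution_cutoff(rs: ReflectionSet, d_min: float = DEFAULT_D_MIN) -> ReflectionSet:
    """Drop reflections with d-spacing below ``d_min`` (default 3.5 A).

    d is computed from the data set's own unit cell via the reciprocal
    metric tensor.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    keep = rs.d_spacings() >= d_min
    return rs.replace(hkl=rs.hkl[keep], f=rs.f[keep])


def average_amplitudes(sets: list[ReflectionSet]) -> AverageAmplitudes:
    """Mean amplitude over the recording data sets, per Miller index.

    Indices recorded nowhere are absent; an empty input gives an empty
    average.
    """
    if not sets:
        return AverageAmplitudes(np.empty((0, 3), dtype=np.int64), np.empty(0), np.empty(0, dtype=np.int64))
    all_hkl = np.concatenate([rs.hkl for rs in sets])
    all_f = np.concatenate([rs.f for rs in sets])
    uniq, inverse = np.unique(all_hkl, axis=0, return_inverse=True)
    sums = np.bincount(inverse, weights=all_f, minlength=len(uniq))
    counts = np.bincount(inverse, minlength=len(uniq))
    return AverageAmplitudes(uniq, sums / counts, counts)


def average_coordinates(models: list[CoordinateModel]) -> AverageCoordinates:
    """Componentwise mean position over the models containing each atom key."""
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for cm in models:
        for key, xyz in zip(cm.atom_keys, cm.coords):
            if key in sums:
                sums[key] = sums[key] + xyz
                counts[key] += 1
            else:
                sums[key] = xyz.copy()
                counts[key] = 1
    keys = sorted(sums)
    cbar = np.array([sums[k] / counts[k] for k in keys]).reshape(-1, 3)
    n = np.array([counts[k] for k in keys], dtype=np.int64)
    return AverageCoordinates(keys, cbar, n)


def build_shells(sets: list[ReflectionSet], n_bins: int = DEFAULT_N_BINS) -> ShellBinning:
    """Equal-volume shell boundaries spanning every recorded reflection.

    r_max is the largest reciprocal radius |s| = 1/d over all data sets,
    each evaluated in its own unit cell; boundaries are global.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    r_max = 0.0
    total = 0
    for rs in sets:
        total += len(rs)
        if len(rs):
            r_max = max(r_max, float(rs.reciprocal_radii().max()))
    if total == 0:
        raise ValueError("cannot build shells with no reflections")
    b = np.arange(n_bins + 1, dtype=np.float64)
    boundaries = r_max * np.cbrt(b / n_bins)
    return ShellBinning(n_bins=n_bins, r_max=r_max, boundaries=boundaries)


def scale_dataset(
    rs: ReflectionSet,
    avg: AverageAmplitudes,
    shells: ShellBinning,
    return_scales: bool = False,
):
    """Rescale one data set shell-by-shell onto the average.

    Per shell, k = sum(F-bar_i) / sum(F_i,n) over reflections recorded in
    both ``rs`` and ``avg`` within that shell; every amplitude of ``rs`` in
    the shell is multiplied by k. Shells with no common reflections keep
    k = 1 (warning logged); a zero amplitude sum with common reflections
    present is an error.
    """
    bins = shells.assign(rs.reciprocal_radii())
    pos = avg.positions_of(rs.hkl)
    common = pos >= 0
    k = np.ones(shells.n_bins)
    for b in range(shells.n_bins):
        in_shell = bins == b
        sel = in_shell & common
        if not np.any(sel):
            if np.any(in_shell):
                logger.warning(
                    "%s: shell %d has no reflections in common with the average; k = 1",
                    rs.dataset_id, b,
                )
            continue
        denom = rs.f[sel].sum()
        if denom == 0.0:
            raise ValueError(f"{rs.dataset_id}: zero amplitude sum in shell {b}")
        k[b] = avg.fbar[pos[sel]].sum() / denom
    scaled = rs.replace(f=rs.f * k[bins])
    if return_scales:
        return scaled, k
    return scaled


def scale_all(
    sets: list[ReflectionSet],
    avg: AverageAmplitudes | None = None,
    shells: ShellBinning | None = None,
    n_bins: int = DEFAULT_N_BINS,
) -> list[ReflectionSet]:
    """Scale every data set against a common average (built here if absent)."""
    if avg is None:
        avg = average_amplitudes(sets)
    if shells is None:
        shells = build_shells(sets, n_bins=n_bins)
    return [scale_dataset(rs, avg, shells) for rs in sets]
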