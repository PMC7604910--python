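"""Synthetic multi-data sets with planted cluster structure.

The generator emulates the heterogeneity phenomena the clustering method
targets, without any diffraction physics: a shared log-normal amplitude
spectrum perturbed along a cluster-specific direction (concerted
reciprocal-space deviation), per-data-set isotropic B-factor damping
exp(-B s^2/4) and unit-cell jitter, multiplicative observation noise,
random missing observations, optional indexing flips, and a random-walk
C-alpha fold moved rigidly per cluster with per-atom noise and dropout.
Everything is drawn from a single seed, so fixtures regenerate
bit-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cluster import apply_index_op, parse_index_op
from .formats import (
    CoordinateModel,
    MultiDataSet,
    ReflectionSet,
    read_model,
    read_reflections,
    reciprocal_radius,
    write_model_pdb,
    write_reflections_mtz,
    write_reflections_tsv,
)

logger = logging.getLogger(__name__)

__all__ = ["FixtureSpec", "FixtureResult", "generate_multidataset", "write_fixture", "read_fixture"]


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic multi-data set.

    Defaults describe a moderately heterogeneous fragment-screen campaign:
    three clusters of twenty crystals, ~400 low-resolution reflections and
    a 60-residue C-alpha trace each, amplitude perturbation twice the
    observation noise (SNR 2), B factors up to 30 A^2 and 10% missing
    observations.
    """

    n_clusters: int = 3
    sizes: list[int] | None = None          # default: 20 per cluster
    n_reflections: int | None = 400         # None: full sphere to d_min_generate
    n_atoms: int = 60
    base_cell: tuple = (48.0, 48.0, 60.0, 90.0, 90.0, 90.0)
    cell_jitter: float = 0.1                # sd of per-set cell-length jitter, A
    amplitude_perturbation: float = 0.05    # per-cluster log-amplitude scale
    coordinate_shift: tuple = (1.0, 2.0)    # per-cluster rigid shift: (A, degrees)
    noise_sd: float = 0.025                 # per-observation noise: log-F fraction / A
    b_factor_range: tuple = (0.0, 30.0)     # per-set isotropic B, A^2
    missing_fraction: float = 0.1
    indexing_flip_fraction: float = 0.0
    flip_op: str = "k,h,-l"
    d_min_generate: float = 3.0             # generation cutoff, below pipeline default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sizes is None:
            self.sizes = [20] * self.n_clusters
        if len(self.sizes) != self.n_clusters:
            raise ValueError("sizes must have n_clusters entries")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValueError("missing_fraction must lie in [0, 1)")
        if not (0.0 <= self.indexing_flip_fraction <= 1.0):
            raise ValueError("indexing_flip_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_datasets(self) -> int:
        return sum(self.sizes)


@dataclass
class FixtureResult:
    """Generated multi-data set plus its planted ground truth."""

    mds: MultiDataSet
    labels: dict[str, int]
    flipped: list[str] = field(default_factory=list)


def _index_universe(spec: FixtureSpec) -> np.ndarray:
    """Sphere-complete Miller-index set of ~n_reflections lowest-resolution points.

    All indices with d above the cutoff of the n-th strongest-d index are
    kept, extended to the complete tie group at that d, so the set is
    closed under cell-preserving index swaps (a = b) and fills reciprocal
    space out to a sphere — the shape resolution shells assume.
    """
    a, b, c = spec.base_cell[:3]
    d_min = spec.d_min_generate
    hmax = int(np.ceil(a / d_min)) + 1
    kmax = int(np.ceil(b / d_min)) + 1
    lmax = int(np.ceil(c / d_min)) + 1
    h, k, l = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    hkl = hkl[np.any(hkl != 0, axis=1)]
    s = reciprocal_radius(spec.base_cell, hkl)
    keep = s <= 1.0 / d_min
    hkl, s = hkl[keep], s[keep]
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0], s))
    hkl, s = hkl[order], s[order]
    if spec.n_reflections is None:
        return hkl
    n = min(spec.n_reflections, len(hkl))
    s_cut = s[n - 1]
    n_ext = int(np.searchsorted(s, s_cut + 1e-9, side="right"))
    return hkl[:n_ext]


def _random_fold(rng: np.random.Generator, n_atoms: int) -> np.ndarray:
    """Compact self-avoiding-ish random walk with 3.8 A C-alpha steps."""
    pos = np.zeros((n_atoms, 3))
    for i in range(1, n_atoms):
        step = rng.standard_normal(3)
        step -= 0.15 * pos[i - 1] / max(np.linalg.norm(pos[i - 1]), 1.0)  # weak recentring
        step *= 3.8 / np.linalg.norm(step)
        pos[i] = pos[i - 1] + step
    return pos - pos.mean(axis=0)


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    kx, ky, kz = axis
    kmat = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + np.sin(t) * kmat + (1 - np.cos(t)) * (kmat @ kmat)


def generate_multidataset(spec: FixtureSpec) -> FixtureResult:
    """Draw one multi-data set with planted clusters from a single seed."""
    rng = np.random.default_rng(spec.seed)
    hkl = _index_universe(spec)
    n_refl = len(hkl)

    f_base = rng.lognormal(mean=3.0, sigma=0.5, size=n_refl)
    cluster_dirs = rng.standard_normal((spec.n_clusters, n_refl))
    f_cluster = f_base[None, :] * np.exp(spec.amplitude_perturbation * cluster_dirs)

    fold = _random_fold(rng, spec.n_atoms)
    shift_a, shift_deg = spec.coordinate_shift
    cluster_coords = []
    for _ in range(spec.n_clusters):
        rot = _rotation_matrix(rng.standard_normal(3), shift_deg * rng.uniform(0.5, 1.0))
        tvec = rng.standard_normal(3)
        tvec *= shift_a / np.linalg.norm(tvec)
        cluster_coords.append(fold @ rot.T + tvec)

    flip_mat = parse_index_op(spec.flip_op)
    atom_keys = [f"A/{i + 1}/" for i in range(spec.n_atoms)]

    entries: list[tuple[ReflectionSet, CoordinateModel]] = []
    labels: dict[str, int] = {}
    flipped: list[str] = []
    ds_index = 0
    for ci, size in enumerate(spec.sizes):
        for _ in range(size):
            did = f"ds{ds_index:03d}"
            ds_index += 1
            labels[did] = ci

            cell = list(spec.base_cell)
            for ax in range(3):
                cell[ax] = max(cell[ax] + rng.normal(0.0, spec.cell_jitter), 1.0)
            cell = tuple(cell)

            f = f_cluster[ci] * np.exp(spec.noise_sd * rng.standard_normal(n_refl))
            bfac = rng.uniform(*spec.b_factor_range)
            s = reciprocal_radius(cell, hkl)
            f = f * np.exp(-bfac * s**2 / 4.0)

            keep = rng.random(n_refl) >= spec.missing_fraction
            rs = ReflectionSet(did, hkl[keep], f[keep], cell)
            if rng.random() < spec.indexing_flip_fraction:
                rs = apply_index_op(rs, flip_mat)
                flipped.append(did)

            coords = cluster_coords[ci] + rng.normal(0.0, spec.noise_sd, (spec.n_atoms, 3))
            akeep = rng.random(spec.n_atoms) >= spec.missing_fraction
            cm = CoordinateModel(did, [k for k, m in zip(atom_keys, akeep) if m],
                                 coords[akeep])
            entries.append((rs, cm))

    return FixtureResult(MultiDataSet(entries), labels, flipped)


def write_fixture(
    result: FixtureResult | MultiDataSet,
    out_dir: str | Path,
    format: str = "tsv",
) -> Path:
    """Write a fixture to disk: per-set reflections + PDB, manifest, label sidecar.

    ``format`` selects the reflection container ("tsv" or "mtz"); models are
    always PDB. Returns the manifest path.
    """
    if isinstance(result, MultiDataSet):
        result = FixtureResult(result, {}, [])
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mds = result.mds
    if mds.n == 0:
        logger.warning("empty multi-data set; writing empty manifest")
    rows = []
    for rs, cm in mds.entries:
        if format == "tsv":
            rpath = out_dir / f"{rs.dataset_id}.tsv"
            write_reflections_tsv(rs, rpath)
        elif format == "mtz":
            rpath = out_dir / f"{rs.dataset_id}.mtz"
            write_reflections_mtz(rs, rpath)
        else:
            raise ValueError(f"unknown format {format!r}")
        mpath = out_dir / f"{cm.dataset_id}.pdb"
        write_model_pdb(cm, mpath, cell=rs.cell)
        rows.append((rs.dataset_id, rpath.name, mpath.name))
    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("dataset_id\treflections\tmodel\n")
        for did, r, m in sorted(rows):
            fh.write(f"{did}\t{r}\t{m}\n")
    if result.labels:
        with open(out_dir / "labels.tsv", "w") as fh:
            fh.write("dataset_id\tlabel\n")
            for did in sorted(result.labels):
                fh.write(f"{did}\t{result.labels[did]}\n")
    if result.flipped:
        with open(out_dir / "flipped.txt", "w") as fh:
            fh.writelines(f"{d}\n" for d in sorted(result.flipped))
    return manifest


def read_fixture(manifest: str | Path) -> MultiDataSet:
    """Load a multi-data set from a manifest written by :func:`write_fixture`."""
    manifest = Path(manifest)
    if manifest.is_dir():
        manifest = manifest / "manifest.tsv"
    base = manifest.parent
    entries = []
    with open(manifest) as fh:
        header = fh.readline()
        if not header.startswith("dataset_id"):
            raise ValueError(f"{manifest}: expected manifest header")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            did, rname, mname = line.split("\t")[:3]
            rs = read_reflections(base / rname, dataset_id=did)
            cm = read_model(base / mname, dataset_id=did)
            entries.append((rs, cm))
    return MultiDataSet(entries)
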