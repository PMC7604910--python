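"""Cluster assignment, recursive subclustering, outlier removal,
symmetry-frame collapse and indexing-ambiguity resolution.

The embedding produced by the SVD of the correlation matrix is partitioned
either by deterministic k-means (the scriptable replacement for manual
selection in a 3D viewer) or by an explicit assignment file reproducing a
manual selection. Partitions are recorded in a ``ClusterNode`` tree whose
nodes remember the comparison mode, the axes used and whether the average
set was recalculated for that node — so any node can be subclustered again
on a recalculated or inherited average, or marked complete.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from sklearn.cluster import KMeans

from .averaging import (
    AverageAmplitudes,
    AverageCoordinates,
    average_amplitudes,
    average_coordinates,
)
from .correlation import AxisProjection, build_matrix, project_axes, svd_decompose
from .formats import CoordinateModel, MultiDataSet, ReflectionSet

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterNode",
    "SymmetryOperator",
    "assign_clusters",
    "cluster_multidataset",
    "subcluster",
    "remove_outliers",
    "collapse_symmetry",
    "operators_from_spacegroup",
    "parse_index_op",
    "index_op_triplet",
    "apply_index_op",
    "resolve_indexing",
]


@dataclass
class ClusterNode:
    """One node of the recursive partition.

    ``id`` is the path-like identifier (root, root-0, root-0-1, ...);
    ``members`` the dataset_ids at this node; ``mode``/``axes``/
    ``average_policy`` record how the node's children were derived;
    ``complete`` marks a node exempt from further subdivision.
    """

    id: str
    members: list[str]
    mode: str | None = None
    axes: tuple[int, int, int] | None = None
    average_policy: str | None = None
    complete: bool = False
    children: list["ClusterNode"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.complete and self.children:
            raise ValueError(f"node {self.id}: complete nodes cannot have children")
        seen: set[str] = set()
        parent = set(self.members)
        for child in self.children:
            cm = set(child.members)
            if not cm <= parent:
                raise ValueError(f"node {child.id}: members not a subset of parent")
            if cm & seen:
                raise ValueError(f"node {child.id}: members overlap a sibling")
            seen |= cm

    def leaves(self) -> list["ClusterNode"]:
        if not self.children:
            return [self]
        out: list[ClusterNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "members": sorted(self.members),
            "mode": self.mode,
            "axes": list(self.axes) if self.axes is not None else None,
            "average_policy": self.average_policy,
            "complete": self.complete,
            "children": [c.to_dict() for c in self.children],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterNode":
        return cls(
            id=d["id"],
            members=list(d["members"]),
            mode=d.get("mode"),
            axes=tuple(d["axes"]) if d.get("axes") else None,
            average_policy=d.get("average_policy"),
            complete=bool(d.get("complete", False)),
            children=[cls.from_dict(c) for c in d.get("children", [])],
        )


@dataclass
class SymmetryOperator:
    """Crystallographic operation in the fractional frame: x' = R x + t."""

    rotation: np.ndarray
    translation: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        det = np.linalg.det(self.rotation)
        if not np.isclose(abs(det), 1.0):
            raise ValueError(f"operator {self.name or self.rotation}: |det| must be 1, got {det}")

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.rotation, np.eye(3)) and np.allclose(self.translation, 0.0)


def operators_from_spacegroup(symbol: str) -> list[SymmetryOperator]:
    """Standard symmetry operators of a space group (identity first)."""
    sg = gemmi.SpaceGroup(symbol)
    ops = []
    for op in sg.operations():
        ops.append(
            SymmetryOperator(
                rotation=np.array(op.rot, dtype=np.float64) / op.DEN,
                translation=np.array(op.tran, dtype=np.float64) / op.DEN,
                name=op.triplet(),
            )
        )
    ops.sort(key=lambda o: not o.is_identity)
    return ops


# ---------------------------------------------------------------------------
# flat assignment and recursion


def _relabel_deterministic(labels: dict[str, int]) -> dict[str, int]:
    """Relabel clusters by descending size, ties by lexicographic first member."""
    groups: dict[int, list[str]] = {}
    for did, lab in labels.items():
        groups.setdefault(lab, []).append(did)
    order = sorted(groups, key=lambda g: (-len(groups[g]), min(groups[g])))
    remap = {old: new for new, old in enumerate(order)}
    return {did: remap[lab] for did, lab in labels.items()}


def assign_clusters(
    proj: AxisProjection,
    method: str = "kmeans",
    k: int | None = None,
    path: str | Path | None = None,
    seed: int = 0,
) -> dict[str, int]:
    """Partition the 3D embedding into a flat labelling.

    ``kmeans``: scikit-learn k-means with ``n_init=10`` and a fixed seed;
    labels are renumbered by descending cluster size (ties by lexicographic
    first member) so identical inputs give identical labels.
    ``file``: read an explicit ``dataset_id <tab> label`` table, supporting
    a manually curated selection.
    """
    if method == "kmeans":
        if k is None or k < 1:
            raise ValueError("kmeans requires k >= 1")
        if k > len(proj.labels):
            raise ValueError(f"k={k} exceeds the {len(proj.labels)} data sets")
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        raw = km.fit_predict(proj.s)
        return _relabel_deterministic(dict(zip(proj.labels, (int(x) for x in raw))))
    if method == "file":
        if path is None:
            raise ValueError("file method requires a path")
        table: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("dataset_id"):
                    continue
                did, lab = line.split("\t")[:2]
                table[did] = int(lab)
        missing = set(proj.labels) - set(table)
        if missing:
            raise ValueError(f"assignment file missing ids: {sorted(missing)}")
        return {did: table[did] for did in proj.labels}
    raise ValueError(f"unknown assignment method {method!r}")


def cluster_multidataset(
    mds: MultiDataSet,
    mode: str = "reciprocal",
    k: int = 2,
    seed: int = 0,
    axes: tuple[int, int, int] | None = None,
    min_common: int = 10,
    avg=None,
    node_id: str = "root",
    weight_axes: bool = True,
) -> tuple[ClusterNode, AxisProjection]:
    """One level of clustering: matrix -> SVD -> projection -> k-means.

    Returns the parent node with one child per cluster, plus the embedding.
    The reflection sets are used as given (scale beforehand for reciprocal
    mode); ``avg`` may carry a precomputed (possibly inherited) average.
    By default the embedding columns fed to k-means are weighted by their
    singular values: k-means is scale-sensitive, and raw orthonormal
    columns would give a noise axis the same leverage as a heavily
    weighted signal axis.
    """
    cm = build_matrix(mds, mode=mode, avg=avg, min_common=min_common)
    svd = svd_decompose(cm)
    proj = project_axes(svd, cm.labels, axes=axes, weight=weight_axes)
    labels = assign_clusters(proj, method="kmeans", k=k, seed=seed)
    node = ClusterNode(
        id=node_id,
        members=list(mds.dataset_ids),
        mode=mode,
        axes=proj.axes,
        average_policy="recalculated" if avg is None else "supplied",
    )
    for lab in sorted(set(labels.values())):
        members = sorted(d for d, l in labels.items() if l == lab)
        node.children.append(ClusterNode(id=f"{node_id}-{lab}", members=members))
    return node, proj


def subcluster(
    node: ClusterNode,
    mds: MultiDataSet,
    mode: str = "reciprocal",
    k: int = 2,
    seed: int = 0,
    average_policy: str = "recalculate",
    parent_avg=None,
    min_cluster_size: int = 3,
    axes: tuple[int, int, int] | None = None,
    min_common: int = 10,
) -> ClusterNode:
    """Re-cluster one node's members, appending children.

    With ``average_policy="recalculate"`` the average set (and, in
    reciprocal mode, the shell scaling) is rebuilt over the subset, so
    subtler variation within the subset dominates the new axes; with
    ``"inherit"`` the parent's average is reused. Subsets smaller than
    ``2 * min_cluster_size`` are marked complete instead.
    """
    if node.complete:
        raise ValueError(f"node {node.id} is marked complete")
    subset = mds.subset(node.members)
    if subset.n < 2 * min_cluster_size:
        logger.warning("node %s: only %d members; marking complete", node.id, subset.n)
        node.complete = True
        return node
    if average_policy == "recalculate":
        avg = None
        if mode == "reciprocal":
            from .averaging import scale_all
            scaled = scale_all(subset.reflection_sets)
            subset = MultiDataSet(list(zip(scaled, subset.models)))
    elif average_policy == "inherit":
        avg = parent_avg
    else:
        raise ValueError(f"unknown average_policy {average_policy!r}")
    new_node, _ = cluster_multidataset(
        subset, mode=mode, k=k, seed=seed, axes=axes,
        min_common=min_common, avg=avg, node_id=node.id,
    )
    node.mode = mode
    node.axes = new_node.axes
    node.average_policy = "recalculated" if average_policy == "recalculate" else "inherited"
    node.children = new_node.children
    return node


# ---------------------------------------------------------------------------
# outliers


def remove_outliers(
    models: list[CoordinateModel],
    avg: AverageCoordinates,
    threshold_mads: float = 5.0,
    mad_floor: float = 0.1,
) -> tuple[list[CoordinateModel], list[CoordinateModel]]:
    """Drop models whose C-alpha trace deviates grossly from the average.

    Per model the score is the mean Euclidean deviation of its atoms from
    the average positions; models scoring above
    median + threshold_mads * max(MAD, mad_floor) are removed. The floor
    (0.1 A) keeps degenerate all-identical inputs from flagging everything.
    Averages should be recomputed afterwards, free of outlier bias.
    """
    if len(models) < 3:
        raise ValueError("outlier removal needs at least 3 models")
    scores = []
    for cm in models:
        pos = avg.positions_of(cm.atom_keys)
        ok = pos >= 0
        dev = np.linalg.norm(cm.coords[ok] - avg.cbar[pos[ok]], axis=1)
        scores.append(float(dev.mean()) if len(dev) else np.inf)
    scores_arr = np.array(scores)
    med = float(np.median(scores_arr))
    mad = float(np.median(np.abs(scores_arr - med)))
    cut = med + threshold_mads * max(mad, mad_floor)
    kept = [cm for cm, s in zip(models, scores) if s <= cut]
    removed = [cm for cm, s in zip(models, scores) if s > cut]
    for cm, s in zip(models, scores):
        if s > cut:
            logger.warning("model %s removed as outlier (score %.3f A > %.3f A)",
                           cm.dataset_id, s, cut)
    return kept, removed


# ---------------------------------------------------------------------------
# symmetry collapse


def _apply_symop(cm: CoordinateModel, op: SymmetryOperator, cell) -> CoordinateModel:
    """Apply a fractional-frame operator to an orthogonal-frame model."""
    gc = gemmi.UnitCell(*cell)
    frac_mat = np.array(gc.frac.mat.tolist())
    orth_mat = np.array(gc.orth.mat.tolist())
    frac = cm.coords @ frac_mat.T
    moved = frac @ op.rotation.T + op.translation
    return cm.replace(coords=moved @ orth_mat.T)


def collapse_symmetry(
    models: list[CoordinateModel],
    operators: list[SymmetryOperator],
    cell,
    max_rounds: int = 5,
) -> tuple[list[CoordinateModel], dict[str, str]]:
    """Bring all models into one symmetry frame.

    Data sets refined in symmetry-related frames make the naive coordinate
    average meaningless: the average of the mixed frames is itself nearly
    invariant under the offending operator, so it cannot discriminate
    frames. The first model therefore anchors the target frame: every model
    adopts the operator minimising its mean C-alpha deviation to that
    anchor, then choices are refined against the recomputed average until
    they stop changing (at most ``max_rounds`` rounds; ties break by
    operator list order, identity first by convention).

    Returns the collapsed models and the operator name chosen per data set
    (cumulative, relative to the input frame).
    """
    if not operators:
        raise ValueError("at least one operator (identity) is required")
    if not any(op.is_identity for op in operators):
        raise ValueError("operator list must include the identity")

    transformed = {
        op.name or str(i): [_apply_symop(cm, op, cell) for cm in models]
        for i, op in enumerate(operators)
    }
    op_names = list(transformed)

    def mean_dev(cm: CoordinateModel, ref: AverageCoordinates) -> float:
        pos = ref.positions_of(cm.atom_keys)
        ok = pos >= 0
        if not np.any(ok):
            return np.inf
        return float(np.linalg.norm(cm.coords[ok] - ref.cbar[pos[ok]], axis=1).mean())

    anchor = average_coordinates([models[0]])
    choices = [0] * len(models)
    ref = anchor
    for _ in range(max_rounds):
        new_choices = []
        for i in range(len(models)):
            devs = [mean_dev(transformed[name][i], ref) for name in op_names]
            new_choices.append(int(np.argmin(devs)))  # argmin: first minimum wins ties
        collapsed = [transformed[op_names[c]][i] for i, c in enumerate(new_choices)]
        ref = average_coordinates(collapsed)
        if new_choices == choices:
            break
        choices = new_choices
    chosen = {models[i].dataset_id: op_names[choices[i]] for i in range(len(models))}
    collapsed = [transformed[op_names[choices[i]]][i] for i in range(len(models))]
    return collapsed, chosen


# ---------------------------------------------------------------------------
# indexing-ambiguity resolution


def parse_index_op(triplet: str) -> np.ndarray:
    """Integer matrix of an index remapping such as ``"k,h,-l"``.

    Returns R with (h', k', l') = R @ (h, k, l); |det R| must be 1.
    """
    symbols = {"h": 0, "k": 1, "l": 2}
    rows = []
    for term in triplet.replace(" ", "").lower().split(","):
        row = [0, 0, 0]
        sign, sym = 1, None
        for ch in term:
            if ch == "-":
                sign = -1
            elif ch == "+":
                sign = 1
            elif ch in symbols:
                row[symbols[ch]] = sign
                sign = 1
                sym = ch
            else:
                raise ValueError(f"cannot parse index triplet {triplet!r}")
        if sym is None:
            raise ValueError(f"cannot parse index triplet {triplet!r}")
        rows.append(row)
    mat = np.array(rows, dtype=np.int64)
    if mat.shape != (3, 3) or abs(round(np.linalg.det(mat))) != 1:
        raise ValueError(f"index remapping {triplet!r} is not bijective")
    return mat


def index_op_triplet(mat: np.ndarray) -> str:
    """Inverse of :func:`parse_index_op` for reporting."""
    syms = "hkl"
    terms = []
    for row in np.asarray(mat, dtype=np.int64):
        parts = []
        for coef, sym in zip(row, syms):
            if coef == 0:
                continue
            parts.append(("-" if coef < 0 else ("+" if parts else "")) + sym * abs(int(coef)))
        terms.append("".join(parts) if parts else "0")
    return ",".join(terms)


def apply_index_op(rs: ReflectionSet, op: np.ndarray) -> ReflectionSet:
    """Remap every Miller index: hkl' = R @ hkl."""
    op = np.asarray(op, dtype=np.int64).reshape(3, 3)
    if abs(round(np.linalg.det(op))) != 1:
        raise ValueError("index remapping must have |det| = 1")
    return rs.replace(hkl=rs.hkl @ op.T)


def _plain_pearson_vs_avg(rs: ReflectionSet, avg: AverageAmplitudes) -> tuple[float, int]:
    """Unclamped Pearson of a set's amplitudes against the average (common indices)."""
    pos = avg.positions_of(rs.hkl)
    ok = pos >= 0
    n = int(ok.sum())
    if n < 2:
        return -np.inf, n
    x = rs.f[ok]
    y = avg.fbar[pos[ok]]
    dx, dy = x - x.mean(), y - y.mean()
    sx, sy = np.sqrt(dx @ dx), np.sqrt(dy @ dy)
    if sx == 0 or sy == 0:
        return -np.inf, n
    return float(dx @ dy / (sx * sy)), n


def resolve_indexing(
    sets: list[ReflectionSet],
    twin_ops: list[np.ndarray | str],
    min_common: int = 10,
    max_iter: int = 10,
) -> tuple[list[ReflectionSet], "pd.DataFrame"]:
    """Bring every data set onto one consistent indexing convention.

    In lattices with an indexing ambiguity, each candidate remapping is
    scored by the plain (sign-carrying) Pearson correlation of the set's
    amplitudes against the current average over their common indices; the
    best remapping is adopted, the average recomputed from the adopted
    orientations, and the loop repeated until the choice vector reaches a
    fixed point (cap ``max_iter``). Remappings with too few common indices
    are skipped with a warning.

    Returns the reindexed sets and a per-set report (chosen cumulative
    operator, correlation before and after).
    """
    import pandas as pd

    ops = []
    for op in twin_ops:
        mat = parse_index_op(op) if isinstance(op, str) else np.asarray(op, dtype=np.int64)
        if abs(round(np.linalg.det(mat))) != 1:
            raise ValueError("index remapping must have |det| = 1")
        ops.append(mat)
    if not any(np.array_equal(m, np.eye(3, dtype=np.int64)) for m in ops):
        raise ValueError("twin_ops must include the identity")

    current = list(sets)
    cumulative = [np.eye(3, dtype=np.int64) for _ in sets]
    avg0 = average_amplitudes(current)
    before = [_plain_pearson_vs_avg(rs, avg0)[0] for rs in current]

    for _ in range(max_iter):
        avg = average_amplitudes(current)
        changed = False
        new_sets, new_cum = [], []
        for rs, cum in zip(current, cumulative):
            best_r, best_i = -np.inf, 0
            for i, mat in enumerate(ops):
                cand = rs if i == 0 and np.array_equal(mat, np.eye(3, dtype=np.int64)) \
                    else apply_index_op(rs, mat)
                r, ncom = _plain_pearson_vs_avg(cand, avg)
                if ncom < min_common:
                    logger.warning("%s: op %s has only %d common reflections; skipped",
                                   rs.dataset_id, index_op_triplet(mat), ncom)
                    continue
                if r > best_r:
                    best_r, best_i = r, i
            mat = ops[best_i]
            if not np.array_equal(mat, np.eye(3, dtype=np.int64)):
                changed = True
                new_sets.append(apply_index_op(rs, mat))
                new_cum.append(mat @ cum)
            else:
                new_sets.append(rs)
                new_cum.append(cum)
        current, cumulative = new_sets, new_cum
        if not changed:
            break

    avg_final = average_amplitudes(current)
    after = [_plain_pearson_vs_avg(rs, avg_final)[0] for rs in current]
    report = pd.DataFrame(
        {
            "dataset_id": [rs.dataset_id for rs in sets],
            "chosen_op": [index_op_triplet(c) for c in cumulative],
            "correlation_before": before,
            "correlation_after": after,
        }
    )
    return current, report
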