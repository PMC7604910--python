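"""End-to-end pipeline: cutoff -> average -> scale -> (reindex) ->
correlate -> embed -> assign -> (subcluster), with deterministic file outputs.

The stage order follows the method's logic: averages are first built from
unscaled amplitudes, each data set is scaled onto them in equal-volume
resolution shells, and the average is refreshed once from the scaled sets
so first-order B-factor bias does not leak into the difference series.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .averaging import (
    DEFAULT_D_MIN,
    DEFAULT_N_BINS,
    apply_resolution_cutoff,
    average_amplitudes,
    average_coordinates,
    build_shells,
    scale_dataset,
)
from .cluster import (
    ClusterNode,
    collapse_symmetry,
    cluster_multidataset,
    operators_from_spacegroup,
    remove_outliers,
    resolve_indexing,
    subcluster,
)
from .correlation import build_matrix, render_matrix
from .formats import MultiDataSet, write_partition
from .simulate import read_fixture

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Effective parameters of one clustering run.

    Defaults follow the method's stated conventions: 3.5 A resolution
    cutoff and 20 equal-volume shells. ``k`` (the number of clusters) is a
    user decision; a silhouette suggestion is logged but never applied.
    """

    manifest: str | None = None
    out_dir: str | None = None
    d_min: float = DEFAULT_D_MIN
    n_bins: int = DEFAULT_N_BINS
    mode: str = "reciprocal"
    axes: tuple[int, int, int] | None = None
    weight_axes: bool = True
    k: int = 2
    seed: int = 0
    min_common: int = 10
    refresh_average: bool = True
    reindex_ops: list[str] = field(default_factory=list)
    outlier_threshold: float | None = None
    space_group: str | None = None
    max_depth: int = 1
    k_sub: int | None = None
    sub_mode: str | None = None
    average_policy: str = "recalculate"
    min_cluster_size: int = 3
    render: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["axes"] = list(self.axes) if self.axes is not None else None
        return d


@dataclass
class PipelineResult:
    tree: ClusterNode
    labels: dict[str, int]
    embedding: np.ndarray
    embedding_labels: list[str]
    matrix: "object"
    svd_weights: np.ndarray
    scaled: MultiDataSet
    reindex_report: "object | None" = None
    removed_outliers: list[str] = field(default_factory=list)


def _silhouette_hint(s: np.ndarray, seed: int) -> None:
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    best_k, best_val = None, -1.0
    for k in range(2, min(9, len(s))):
        lab = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(s)
        val = silhouette_score(s, lab)
        if val > best_val:
            best_k, best_val = k, val
    if best_k is not None:
        logger.info("silhouette suggests k = %d (score %.3f); not applied", best_k, best_val)


def run_pipeline(config: RunConfig, mds: MultiDataSet | None = None) -> PipelineResult:
    """Run the full clustering pipeline on a multi-data set.

    ``mds`` may be passed directly (e.g. from the synthetic generator);
    otherwise it is loaded from ``config.manifest``. When ``config.out_dir``
    is set, partition files, the embedding, the matrix (TSV and image),
    diagnostic tables and a provenance record are written there.
    """
    if mds is None:
        if config.manifest is None:
            raise ValueError("either a manifest or an in-memory multi-data set is required")
        mds = read_fixture(config.manifest)
    if mds.n < 2:
        raise ValueError("N >= 2 data sets required")

    # resolution cutoff
    cut = [apply_resolution_cutoff(rs, config.d_min) for rs in mds.reflection_sets]
    models = list(mds.models)

    # optional indexing-ambiguity resolution
    reindex_report = None
    if config.reindex_ops:
        cut, reindex_report = resolve_indexing(cut, ["h,k,l"] + list(config.reindex_ops),
                                               min_common=config.min_common)

    # scaling: average (unscaled) -> per-set shell scaling -> refreshed average
    avg0 = average_amplitudes(cut)
    shells = build_shells(cut, n_bins=config.n_bins)
    scaled_sets, scale_table = [], []
    for rs in cut:
        scaled, k = scale_dataset(rs, avg0, shells, return_scales=True)
        scaled_sets.append(scaled)
        scale_table.append(k)
    avg_f = average_amplitudes(scaled_sets) if config.refresh_average else avg0

    # optional outlier removal on the coordinate models
    removed_ids: list[str] = []
    if config.outlier_threshold is not None and len(models) >= 3:
        kept, removed = remove_outliers(models, average_coordinates(models),
                                        threshold_mads=config.outlier_threshold)
        removed_ids = [cm.dataset_id for cm in removed]
        if removed_ids:
            keep_ids = {cm.dataset_id for cm in kept}
            scaled_sets = [rs for rs in scaled_sets if rs.dataset_id in keep_ids]
            models = kept

    # optional symmetry collapse into a common frame
    if config.space_group is not None and models:
        ops = operators_from_spacegroup(config.space_group)
        cell = scaled_sets[0].cell
        models, _ = collapse_symmetry(models, ops, cell)

    work = MultiDataSet(list(zip(scaled_sets, models)))
    avg = avg_f if config.mode == "reciprocal" else average_coordinates(models)

    tree, proj = cluster_multidataset(
        work, mode=config.mode, k=config.k, seed=config.seed,
        axes=config.axes, min_common=config.min_common, avg=avg,
        weight_axes=config.weight_axes,
    )
    matrix = build_matrix(work, mode=config.mode, avg=avg, min_common=config.min_common)
    svd_w = np.linalg.svd(matrix.matrix, compute_uv=False)
    _silhouette_hint(proj.s, config.seed)

    # recursive subclustering
    if config.max_depth > 1:
        k_sub = config.k_sub or config.k
        sub_mode = config.sub_mode or config.mode

        def recurse(node: ClusterNode, depth: int) -> None:
            if depth >= config.max_depth:
                return
            for child in node.children:
                if len(child.members) < 2 * config.min_cluster_size:
                    child.complete = True
                    continue
                subcluster(child, work, mode=sub_mode, k=k_sub, seed=config.seed,
                           average_policy=config.average_policy,
                           min_cluster_size=config.min_cluster_size,
                           min_common=config.min_common)
                recurse(child, depth + 1)

        recurse(tree, 1)

    labels = {}
    for leaf in tree.leaves():
        for did in leaf.members:
            labels[did] = leaf.id

    result = PipelineResult(
        tree=tree,
        labels=labels,
        embedding=proj.s,
        embedding_labels=proj.labels,
        matrix=matrix,
        svd_weights=svd_w,
        scaled=work,
        reindex_report=reindex_report,
        removed_outliers=removed_ids,
    )

    if config.out_dir is not None:
        _write_outputs(config, result, shells, scale_table, cut)
    return result


def _write_outputs(config: RunConfig, result: PipelineResult, shells, scale_table, cut) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_partition(result.tree, out)

    with open(out / "embedding.tsv", "w") as fh:
        fh.write("dataset_id\ts1\ts2\ts3\n")
        for did, row in sorted(zip(result.embedding_labels, result.embedding)):
            fh.write(f"{did}\t{row[0] + 0.0:.12g}\t{row[1] + 0.0:.12g}\t{row[2] + 0.0:.12g}\n")

    with open(out / "matrix.tsv", "w") as fh:
        fh.write("\t" + "\t".join(result.matrix.labels) + "\n")
        for lab, row in zip(result.matrix.labels, result.matrix.matrix):
            fh.write(lab + "\t" + "\t".join(f"{x:.12g}" for x in row) + "\n")

    with open(out / "svd_weights.tsv", "w") as fh:
        fh.write("axis\tweight\n")
        for i, w in enumerate(result.svd_weights):
            fh.write(f"{i}\t{w:.12g}\n")

    with open(out / "shells.tsv", "w") as fh:
        fh.write("bin\tr_lo\tr_hi\t" + "\t".join(rs.dataset_id for rs in cut) + "\n")
        for b in range(shells.n_bins):
            ks = "\t".join(f"{scale_table[i][b]:.12g}" for i in range(len(cut)))
            fh.write(f"{b}\t{shells.boundaries[b]:.12g}\t{shells.boundaries[b + 1]:.12g}\t{ks}\n")

    if result.reindex_report is not None:
        result.reindex_report.to_csv(out / "reindex_report.tsv", sep="\t", index=False)
    if result.removed_outliers:
        (out / "removed_outliers.txt").write_text(
            "".join(f"{d}\n" for d in sorted(result.removed_outliers)))

    if config.render:
        render_matrix(result.matrix, out / "matrix.png", tree=result.tree)

    provenance = {"tool": "xtalcluster", "version": __version__, "config": config.to_dict()}
    with open(out / "provenance.yaml", "w") as fh:
        yaml.safe_dump(provenance, fh, sort_keys=True)
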