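"""Estimator-style front ends for the scaling and clustering stages.

These follow scikit-learn conventions (constructor parameters mirrored by
``get_params``/``set_params``, fitted state in trailing-underscore
attributes, ``fit``/``transform``/``fit_predict``) so runs compose with
sklearn tooling, while accepting the package's domain containers
(lists of :class:`~xtalcluster.formats.ReflectionSet`, or a
:class:`~xtalcluster.formats.MultiDataSet`) instead of numeric matrices.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin

from .averaging import (
    DEFAULT_D_MIN,
    DEFAULT_N_BINS,
    apply_resolution_cutoff,
    average_amplitudes,
    average_coordinates,
    build_shells,
    scale_dataset,
)
from .cluster import assign_clusters
from .correlation import build_matrix, project_axes, svd_decompose
from .formats import MultiDataSet, ReflectionSet

__all__ = ["ShellScaler", "MultiDatasetClusterer"]


class ShellScaler(BaseEstimator, TransformerMixin):
    """Equal-volume resolution-shell scaling onto a multi-data-set average.

    ``fit`` applies the resolution cutoff, builds the average amplitudes
    and the shell geometry from the training sets; ``transform`` rescales
    any list of reflection sets shell-by-shell onto that average, removing
    per-data-set global isotropic B-factor damping.

    Parameters
    ----------
    d_min : float
        Resolution cutoff in Angstrom (default 3.5).
    n_bins : int
        Number of equal-volume shells (default 20).

    Attributes
    ----------
    average_ : AverageAmplitudes
        Mean amplitude per Miller index over the training sets.
    shells_ : ShellBinning
        Global equal-volume shell boundaries.
    scales_ : (n_sets, n_bins) ndarray
        Per-shell scale factors of the most recent ``transform``.
    """

    def __init__(self, d_min: float = DEFAULT_D_MIN, n_bins: int = DEFAULT_N_BINS):
        self.d_min = d_min
        self.n_bins = n_bins

    def fit(self, X: list[ReflectionSet], y=None) -> "ShellScaler":
        cut = [apply_resolution_cutoff(rs, self.d_min) for rs in X]
        self.average_ = average_amplitudes(cut)
        self.shells_ = build_shells(cut, n_bins=self.n_bins)
        return self

    def transform(self, X: list[ReflectionSet]) -> list[ReflectionSet]:
        if not hasattr(self, "average_"):
            raise RuntimeError("ShellScaler must be fitted before transform")
        out, scales = [], []
        for rs in X:
            scaled, k = scale_dataset(apply_resolution_cutoff(rs, self.d_min),
                                      self.average_, self.shells_, return_scales=True)
            out.append(scaled)
            scales.append(k)
        self.scales_ = np.array(scales)
        return out


class MultiDatasetClusterer(BaseEstimator, ClusterMixin):
    """Correlation-of-difference-series clustering of a multi-data set.

    ``fit`` runs cutoff, shell scaling (reciprocal mode), the bounded
    Pearson correlation matrix over difference series, its SVD, projection
    onto three axes and deterministic k-means — one level of the recursive
    procedure.

    Parameters
    ----------
    mode : {"reciprocal", "realspace"}
        Compare scaled amplitude deviations or C-alpha deviations.
    n_clusters : int
        Number of clusters (a user decision, as in the manual workflow).
    d_min, n_bins : float, int
        Scaling parameters (reciprocal mode).
    axes : 3-tuple of int, optional
        SVD axes for the embedding; default the three largest weights.
    weight_axes : bool
        Multiply embedding columns by their singular values.
    min_common : int
        Shared observations below which a pair's coefficient is 0.
    refresh_average : bool
        Rebuild the amplitude average from the scaled sets before
        correlating (removes first-order B-factor bias from F-bar).
    random_state : int
        Seed for k-means.

    Attributes
    ----------
    labels_ : (N,) int ndarray
        Cluster label per data set, in input order.
    label_map_ : dict
        dataset_id -> label.
    embedding_ : (N, 3) ndarray
        SVD-axis coordinates per data set.
    matrix_ : CorrelationMatrix
        The bounded-coefficient matrix.
    svd_weights_ : (N,) ndarray
        Singular values, descending.
    """

    def __init__(
        self,
        mode: str = "reciprocal",
        n_clusters: int = 2,
        d_min: float = DEFAULT_D_MIN,
        n_bins: int = DEFAULT_N_BINS,
        axes: tuple[int, int, int] | None = None,
        weight_axes: bool = True,
        min_common: int = 10,
        refresh_average: bool = True,
        random_state: int = 0,
    ):
        self.mode = mode
        self.n_clusters = n_clusters
        self.d_min = d_min
        self.n_bins = n_bins
        self.axes = axes
        self.weight_axes = weight_axes
        self.min_common = min_common
        self.refresh_average = refresh_average
        self.random_state = random_state

    def fit(self, X: MultiDataSet, y=None) -> "MultiDatasetClusterer":
        if not isinstance(X, MultiDataSet):
            raise TypeError("X must be a MultiDataSet")
        if X.n < 2:
            raise ValueError("N >= 2 data sets required")
        if self.mode == "reciprocal":
            scaler = ShellScaler(d_min=self.d_min, n_bins=self.n_bins).fit(X.reflection_sets)
            scaled = scaler.transform(X.reflection_sets)
            avg = average_amplitudes(scaled) if self.refresh_average else scaler.average_
            work = MultiDataSet(list(zip(scaled, X.models)))
            self.scaler_ = scaler
        elif self.mode == "realspace":
            avg = average_coordinates(X.models)
            work = X
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        self.average_ = avg
        self.matrix_ = build_matrix(work, mode=self.mode, avg=avg,
                                    min_common=self.min_common)
        svd = svd_decompose(self.matrix_)
        self.svd_weights_ = svd.w
        proj = project_axes(svd, self.matrix_.labels, axes=self.axes,
                            weight=self.weight_axes)
        self.embedding_ = proj.s
        self.label_map_ = assign_clusters(proj, method="kmeans", k=self.n_clusters,
                                          seed=self.random_state)
        self.labels_ = np.array([self.label_map_[d] for d in X.dataset_ids])
        return self

    def fit_predict(self, X: MultiDataSet, y=None) -> np.ndarray:
        return self.fit(X).labels_
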