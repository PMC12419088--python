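"""Resampling consensus clustering of ablated layers and marker annotation.

Layer clusters are defined on control samples: samples are repeatedly
subsampled, hierarchically clustered, and the fraction of co-clusterings
among co-selections forms the consensus matrix (Monti-style consensus
clustering).  The number of clusters is chosen by the relative change of the
area under the consensus CDF, taking the smallest k within 5% of the largest
relative gain.  Anatomical identity of the resulting clusters is annotated
with skin/bone/meninges/cortex marker panels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics.pairwise import nan_euclidean_distances

from .simulate import DEFAULT_MARKER_PANELS

logger = logging.getLogger(__name__)


def consensus_cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of the off-diagonal consensus entries."""
    n = consensus.shape[0]
    vals = np.sort(consensus[np.triu_indices(n, k=1)])
    if vals.size == 0:
        return 0.0
    # A = sum (x_i - x_{i-1}) * CDF(x_{i-1}), evaluated over unique values
    uniq, counts = np.unique(vals, return_counts=True)
    cdf = np.cumsum(counts) / vals.size
    if uniq[0] > 0:
        uniq = np.concatenate([[0.0], uniq])
        cdf = np.concatenate([[0.0], cdf])
    if uniq[-1] < 1:
        uniq = np.concatenate([uniq, [1.0]])
        cdf = np.concatenate([cdf, [cdf[-1]]])
    return float(np.sum(np.diff(uniq) * cdf[:-1]))


class ConsensusClustering(BaseEstimator, ClusterMixin):
    """Monti-style consensus clustering over subsampled hierarchical runs.

    Parameters
    ----------
    k_range : candidate cluster numbers (each must be < n_samples).
    n_resamples : subsampling repetitions per k.
    subsample_fraction : fraction of samples drawn (without replacement).
    linkage_method : scipy linkage method for the inner clustering.
    min_feature_validity : features observed in fewer samples are dropped
        before the (pairwise-complete Euclidean) distance computation.
    elbow_tolerance : the selected k is the smallest k whose relative
        delta-area is within this fraction of the maximum.

    Fitted attributes: ``consensus_matrices_`` (dict k -> matrix),
    ``areas_``, ``deltas_``, ``selected_k_``, ``labels_``.
    """

    def __init__(self, k_range: Sequence[int] = (2, 3, 4, 5, 6),
                 n_resamples: int = 250, subsample_fraction: float = 0.8,
                 linkage_method: str = "ward",
                 min_feature_validity: float = 0.5,
                 elbow_tolerance: float = 0.05,
                 random_state: int | None = None):
        self.k_range = k_range
        self.n_resamples = n_resamples
        self.subsample_fraction = subsample_fraction
        self.linkage_method = linkage_method
        self.min_feature_validity = min_feature_validity
        self.elbow_tolerance = elbow_tolerance
        self.random_state = random_state

    def fit(self, X, y=None):
        values = np.asarray(X, dtype=float)  # samples x features
        n = values.shape[0]
        ks = sorted(set(int(k) for k in self.k_range))
        if not ks or ks[0] < 2 or ks[-1] > n - 1:
            raise ValueError(f"k_range must lie within [2, {n - 1}]")
        rng = np.random.default_rng(self.random_state)

        obs_frac = np.mean(~np.isnan(values), axis=0)
        values = values[:, obs_frac >= self.min_feature_validity]
        dist = nan_euclidean_distances(values)
        dist = (dist + dist.T) / 2.0
        np.fill_diagonal(dist, 0.0)

        n_sub = max(2, math.ceil(self.subsample_fraction * n))
        # one shared resample schedule across k, as in consensus clustering
        draws = [rng.choice(n, size=n_sub, replace=False)
                 for _ in range(self.n_resamples)]
        coselect = np.zeros((n, n))
        for idx in draws:
            coselect[np.ix_(idx, idx)] += 1.0

        self.consensus_matrices_ = {}
        areas = []
        for k in ks:
            cocluster = np.zeros((n, n))
            for idx in draws:
                sub = dist[np.ix_(idx, idx)]
                Z = linkage(squareform(sub, checks=False), method=self.linkage_method)
                lab = fcluster(Z, k, criterion="maxclust")
                same = lab[:, None] == lab[None, :]
                cocluster[np.ix_(idx, idx)] += same
            with np.errstate(invalid="ignore", divide="ignore"):
                consensus = np.where(coselect > 0, cocluster / coselect, 0.0)
            np.fill_diagonal(consensus, 1.0)
            self.consensus_matrices_[k] = consensus
            areas.append(consensus_cdf_area(consensus))

        deltas = [areas[0]]
        for i in range(1, len(ks)):
            prev = areas[i - 1]
            deltas.append((areas[i] - prev) / prev if prev > 0 else 0.0)
        self.areas_ = dict(zip(ks, areas))
        self.deltas_ = dict(zip(ks, deltas))
        cutoff = (1.0 - self.elbow_tolerance) * max(deltas)
        self.selected_k_ = next(k for k, d in zip(ks, deltas) if d >= cutoff)

        final = self.consensus_matrices_[self.selected_k_]
        Z = linkage(squareform(1.0 - final, checks=False), method="average")
        self.labels_ = fcluster(Z, self.selected_k_, criterion="maxclust")
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass
class LayerClusterResult:
    """Consensus clustering outcome mapped back to layer indices."""

    selected_k: int
    layer_to_cluster: dict[int, int]       # cluster labels 1..k, superficial first
    sample_labels: pd.Series               # per sample cluster label
    consensus_matrices: dict[int, pd.DataFrame]
    areas: dict[int, float]
    deltas: dict[int, float]

    def cluster_layers(self, cluster: int) -> list[int]:
        return sorted(l for l, c in self.layer_to_cluster.items() if c == cluster)


def cluster_layers(matrix: pd.DataFrame, manifest: pd.DataFrame,
                   timepoint: str, model: str = "CTRL",
                   k_range: Sequence[int] = (2, 3, 4, 5, 6),
                   n_resamples: int = 250, subsample_fraction: float = 0.8,
                   random_state: int | None = 0) -> LayerClusterResult:
    """Consensus-cluster the layers of one timepoint from one model's samples.

    Each layer is assigned to the cluster holding the majority of its
    replicate samples; clusters are renumbered by ascending mean layer index
    (cluster 1 = most superficial).  Non-contiguous layer assignments are
    possible in principle and logged as a warning.
    """
    meta = manifest[(~manifest["excluded"])
                    & (manifest["timepoint"] == timepoint)
                    & (manifest["model"] == model)]
    samples = [s for s in meta["sample_id"] if s in matrix.columns]
    if len(samples) < 4:
        raise ValueError("not enough samples for consensus clustering")
    layers = meta.set_index("sample_id").loc[samples, "layer_index"]

    est = ConsensusClustering(k_range=k_range, n_resamples=n_resamples,
                              subsample_fraction=subsample_fraction,
                              random_state=random_state)
    est.fit(matrix[samples].T)
    raw = pd.Series(est.labels_, index=samples)

    vote = {}
    for layer in sorted(layers.unique()):
        labs = raw[layers[layers == layer].index]
        vote[int(layer)] = int(labs.value_counts().idxmax())
    # renumber clusters: superficial-most cluster first
    mean_layer = pd.Series(vote).groupby(pd.Series(vote)).apply(
        lambda s: np.mean(s.index))
    order = {old: new + 1 for new, old in
             enumerate(mean_layer.sort_values().index)}
    layer_map = {l: order[c] for l, c in vote.items()}
    sample_labels = raw.map(lambda c: order.get(c, c)).astype(int)

    for c in set(layer_map.values()):
        ls = sorted(l for l, cc in layer_map.items() if cc == c)
        if ls != list(range(ls[0], ls[-1] + 1)):
            logger.warning("cluster %d covers non-contiguous layers %s", c, ls)

    cons = {k: pd.DataFrame(m, index=samples, columns=samples)
            for k, m in est.consensus_matrices_.items()}
    return LayerClusterResult(selected_k=est.selected_k_,
                              layer_to_cluster=layer_map,
                              sample_labels=sample_labels,
                              consensus_matrices=cons,
                              areas=est.areas_, deltas=est.deltas_)


def marker_panel_profile(matrix: pd.DataFrame, manifest: pd.DataFrame,
                         timepoint: str, model: str = "CTRL",
                         panels: Mapping[str, Sequence[str]] | None = None
                         ) -> pd.DataFrame:
    """Per-layer scaled mean abundance of each marker panel.

    Per panel protein: mean over the replicates of each layer, then z-scaled
    across layers; the panel profile is the mean of its proteins' scaled
    profiles.  Proteins missing from the matrix are skipped with a warning;
    zero-variance proteins contribute 0 by convention.  Rows are layers,
    columns compartments.
    """
    panels = DEFAULT_MARKER_PANELS if panels is None else panels
    meta = manifest[(~manifest["excluded"])
                    & (manifest["timepoint"] == timepoint)
                    & (manifest["model"] == model)]
    samples = [s for s in meta["sample_id"] if s in matrix.columns]
    layers = meta.set_index("sample_id").loc[samples, "layer_index"]
    layer_means = matrix[samples].T.groupby(layers).mean().T  # proteins x layers

    if not any(p in matrix.index for ps in panels.values() for p in ps):
        raise ValueError("no panel protein present in the matrix")

    out = {}
    for compartment, prots in panels.items():
        present = [p for p in prots if p in layer_means.index]
        missing = [p for p in prots if p not in layer_means.index]
        if missing:
            logger.warning("panel %s: proteins absent from matrix: %s",
                           compartment, missing)
        if not present:
            out[compartment] = pd.Series(np.nan, index=layer_means.columns)
            continue
        sub = layer_means.loc[present]
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        z = sub.sub(mu, axis=0).div(sd.where(sd > 0), axis=0).fillna(0.0)
        out[compartment] = z.mean(axis=0)
    profile = pd.DataFrame(out)
    profile.index.name = "layer_index"
    return profile.sort_index()
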