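"""Structural subpopulations of single-cell conformations.

Conformations pooled across cell types are embedded as vectors of all
pairwise bead distances (rigid-motion invariant by construction),
standardized, and clustered with k-means. Cluster summaries report
per-source subpopulation proportions, per-cluster compactness (mean
radius of gyration, clusters reported from most to least compact) and
per-cluster aggregated contact maps.

The cluster count K is user-set; a silhouette scan over a K range is
provided to aid the choice but never auto-selects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.preprocessing import StandardScaler

from .ensemble_analysis import radius_of_gyration
from .null_ensemble import CONTACT_THRESHOLD_NM, ConformationEnsemble

__all__ = [
    "ClusterModel",
    "ClusterSummary",
    "featurize",
    "cluster_conformations",
    "summarize_clusters",
    "silhouette_scan",
]


@dataclass
class ClusterModel:
    K: int
    assignments: np.ndarray  # label per pooled conformation
    sources: np.ndarray      # cell-type tag per pooled conformation
    centers: np.ndarray      # centroids in standardized feature space
    inertia: float
    seed: int | None


@dataclass
class ClusterSummary:
    proportions: dict          # source -> per-cluster fraction vector
    mean_rg: np.ndarray        # per cluster, nm, nondecreasing in report order
    maps: list                 # per-cluster ContactMatrix or None if empty
    order: np.ndarray          # report position -> model label
    notices: list


def featurize(ensemble: ConformationEnsemble) -> np.ndarray:
    """One row per conformation: upper-triangle pairwise bead distances.

    Length n(n-1)/2; invariant to rigid rotation/translation/reflection.
    """
    X = ensemble.coords_array()
    n = X.shape[1]
    iu = np.triu_indices(n, k=1)
    diff = X[:, iu[0], :] - X[:, iu[1], :]
    return np.sqrt((diff ** 2).sum(axis=-1))


def _binary_featurize(ensemble: ConformationEnsemble,
                      threshold: float = CONTACT_THRESHOLD_NM) -> np.ndarray:
    return (featurize(ensemble) < threshold).astype(float)


def cluster_conformations(ensembles: list[tuple[str, ConformationEnsemble]],
                          K: int, seed: int | None = None, n_init: int = 10,
                          features: str = "distances") -> ClusterModel:
    """Pooled k-means over labeled ensembles (one per cell type).

    Features are standardized to zero mean / unit variance over the pooled
    set; ``n_init`` seeded restarts keep the best inertia. Deterministic
    given ``seed``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not ensembles:
        raise ValueError("no ensembles given")
    feats, sources = [], []
    for label, ens in ensembles:
        f = featurize(ens) if features == "distances" else _binary_featurize(ens)
        feats.append(f)
        sources.extend([label] * len(ens))
    F = np.vstack(feats)
    if K > F.shape[0]:
        raise ValueError(f"K={K} exceeds pooled ensemble size {F.shape[0]}")
    Fs = StandardScaler().fit_transform(F)
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed).fit(Fs)
    return ClusterModel(K, km.labels_.copy(), np.array(sources),
                        km.cluster_centers_.copy(), float(km.inertia_), seed)


def summarize_clusters(model: ClusterModel,
                       ensembles: list[tuple[str, ConformationEnsemble]],
                       threshold: float = CONTACT_THRESHOLD_NM) -> ClusterSummary:
    """Proportions, compactness ordering and per-cluster contact maps.

    Clusters are reported in increasing mean radius of gyration (most
    compact first); per-source proportion vectors sum to 1.
    """
    from .null_ensemble import contact_frequency_matrix

    pooled = [c for _, ens in ensembles for c in ens.conformations]
    sources = np.concatenate([[lab] * len(ens) for lab, ens in ensembles])
    if len(pooled) != model.assignments.size:
        raise ValueError("model does not match the given ensembles")
    rg = np.array([radius_of_gyration(c) for c in pooled])
    K = model.K
    mean_rg_by_label = np.full(K, np.inf)
    notices = []
    for k in range(K):
        members = model.assignments == k
        if members.any():
            mean_rg_by_label[k] = rg[members].mean()
        else:
            notices.append(f"cluster {k} is empty: map omitted")
    order = np.argsort(mean_rg_by_label, kind="stable")
    proportions = {}
    for lab, _ in ensembles:
        mask = sources == lab
        counts = np.array([(model.assignments[mask] == order[p]).sum()
                           for p in range(K)], dtype=float)
        proportions[lab] = counts / counts.sum()
    maps = []
    for p in range(K):
        members = np.flatnonzero(model.assignments == order[p])
        if members.size == 0:
            maps.append(None)
            continue
        sub = ConformationEnsemble([pooled[m] for m in members])
        maps.append(contact_frequency_matrix(sub, threshold))
    mean_rg = mean_rg_by_label[order]
    mean_rg = np.where(np.isinf(mean_rg), np.nan, mean_rg)
    return ClusterSummary(proportions, mean_rg, maps, order, notices)


def silhouette_scan(ensembles: list[tuple[str, ConformationEnsemble]],
                    k_range=range(2, 9), seed: int | None = None,
                    n_init: int = 10) -> dict[int, float]:
    """Mean silhouette score per K; a report to aid choosing K, not a selector."""
    feats = np.vstack([featurize(ens) for _, ens in ensembles])
    Fs = StandardScaler().fit_transform(feats)
    scores = {}
    for k in k_range:
        if k >= Fs.shape[0]:
            break
        labels = KMeans(n_clusters=k, n_init=n_init, random_state=seed
                        ).fit_predict(Fs)
        scores[k] = float(silhouette_score(Fs, labels))
    return scores
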