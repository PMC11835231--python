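"""Simulated Hi-C maps, map comparison, baselines and conformation geometry."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genome_io import ContactMatrix
from .null_ensemble import (CONTACT_THRESHOLD_NM, Conformation,
                            ConformationEnsemble, contact_frequency_matrix)

__all__ = [
    "MapComparison",
    "simulate_hic",
    "pearson_map_similarity",
    "distance_decay_baseline",
    "radius_of_gyration",
    "pairwise_distance_summary",
    "contact_decay_curve",
    "decay_monotonicity_violation",
]


@dataclass(frozen=True)
class MapComparison:
    """Pearson similarity between two contact maps over masked entries."""

    pearson_r: float
    n_entries: int
    mask_rule: str = "upper triangle, |i-j| >= 2"


def simulate_hic(ensemble: ConformationEnsemble,
                 threshold: float = CONTACT_THRESHOLD_NM,
                 n_sample: int | None = None,
                 seed: int | None = None) -> ContactMatrix:
    """Aggregate a (sub)sample of single-cell conformations into a contact map.

    With ``n_sample`` None or >= the ensemble size the full weighted ensemble
    is used and the result is deterministic.
    """
    if n_sample is not None:
        ensemble = ensemble.subsample(n_sample, seed=seed)
    return contact_frequency_matrix(ensemble, threshold)


def pearson_map_similarity(a: ContactMatrix, b: ContactMatrix,
                           min_lag: int = 2) -> MapComparison:
    """Pearson correlation over strict upper-triangle entries with |i-j| >= min_lag.

    The diagonal and adjacent entries are near 1 in any polymer map and would
    inflate the correlation, so they are excluded.
    """
    if a.n_beads != b.n_beads:
        raise ValueError("maps have different shapes")
    i, j = np.triu_indices(a.n_beads, k=min_lag)
    x, y = a.values[i, j], b.values[i, j]
    if x.size <= 2:
        raise ValueError("too few entries to correlate")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant map: correlation undefined")
    r, _ = stats.pearsonr(x, y)
    return MapComparison(float(r), int(x.size))


def distance_decay_baseline(observed: ContactMatrix) -> ContactMatrix:
    """Predict each entry by the mean of its genomic-separation diagonal.

    The classic 1D-distance benchmark: information beyond the overall
    contact-decay P(s) curve is discarded.
    """
    n = observed.n_beads
    if n < 4:
        raise ValueError("need at least 4 beads")
    pred = np.zeros((n, n))
    for s in range(1, n):
        pred += np.diag(np.full(n - s, np.diag(observed.values, s).mean()), s)
    pred = pred + pred.T
    np.fill_diagonal(pred, 1.0)
    if observed.kind == "probability":
        np.clip(pred, 0.0, 1.0, out=pred)
        return ContactMatrix(observed.locus, pred, "probability")
    # count maps: per-diagonal mean is generally non-integer; return as
    # probabilities after scaling into [0, 1] is not meaningful here, so
    # normalize by the adjacent-diagonal mean as an expected-contact proxy
    scale = np.diag(observed.values, 1).mean()
    if scale > 0:
        pred = np.minimum(1.0, pred / scale)
    np.fill_diagonal(pred, 1.0)
    return ContactMatrix(observed.locus, pred, "probability")


def radius_of_gyration(conformation: Conformation | np.ndarray) -> float:
    """Root-mean-square bead distance from the centroid (nm)."""
    x = conformation.coords if isinstance(conformation, Conformation) \
        else np.asarray(conformation, dtype=float)
    centered = x - x.mean(axis=0)
    return float(np.sqrt((centered ** 2).sum(axis=1).mean()))


def _weighted_quantiles(values: np.ndarray, weights: np.ndarray,
                        qs=(0.25, 0.5, 0.75)) -> np.ndarray:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    cw /= cw[-1]
    return np.array([v[np.searchsorted(cw, q)] for q in qs])


def pairwise_distance_summary(ensemble: ConformationEnsemble, i: int, j: int,
                              n_sample: int | None = None,
                              seed: int | None = None) -> dict:
    """Weighted median and quartiles (nm) of the bead-pair distance.

    A seeded uniform subsample of ``n_sample`` conformations is used when
    requested, mirroring the practice of summarizing a few thousand cells
    out of a larger ensemble.
    """
    n = ensemble.n_beads
    if not (0 <= i < n and 0 <= j < n):
        raise ValueError(f"bead indices ({i}, {j}) outside [0, {n})")
    if i == j:
        return {"median": 0.0, "q1": 0.0, "q3": 0.0, "n": len(ensemble)}
    if n_sample is not None:
        ensemble = ensemble.subsample(n_sample, seed=seed)
    X = ensemble.coords_array()
    d = np.linalg.norm(X[:, i, :] - X[:, j, :], axis=-1)
    q1, med, q3 = _weighted_quantiles(d, ensemble.weights())
    return {"median": float(med), "q1": float(q1), "q3": float(q3),
            "n": len(ensemble)}


def decay_monotonicity_violation(map_or_ensemble, min_lag: int = 3,
                                 threshold: float = CONTACT_THRESHOLD_NM) -> float:
    """How far P(s) departs from a nonincreasing curve, for s >= min_lag.

    Pair-count-weighted mean absolute distance between the per-lag contact
    probabilities and their best nonincreasing (isotonic) fit. Zero for any
    genuinely decaying map; plateau sampling noise contributes only at the
    per-lag estimator-precision level because lags are weighted by how many
    pairs they average.
    """
    from sklearn.isotonic import IsotonicRegression

    s, p = contact_decay_curve(map_or_ensemble, threshold)
    keep = s >= min_lag
    s, p = s[keep], p[keep]
    n = s.max() + 1
    w = (n - s).astype(float)
    fit = IsotonicRegression(increasing=False).fit(s, p, sample_weight=w)
    return float((w * np.abs(p - fit.predict(s))).sum() / w.sum())


def contact_decay_curve(map_or_ensemble, threshold: float = CONTACT_THRESHOLD_NM
                        ) -> tuple[np.ndarray, np.ndarray]:
    """P(s): mean contact probability per genomic separation s = 1..n-1."""
    if isinstance(map_or_ensemble, ConformationEnsemble):
        m = contact_frequency_matrix(map_or_ensemble, threshold).values
    else:
        m = map_or_ensemble.values
    n = m.shape[0]
    s = np.arange(1, n)
    p = np.array([np.diag(m, k).mean() for k in s])
    return s, p
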