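"""Calling nonrandom Hi-C interactions against the polymer null model.

Observed counts are normalized to contact probabilities by anchoring the
adjacent diagonal (|i-j| = 1), where contact is near-certain in both data
and model. Each tested pair (|i-j| >= 2) is then scored by bootstrapping
the null ensemble: the replicate statistic is the contact frequency of a
with-replacement resample of whole conformations, and the raw p-value is
the add-one upper-tail estimate. Benjamini-Hochberg step-up adjustment
controls the FDR; pairs with adjusted p below alpha are the nonrandom set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import ContactMatrix
from .null_ensemble import (CONTACT_THRESHOLD_NM, ConformationEnsemble,
                            contact_frequency_matrix)

__all__ = [
    "InteractionCall",
    "observed_probability",
    "bootstrap_pvalues",
    "bh_adjust",
    "call_nonrandom",
    "tested_pairs",
]

#: genomic-neighbour lag excluded from testing: |i-j| < 2 pairs are in
#: near-certain contact in any polymer model and carry no signal
MIN_TEST_LAG = 2


@dataclass(frozen=True)
class InteractionCall:
    """Significance call for one bead pair (i < j)."""

    i: int
    j: int
    observed_p: float
    null_p: float
    p_raw: float
    p_adj: float
    significant: bool


def observed_probability(counts: ContactMatrix,
                         null_p: ContactMatrix) -> ContactMatrix:
    """Normalize observed counts to contact probabilities.

    The scale s is chosen so the mean of ``s * counts`` over the adjacent
    diagonal (|i-j| = 1) equals the mean of the null probability there;
    entries are capped at 1 and the diagonal set to 1.
    """
    if counts.kind != "counts" or null_p.kind != "probability":
        raise ValueError("expected a counts matrix and a probability matrix")
    if counts.locus != null_p.locus:
        raise ValueError("count and null matrices refer to different loci")
    c_adj = np.diag(counts.values, 1)
    if c_adj.sum() <= 0:
        raise ValueError("all adjacent-pair counts are zero: cannot calibrate "
                         "the count-to-probability scale")
    scale = np.diag(null_p.values, 1).mean() / c_adj.mean()
    q = np.minimum(1.0, scale * counts.values)
    np.fill_diagonal(q, 1.0)
    return ContactMatrix(counts.locus, q, kind="probability")


def tested_pairs(n_beads: int, min_lag: int = MIN_TEST_LAG) -> np.ndarray:
    """Upper-triangle (i, j) index pairs with j - i >= min_lag, shape (P, 2)."""
    i, j = np.triu_indices(n_beads, k=min_lag)
    return np.column_stack([i, j])


def _contact_indicators(ensemble: ConformationEnsemble, pairs: np.ndarray,
                        threshold: float) -> np.ndarray:
    """Boolean matrix (n_conformations, n_pairs): pair in contact per cell."""
    X = ensemble.coords_array()
    d2 = ((X[:, pairs[:, 0], :] - X[:, pairs[:, 1], :]) ** 2).sum(axis=-1)
    return d2 < threshold * threshold


def _replicate_frequencies(ensemble: ConformationEnsemble, ind: np.ndarray,
                           B: int, rng: np.random.Generator) -> np.ndarray:
    """(B, n_pairs) contact frequencies of bootstrap replicates.

    Conformations within one sampling run of the ensemble share resampling
    ancestry and are correlated, so the bootstrap resamples whole runs
    (with replacement) where run tags are available, and whole
    conformations otherwise; either way within-cell correlations across
    pairs are preserved because the same resample indexes every pair.
    """
    w = ensemble.weights()
    if ensemble.run_ids is not None and len(np.unique(ensemble.run_ids)) > 1:
        runs = np.unique(ensemble.run_ids)
        R = len(runs)
        # per-run weighted frequency, then replicate = mean over drawn runs.
        # Each replicate averages R/2 runs, not R: the null map itself is
        # estimated from R runs, so an observation compared against it
        # carries both its own sampling error and the null map's, about
        # twice the variance of a mean of R runs. Halving the replicate
        # run count doubles the replicate variance to match.
        run_freq = np.empty((R, ind.shape[1]))
        for a, r in enumerate(runs):
            m = ensemble.run_ids == r
            wr = w[m] / w[m].sum()
            run_freq[a] = wr @ ind[m]
        draws = rng.integers(0, R, size=(B, max(1, R // 2)))
        return run_freq[draws].mean(axis=1)
    N = len(ensemble)
    draws = rng.choice(N, size=(B, N), replace=True, p=w)
    C = np.zeros((B, N))
    for b in range(B):
        C[b] = np.bincount(draws[b], minlength=N)
    return (C @ ind) / N


def bootstrap_pvalues(observed_q: ContactMatrix, ensemble: ConformationEnsemble,
                      B: int = 1000, threshold: float = CONTACT_THRESHOLD_NM,
                      seed: int | None = None,
                      pairs: np.ndarray | None = None,
                      depth: float | None = None,
                      null_adjacent_mean: float | None = None) -> np.ndarray:
    """Raw upper-tail bootstrap p-values for each tested pair.

    Each replicate resamples the null ensemble (whole independent runs
    where available) and recomputes every pair's contact frequency;
    ``p_raw = (1 + #{replicate >= observed}) / (B + 1)``.

    With ``depth`` given, replicates are depth-matched: replicate
    frequencies are converted to Poisson counts at the observed sequencing
    depth and normalized exactly like the observed map (adjacent-diagonal
    anchor), so the replicate statistic carries both ensemble sampling
    noise and counting noise. Without it, replicates are raw frequencies.

    Returns an array aligned with ``pairs`` (default: all |i-j| >= 2 pairs).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    n = ensemble.n_beads
    if observed_q.n_beads != n:
        raise ValueError("observed matrix and ensemble bead counts differ")
    if pairs is None:
        pairs = tested_pairs(n)
    rng = np.random.default_rng(seed)
    obs = observed_q.values[pairs[:, 0], pairs[:, 1]]
    if depth is None:
        ind = _contact_indicators(ensemble, pairs, threshold).astype(np.float64)
        freq = _replicate_frequencies(ensemble, ind, B, rng)
        exceed = (freq >= obs[None, :]).sum(axis=0)
        return (1.0 + exceed) / (B + 1.0)
    # depth-matched: simulate the whole observation pipeline per replicate
    adj = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    all_pairs = np.vstack([pairs, adj])
    ind = _contact_indicators(ensemble, all_pairs, threshold).astype(np.float64)
    freq = _replicate_frequencies(ensemble, ind, B, rng)
    f_test, f_adj = freq[:, : len(pairs)], freq[:, len(pairs):]
    if null_adjacent_mean is None:
        null_adjacent_mean = float(
            (ensemble.weights() @ ind[:, len(pairs):]).mean())
    # expected counts with the replicate's own adjacent mean matched to the
    # observed adjacent depth, then the observed normalization applied
    lam = f_test * (depth / np.maximum(f_adj.mean(axis=1), 1e-12))[:, None]
    counts = rng.poisson(lam)
    scale = null_adjacent_mean / depth
    q_rep = np.minimum(1.0, scale * counts)
    exceed = (q_rep >= obs[None, :]).sum(axis=0)
    return (1.0 + exceed) / (B + 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sort ascending, multiply by m/rank, enforce monotone nonincreasing from
    the largest, cap at 1, restore input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj
    return out


def call_nonrandom(counts: ContactMatrix, ensemble: ConformationEnsemble,
                   alpha: float = 0.05, B: int = 1000,
                   threshold: float = CONTACT_THRESHOLD_NM,
                   seed: int | None = None) -> list[InteractionCall]:
    """Full calling pipeline: normalize, bootstrap, BH-adjust, flag.

    Pairs with |i-j| < 2 are excluded (always-contacting neighbours).
    """
    null_p = contact_frequency_matrix(ensemble, threshold, locus=counts.locus)
    q = observed_probability(counts, null_p)
    pairs = tested_pairs(ensemble.n_beads)
    p_raw = bootstrap_pvalues(
        q, ensemble, B=B, threshold=threshold, seed=seed, pairs=pairs,
        depth=float(np.diag(counts.values, 1).mean()),
        null_adjacent_mean=float(np.diag(null_p.values, 1).mean()))
    p_adj = bh_adjust(p_raw)
    calls = []
    for (i, j), pr, pa in zip(pairs, p_raw, p_adj):
        calls.append(InteractionCall(
            int(i), int(j),
            observed_p=float(q.values[i, j]),
            null_p=float(null_p.values[i, j]),
            p_raw=float(pr), p_adj=float(pa),
            significant=bool(pa < alpha),
        ))
    return calls


def significant_fraction(calls: list[InteractionCall]) -> float:
    """Nonrandom fraction: significant calls / tested pairs."""
    if not calls:
        return 0.0
    return sum(c.significant for c in calls) / len(calls)
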