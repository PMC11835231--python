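"""Population-based sequential chain growth with checkpoint resampling.

A single vectorized engine serves both the unconstrained null model and
constraint-biased folding: chains grow bead by bead, each new bead drawn
among ``n_trial_directions`` uniform points on the bond sphere of the
previous bead, restricted to placements that respect the hard-core and
confinement constraints and optionally reweighted by per-candidate bias
factors supplied in log space. The accumulated log-weight is the
Rosenbluth-style correction ``log(sum of candidate weights / n_trials)``
per step, so weighted averages target the uniform distribution over
feasible chains times the product of all bias factors applied.

At every checkpoint the population is systematically resampled when the
Kish effective sample size falls below ``ess_threshold`` times the
population size, or when chains have died; weights reset to uniform. An
optional checkpoint score adds a lookahead term to the resampling weights
(guided SMC), steering the population toward chains still able to meet
pending constraints.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["GrowthError", "grow_population"]

# relative slack on the hard-core test so a bond of exactly one diameter
# never fails by float rounding
_CORE_RTOL = 1e-9

#: bias(k, candidates, coords) -> (N, T) log bias factors for the candidate
#: placements of bead k; candidates are selected proportionally to
#: ok * exp(bias), normalized per chain in log space so arbitrarily strong
#: penalties never underflow a chain to death, and the factors enter the
#: chain log-weight (they are part of the sampling target).
BiasFn = Callable[[int, np.ndarray, np.ndarray], np.ndarray]

#: checkpoint_score(k, coords) -> (N,) log lookahead scores added to the
#: resampling weights at checkpoints.
ScoreFn = Callable[[int, np.ndarray], np.ndarray]


class GrowthError(RuntimeError):
    """Raised when the whole population dies at some growth step."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"all chains failed at growth step {step}")


def _random_unit_vectors(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    v = rng.standard_normal(shape + (3,))
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    # a zero-norm draw has probability 0; guard anyway
    norm[norm == 0] = 1.0
    return v / norm


def _systematic_resample(weights: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Systematic (low-variance) resampling of ``n`` indices from ``weights``."""
    w = weights / weights.sum()
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(w), positions).clip(0, len(w) - 1)


def grow_population(
    n_conformations: int,
    n_beads: int,
    *,
    bead_diameter: float,
    bond_length: float,
    confinement_radius: float,
    n_trial_directions: int,
    checkpoint_interval: int,
    ess_threshold: float,
    rng: np.random.Generator,
    bias: BiasFn | None = None,
    checkpoint_score: ScoreFn | None = None,
    on_resample: Callable[[np.ndarray], None] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Grow ``n_conformations`` chains of ``n_beads`` beads in lockstep.

    Returns ``(coords, log_weights)`` with shapes ``(N, n_beads, 3)`` and
    ``(N,)``. ``on_resample`` is called with the survivor index array after
    every resampling event so callers can permute per-chain state.
    """
    N, T = n_conformations, n_trial_directions
    R = confinement_radius
    if bond_length < bead_diameter:
        raise ValueError(
            f"bond_length ({bond_length} nm) < bead_diameter ({bead_diameter} nm): "
            "adjacent beads would overlap the hard core"
        )
    if R < bead_diameter / 2:
        raise ValueError("confinement radius smaller than a bead radius")

    d2min = (bead_diameter * (1.0 - _CORE_RTOL)) ** 2
    coords = np.zeros((N, n_beads, 3))
    log_w = np.zeros(N)
    alive = np.ones(N, dtype=bool)

    # bead 0: uniform in the confinement sphere
    radii = R * rng.random(N) ** (1.0 / 3.0)
    coords[:, 0, :] = radii[:, None] * _random_unit_vectors(rng, (N,))

    for k in range(1, n_beads):
        dirs = _random_unit_vectors(rng, (N, T))
        cand = coords[:, k - 1, None, :] + bond_length * dirs
        ok = (cand ** 2).sum(axis=-1) <= R * R
        if k >= 2:
            # hard core against beads 0..k-2 (bead k-1 sits at bond length)
            diff = cand[:, :, None, :] - coords[:, None, : k - 1, :]
            ok &= ((diff ** 2).sum(axis=-1) >= d2min).all(axis=2)
        if bias is not None:
            log_f = np.where(ok, bias(k, cand, coords), -np.inf)
            shift = log_f.max(axis=1)  # -inf only when no open placement
            alive &= np.isfinite(shift)
            w = np.exp(log_f - np.where(np.isfinite(shift), shift, 0.0)[:, None])
        else:
            w = ok.astype(float)
            shift = None
            alive &= ok.any(axis=1)
        if not alive.any():
            raise GrowthError(k)
        tot = w.sum(axis=1)
        # inverse-CDF selection, one uniform per chain (dead rows pick junk)
        u = rng.random(N) * np.where(tot > 0, tot, 1.0)
        sel = (np.cumsum(w, axis=1) < u[:, None]).sum(axis=1).clip(0, T - 1)
        coords[:, k, :] = cand[np.arange(N), sel]
        log_w[alive] += np.log(tot[alive] / T)
        if shift is not None:
            log_w[alive] += shift[alive]

        at_checkpoint = (k + 1) % checkpoint_interval == 0
        last_bead = k == n_beads - 1
        if at_checkpoint or (last_bead and not alive.all()):
            lw_sel = log_w
            if checkpoint_score is not None and not last_bead:
                lw_sel = log_w + checkpoint_score(k, coords)
            rel = np.where(alive,
                           np.exp(np.minimum(lw_sel - lw_sel[alive].max(), 0.0)),
                           0.0)
            ess = rel.sum() ** 2 / (rel ** 2).sum()
            if ess < ess_threshold * N or not alive.all():
                idx = _systematic_resample(rel, N, rng)
                coords = coords[idx].copy()
                log_w = np.zeros(N)
                alive = np.ones(N, dtype=bool)
                if on_resample is not None:
                    on_resample(idx)

    return coords, log_w
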