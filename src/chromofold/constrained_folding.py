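"""Constraint-biased reconstruction of single-cell chromatin conformations.

Nonrandom interactions become spatial constraints on chain growth. Each
constraint carries an activation probability: in every simulated cell the
constraint is independently active with that probability, reflecting that
a loop called from population Hi-C is present in a fraction of cells, not
all of them. Constraints built from interaction calls use the excess
contact probability ``(q - null) / (1 - null)`` so that the folded
population reproduces the observed contact frequency q once random
polymer collisions are added back; planted constraint sets default to
activation 1 (enforced in every cell).

Within a cell, an active constraint (i, j) weights each candidate
placement of bead j by the one-sided flat-bottom likelihood

    L = exp(-max(0, d(i, j) - target)^2 / (2 sigma^2)),

so satisfied constraints are unpenalized. Two guidance terms keep the
population on track: a reachability funnel (candidates drifting beyond
``target + remaining_contour * FUNNEL_GAMMA`` of a pending partner are
downweighted) and checkpoint lookahead scores on the same funnel that
steer resampling. Both act only on trajectories that are already failing
a pending constraint — configurations satisfying their constraints are
never touched — so the sampled distribution agrees with the
constraint-conditioned target on the satisfied set and merely
down-weights how violating chains are represented. With an empty
constraint set the procedure is bead-for-bead identical to null-chain
growth.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from ._growth import GrowthError, _systematic_resample, grow_population
from .null_ensemble import (CONTACT_THRESHOLD_NM, ChainParams, Conformation,
                            ConformationEnsemble)
from .genome_io import LocusSpec

__all__ = [
    "ConstraintSet",
    "DEFAULT_SIGMA_NM",
    "fold_chain",
    "fold_ensemble",
    "fold_from_calls",
    "constraint_satisfaction",
]

#: softness (nm) of the one-sided constraint potential; sharp enough that an
#: active, satisfied pair rarely exceeds the target by more than a few nm
DEFAULT_SIGMA_NM = 2.0

#: fraction of the fully-extended remaining contour length assumed reachable
#: by the chain when steering toward a pending constraint; < 1 because a
#: confined self-avoiding chain never extends straight
FUNNEL_GAMMA = 0.7

#: beads between resampling checkpoints during constrained folding; denser
#: than for null growth because constraint likelihoods degrade weights fast
FOLD_CHECKPOINT_INTERVAL = 5

#: minimum internal SMC population during folding; the requested ensemble
#: size is drawn from the final population, larger populations keep lineage
#: diversity under many simultaneous constraints
FOLD_MIN_POPULATION = 3000

#: population size of one independent folding run; checkpoint resampling
#: acts within a run, so runs bound how far lineage collapse can spread
FOLD_RUN_SIZE = 100

#: candidate placements per growth step during folding; more trials than
#: null growth because selection quality limits constraint satisfaction
FOLD_TRIAL_DIRECTIONS = 40


@dataclass(frozen=True)
class ConstraintSet:
    """Pairwise spatial constraints: (i, j, target nm, activation probability)."""

    pairs: tuple[tuple[int, int, float, float], ...]
    source: str = ""

    def __init__(self, pairs: Iterable[tuple], source: str = "") -> None:
        norm = []
        seen = set()
        for p in pairs:
            p = tuple(p)
            i, j = int(p[0]), int(p[1])
            t = float(p[2]) if len(p) > 2 else CONTACT_THRESHOLD_NM
            prob = float(p[3]) if len(p) > 3 else 1.0
            if i >= j:
                raise ValueError(f"constraint ({i}, {j}) must have i < j")
            if (i, j) in seen:
                raise ValueError(f"duplicate constraint ({i}, {j})")
            if t <= 0:
                raise ValueError("constraint target distance must be positive")
            if not (0 < prob <= 1):
                raise ValueError("activation probability must be in (0, 1]")
            seen.add((i, j))
            norm.append((i, j, t, prob))
        object.__setattr__(self, "pairs", tuple(norm))
        object.__setattr__(self, "source", source)

    def __len__(self) -> int:
        return len(self.pairs)

    def validate_for(self, n_beads: int) -> None:
        for i, j, _, _ in self.pairs:
            if not (0 <= i < j < n_beads):
                raise ValueError(
                    f"constraint ({i}, {j}) outside locus of {n_beads} beads")

    @classmethod
    def from_calls(cls, calls, source: str = "nonrandom-calls",
                   target: float = CONTACT_THRESHOLD_NM) -> "ConstraintSet":
        """Constraints from significant interaction calls.

        Activation probability is the excess contact probability
        ``(observed - null) / (1 - null)``: the fraction of cells that must
        hold the contact deliberately for the population frequency to match
        the observation once random collisions are included.
        """
        pairs = []
        for c in calls:
            if not c.significant:
                continue
            prob = (c.observed_p - c.null_p) / max(1e-12, 1.0 - c.null_p)
            prob = min(1.0, max(0.0, prob))
            if prob > 0:
                pairs.append((c.i, c.j, target, prob))
        return cls(pairs, source)


def _constraint_bias(constraints: ConstraintSet, sigma: float,
                     bond_length: float, active: np.ndarray | None = None):
    """Build (bias, checkpoint_score) callbacks for the growth engine.

    ``active`` is the per-chain activation mask, shape
    (n_chains, n_constraints); None means all constraints active in every
    chain. Returns (None, None) for an empty set.
    """
    if len(constraints) == 0:
        return None, None
    n_con = len(constraints)
    # per growth step k: constraint rows ending at k, and rows pending at k
    # with their reachability limit
    finals: dict[int, list[tuple[int, int, float]]] = defaultdict(list)
    pending: dict[int, list[tuple[int, int, float]]] = defaultdict(list)
    for c_idx, (i, j, t, _) in enumerate(constraints.pairs):
        finals[j].append((c_idx, i, t))
        for k in range(i + 1, j):
            pending[k].append((c_idx, i, t + (j - k) * bond_length * FUNNEL_GAMMA))

    def _pack(table):
        return {k: (np.array([c for c, _, _ in v], dtype=int),
                    np.array([i for _, i, _ in v], dtype=int),
                    np.array([lim for _, _, lim in v]))
                for k, v in table.items()}

    final_arr, pend_arr = _pack(finals), _pack(pending)
    inv_2s2 = 1.0 / (2.0 * sigma * sigma)

    def _log_penalty(points: np.ndarray, coords: np.ndarray,
                     entry) -> np.ndarray:
        c_idx, part, limits = entry
        partners = coords[:, part, :]                     # (N, m, 3)
        mask = None if active is None else active[:, c_idx]  # (N, m)
        if points.ndim == 3:                              # (N, T, 3)
            # d^2 via |p|^2 + |c|^2 - 2 p.c, avoiding a (N,T,m,3) temporary
            d2 = ((points ** 2).sum(-1)[:, :, None]
                  + (partners ** 2).sum(-1)[:, None, :]
                  - 2.0 * np.einsum("ntk,nmk->ntm", points, partners))
            excess = np.maximum(0.0, np.sqrt(np.maximum(d2, 0.0))
                                - limits[None, None, :])
            pen = excess * excess
            if mask is not None:
                return -np.einsum("ntm,nm->nt", pen, mask) * inv_2s2
            return -pen.sum(axis=2) * inv_2s2
        d = np.linalg.norm(points[:, None, :] - partners, axis=-1)
        excess = np.maximum(0.0, d - limits[None, :])
        pen = excess * excess
        if mask is not None:
            pen = pen * mask
        return -pen.sum(axis=1) * inv_2s2

    # NB: the guide factors enter the chain weights (engine contract), so
    # the effective target multiplies the flat-bottom constraint likelihood
    # by funnel terms that are 1 on every constraint-satisfying trajectory

    def bias(k: int, cand: np.ndarray, coords: np.ndarray) -> np.ndarray:
        shape = cand.shape[:2]
        log_phi = _log_penalty(cand, coords, final_arr[k]) \
            if k in final_arr else np.zeros(shape)
        log_guide = _log_penalty(cand, coords, pend_arr[k]) \
            if k in pend_arr else np.zeros(shape)
        return log_phi + log_guide

    def checkpoint_score(k: int, coords: np.ndarray) -> np.ndarray:
        if k not in pend_arr:
            return np.zeros(coords.shape[0])
        return _log_penalty(coords[:, k, :], coords, pend_arr[k])

    return bias, checkpoint_score


def fold_chain(constraints: ConstraintSet, n_beads: int,
               params: ChainParams | None = None,
               rng: np.random.Generator | int | None = None,
               sigma: float = DEFAULT_SIGMA_NM) -> Conformation:
    """Grow one chain biased toward the given constraints (all active)."""
    params = params or ChainParams()
    constraints.validate_for(n_beads)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    bias, _ = _constraint_bias(constraints, sigma, params.effective_bond_length)
    coords, log_w = grow_population(
        1, n_beads,
        bead_diameter=params.bead_diameter,
        bond_length=params.effective_bond_length,
        confinement_radius=params.radius_for(n_beads),
        n_trial_directions=params.n_trial_directions,
        checkpoint_interval=n_beads + 1,  # no resampling for a lone chain
        ess_threshold=params.ess_threshold,
        rng=rng,
        bias=bias,
    )
    return Conformation(coords[0], log_w[0], validate=False)


def fold_ensemble(constraints: ConstraintSet, n_conformations: int,
                  n_beads: int, params: ChainParams | None = None,
                  seed: int | None = None, sigma: float = DEFAULT_SIGMA_NM,
                  locus: LocusSpec | None = None,
                  min_population: int = FOLD_MIN_POPULATION) -> ConformationEnsemble:
    """Population fold with checkpoint resampling; reproducible from seed.

    Per chain, each constraint is active with its activation probability;
    the internal SMC population is ``max(n_conformations, min_population)``
    and the returned ensemble holds ``n_conformations`` conformations drawn
    from the final weighted population by systematic resampling.
    """
    if n_conformations < 1:
        raise ValueError("n_conformations must be >= 1")
    params = params or ChainParams(n_trial_directions=FOLD_TRIAL_DIRECTIONS,
                                   checkpoint_interval=FOLD_CHECKPOINT_INTERVAL)
    constraints.validate_for(n_beads)
    n_pop = max(n_conformations, min_population)
    n_runs = max(1, -(-n_pop // FOLD_RUN_SIZE))
    max_retries = 3
    seeds = np.random.SeedSequence(seed).spawn(n_runs * (1 + max_retries) + 1)
    out_rng = np.random.default_rng(seeds[-1])
    probs = np.array([p for _, _, _, p in constraints.pairs]) \
        if len(constraints) else None
    # distribute the requested ensemble size evenly over runs
    quota = np.full(n_runs, n_conformations // n_runs)
    quota[: n_conformations % n_runs] += 1
    all_coords, all_runs, all_masks = [], [], []
    for r in range(n_runs):
        if quota[r] == 0:
            continue
        run_n = min(FOLD_RUN_SIZE, n_pop)
        last_err: GrowthError | None = None
        for attempt in range(1 + max_retries):
            run_rng = np.random.default_rng(seeds[r * (1 + max_retries) + attempt])
            active = None
            on_resample = None
            if probs is not None and (probs < 1).any():
                active = (run_rng.random((run_n, len(constraints))) < probs
                          ).astype(float)

                def on_resample(idx: np.ndarray, active=active) -> None:
                    active[:] = active[idx]

            bias, score = _constraint_bias(constraints, sigma,
                                           params.effective_bond_length, active)
            try:
                coords, log_w = grow_population(
                    run_n, n_beads,
                    bead_diameter=params.bead_diameter,
                    bond_length=params.effective_bond_length,
                    confinement_radius=params.radius_for(n_beads),
                    n_trial_directions=params.n_trial_directions,
                    checkpoint_interval=params.checkpoint_interval,
                    ess_threshold=params.ess_threshold,
                    rng=run_rng,
                    bias=bias,
                    checkpoint_score=score,
                    on_resample=on_resample,
                )
                last_err = None
                break
            except GrowthError as e:
                last_err = e
        if last_err is not None:
            spans = [f"({i},{j})" for i, j, _, _ in constraints.pairs
                     if j <= last_err.step]
            raise GrowthError(
                last_err.step,
                f"folding run {r} extinct at bead {last_err.step} in "
                f"{1 + max_retries} attempts; constraints active so far: "
                f"{', '.join(spans) or 'none'}",
            ) from last_err
        w = np.exp(log_w - log_w.max())
        idx = _systematic_resample(w, int(quota[r]), out_rng)
        all_coords.append(coords[idx])
        all_runs.append(np.full(int(quota[r]), r))
        if active is not None:
            all_masks.append(active[idx])
    coords = np.concatenate(all_coords)
    ens = ConformationEnsemble.from_arrays(
        coords, np.zeros(len(coords)), locus, params, seed,
        run_ids=np.concatenate(all_runs))
    # per-conformation activation masks, for calibration diagnostics
    ens.activation_masks = np.concatenate(all_masks) if all_masks else None
    return ens


#: activation probabilities below this are dropped during calibration: the
#: pair's observed frequency is already explained by passive collisions
MIN_ACTIVATION = 0.02


def fold_from_calls(calls, n_conformations: int, n_beads: int,
                    params: ChainParams | None = None,
                    seed: int | None = None,
                    sigma: float = DEFAULT_SIGMA_NM,
                    locus: LocusSpec | None = None,
                    calibration_rounds: int = 3,
                    calibration_size: int = 500,
                    calibration_population: int = 2000,
                    final_population: int | None = None,
                    target: float = CONTACT_THRESHOLD_NM
                    ) -> tuple[ConformationEnsemble, ConstraintSet]:
    """Fold an ensemble that reproduces the observed contact frequencies.

    Nonrandom calls give initial activation probabilities (excess over the
    null), but calls are correlated: pairs elevated as a by-product of a
    few true loops would, if activated independently, over-compact the
    ensemble. Each calibration round folds a pilot ensemble and measures,
    for every constrained pair, its contact frequency among cells where
    the constraint was active (m1) and where it was passive (m0); under
    the mixture model ``achieved = a*m1 + (1-a)*m0`` the activation that
    hits the observed target q is ``a = (q - m0) / (m1 - m0)``, clipped to
    [0, 1]. Pairs whose passive frequency already reaches the target are
    dropped (activation below ``MIN_ACTIVATION``): the rest of the
    constraint system explains them, and re-imposing them independently
    would over-compact the ensemble. The final fold uses the calibrated
    set. Returns (ensemble, calibrated_constraints).
    """
    sig = [c for c in calls if c.significant]
    cs = ConstraintSet.from_calls(calls, target=target)
    targets = {(c.i, c.j): c.observed_p for c in sig}
    null_ps = {(c.i, c.j): c.null_p for c in sig}
    rng = np.random.default_rng(seed)
    for _ in range(calibration_rounds):
        if len(cs) == 0:
            break
        pilot = fold_ensemble(cs, calibration_size, n_beads, params=params,
                              seed=int(rng.integers(2 ** 31)), sigma=sigma,
                              locus=locus, min_population=calibration_population)
        X = pilot.coords_array()
        masks = pilot.activation_masks
        new_pairs = []
        for c_idx, (i, j, t, a) in enumerate(cs.pairs):
            q = targets[(i, j)]
            contact = (np.linalg.norm(X[:, i, :] - X[:, j, :], axis=-1)
                       < target)
            act = masks[:, c_idx].astype(bool) if masks is not None \
                else np.ones(len(contact), dtype=bool)
            n1 = act.sum()
            m1 = contact[act].mean() if n1 else 1.0
            m0 = contact[~act].mean() if n1 < len(contact) \
                else null_ps[(i, j)]
            # mixture solve: achieved = a*m1 + (1-a)*m0 = q
            a_new = (q - m0) / max(m1 - m0, 1e-3)
            a_new = float(np.clip(a_new, 0.0, 1.0))
            if a_new >= MIN_ACTIVATION:
                new_pairs.append((i, j, t, a_new))
        cs = ConstraintSet(new_pairs, source=cs.source + "|calibrated")
    ens = fold_ensemble(cs, n_conformations, n_beads, params=params,
                        seed=int(rng.integers(2 ** 31)), sigma=sigma,
                        locus=locus,
                        min_population=final_population or FOLD_MIN_POPULATION)
    return ens, cs


def constraint_satisfaction(ensemble: ConformationEnsemble,
                            constraints: ConstraintSet,
                            threshold: float = CONTACT_THRESHOLD_NM) -> dict:
    """Weighted per-constraint and overall satisfied fractions.

    A constraint is satisfied in a conformation when d(i, j) < threshold.
    Returns ``{"per_constraint": {(i, j): fraction}, "overall": mean}``;
    an empty constraint set yields an empty report.
    """
    if len(constraints) == 0:
        return {"per_constraint": {}, "overall": float("nan")}
    constraints.validate_for(ensemble.n_beads)
    X = ensemble.coords_array()
    w = ensemble.weights()
    per = {}
    for i, j, _, _ in constraints.pairs:
        d = np.linalg.norm(X[:, i, :] - X[:, j, :], axis=-1)
        per[(i, j)] = float((w * (d < threshold)).sum())
    return {"per_constraint": per,
            "overall": float(np.mean(list(per.values())))}
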