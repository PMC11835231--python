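"""Random confined self-avoiding polymer ensembles: the null model.

Chromatin at a locus is modeled as a linear chain of beads, one bead per
Hi-C bin (5 kb by default), with a hard-core excluded volume of one bead
diameter and a fixed bond length, grown inside a confinement sphere whose
volume is set by the bead occupancy fraction (a proxy for nuclear volume
per unit chromatin). Ensembles of such chains, sampled uniformly over all
feasible conformations by sequential importance sampling with checkpoint
resampling, give the contact probabilities expected from random polymer
collision alone — the null against which observed Hi-C contacts are
scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._growth import GrowthError, grow_population
from .genome_io import ContactMatrix, LocusSpec

__all__ = [
    "ChainParams",
    "Conformation",
    "ConformationEnsemble",
    "GrowthError",
    "confinement_radius_for",
    "grow_chain",
    "generate_null_ensemble",
    "contact_frequency_matrix",
    "validate_conformation",
]

#: spatial distance (nm) below which two beads count as a cross-linkable contact
CONTACT_THRESHOLD_NM = 80.0


def confinement_radius_for(n_beads: int, bead_diameter: float,
                           volume_fraction: float) -> float:
    """Confinement-sphere radius for a target bead volume fraction.

    Solves ``n_beads * (d/2)^3 / R^3 = volume_fraction`` for R, i.e. the
    summed bead volume occupies ``volume_fraction`` of the sphere.
    """
    if n_beads <= 0 or bead_diameter <= 0 or volume_fraction <= 0:
        raise ValueError("n_beads, bead_diameter and volume_fraction must be positive")
    if volume_fraction > 1:
        raise ValueError("volume_fraction cannot exceed 1")
    return (bead_diameter / 2.0) * (n_beads / volume_fraction) ** (1.0 / 3.0)


@dataclass(frozen=True)
class ChainParams:
    """Geometry and sampler settings for chain growth.

    Parameters
    ----------
    bead_diameter:
        Hard-core diameter of a 5 kb bead, nm.
    bond_length:
        Distance between consecutive beads, nm; defaults to the bead
        diameter (tangent beads).
    confinement_radius:
        Radius of the confinement sphere, nm. If None it is derived per
        locus from ``volume_fraction``.
    volume_fraction:
        Fraction of the confinement sphere occupied by bead volume.
    n_trial_directions:
        Candidate placements evaluated per growth step.
    checkpoint_interval:
        Beads between resampling checkpoints.
    ess_threshold:
        Fraction of the population size below which the Kish effective
        sample size triggers systematic resampling.
    """

    bead_diameter: float = 30.0
    bond_length: float | None = None
    confinement_radius: float | None = None
    volume_fraction: float = 0.1
    n_trial_directions: int = 20
    checkpoint_interval: int = 25
    ess_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.bead_diameter <= 0:
            raise ValueError("bead_diameter must be positive")
        bond = self.bond_length
        if bond is not None and bond < 0.5 * self.bead_diameter:
            raise ValueError("bond_length must be at least half a bead diameter")
        if not (0 < self.volume_fraction <= 1):
            raise ValueError("volume_fraction must be in (0, 1]")
        if self.confinement_radius is not None and \
                self.confinement_radius < self.bead_diameter / 2:
            raise ValueError("confinement_radius must hold at least one bead")
        if self.n_trial_directions < 1:
            raise ValueError("n_trial_directions must be >= 1")
        if self.checkpoint_interval < 1:
            raise ValueError("checkpoint_interval must be >= 1")
        if not (0 < self.ess_threshold <= 1):
            raise ValueError("ess_threshold must be in (0, 1]")

    @property
    def effective_bond_length(self) -> float:
        return self.bond_length if self.bond_length is not None else self.bead_diameter

    def radius_for(self, n_beads: int) -> float:
        if self.confinement_radius is not None:
            return self.confinement_radius
        return confinement_radius_for(n_beads, self.bead_diameter, self.volume_fraction)


@dataclass
class Conformation:
    """Ordered 3D bead coordinates (nm) with an importance log-weight."""

    coords: np.ndarray
    log_weight: float = 0.0

    def __init__(self, coords: np.ndarray, log_weight: float = 0.0,
                 validate: bool = True) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_beads, 3)")
        if validate and not np.isfinite(coords).all():
            raise ValueError("coordinates must be finite")
        self.coords = coords
        self.log_weight = float(log_weight)

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]


def validate_conformation(conf: Conformation, params: ChainParams,
                          confinement_radius: float | None = None,
                          rtol: float = 1e-6) -> None:
    """Assert hard-core, bond and confinement constraints; raise on violation."""
    x = conf.coords
    bond = params.effective_bond_length
    R = confinement_radius if confinement_radius is not None \
        else params.radius_for(conf.n_beads)
    bond_d = np.linalg.norm(np.diff(x, axis=0), axis=1)
    if bond_d.size and np.abs(bond_d - bond).max() > rtol * bond:
        raise ValueError("bond length violated")
    if conf.n_beads >= 3:
        from scipy.spatial.distance import pdist

        d = pdist(x)
        # consecutive pairs are the bond itself; test all pairs against the
        # hard core with relative slack
        if d.min() < params.bead_diameter * (1 - rtol):
            raise ValueError("hard-core overlap")
    norms = np.linalg.norm(x, axis=1)
    if norms.max() > R * (1 + rtol):
        raise ValueError("bead outside confinement sphere")


class ConformationEnsemble:
    """A weighted collection of equal-length conformations.

    ``run_ids`` tags each conformation with the independent sampling run it
    came from; conformations within a run share resampling ancestry and are
    therefore correlated, while runs are statistically independent. Run ids
    are the exchangeable unit for bootstrap procedures.
    """

    def __init__(self, conformations: Sequence[Conformation],
                 locus: LocusSpec | None = None,
                 params: ChainParams | None = None,
                 seed: int | None = None,
                 run_ids: np.ndarray | None = None) -> None:
        if not conformations:
            raise ValueError("ensemble must contain at least one conformation")
        n_beads = conformations[0].n_beads
        for c in conformations:
            if c.n_beads != n_beads:
                raise ValueError("all conformations must share a bead count")
            if not np.isfinite(c.log_weight):
                raise ValueError("log-weights must be finite")
        self.conformations = list(conformations)
        self.locus = locus
        self.params = params
        self.seed = seed
        if run_ids is not None:
            run_ids = np.asarray(run_ids, dtype=int)
            if run_ids.shape != (len(conformations),):
                raise ValueError("run_ids must give one run per conformation")
        self.run_ids = run_ids
        self._coords: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.conformations)

    @property
    def n_beads(self) -> int:
        return self.conformations[0].n_beads

    def coords_array(self) -> np.ndarray:
        """Stacked coordinates, shape (n_conformations, n_beads, 3)."""
        if self._coords is None:
            self._coords = np.stack([c.coords for c in self.conformations])
        return self._coords

    def log_weights(self) -> np.ndarray:
        return np.array([c.log_weight for c in self.conformations])

    def weights(self) -> np.ndarray:
        """Normalized importance weights (sum to 1).

        With run tags, weights are normalized within each run and runs get
        equal total mass: every run is an independent unbiased estimate of
        the same distribution, so averaging runs evenly has lower variance
        than letting a lucky run dominate globally.
        """
        lw = self.log_weights()
        if self.run_ids is None:
            w = np.exp(lw - lw.max())
            return w / w.sum()
        w = np.zeros_like(lw)
        runs = np.unique(self.run_ids)
        for r in runs:
            m = self.run_ids == r
            wr = np.exp(lw[m] - lw[m].max())
            w[m] = wr / wr.sum() / len(runs)
        return w

    def subsample(self, n_sample: int, seed: int | None = None) -> "ConformationEnsemble":
        """Seeded uniform subsample without replacement (all if n_sample >= size)."""
        if n_sample < 1:
            raise ValueError("n_sample must be >= 1")
        if n_sample >= len(self):
            return self
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(self), size=n_sample, replace=False)
        return ConformationEnsemble(
            [self.conformations[i] for i in idx], self.locus, self.params,
            self.seed,
            run_ids=None if self.run_ids is None else self.run_ids[idx])

    @classmethod
    def from_arrays(cls, coords: np.ndarray, log_weights: np.ndarray,
                    locus: LocusSpec | None = None,
                    params: ChainParams | None = None,
                    seed: int | None = None,
                    run_ids: np.ndarray | None = None) -> "ConformationEnsemble":
        confs = [Conformation(c, lw, validate=False)
                 for c, lw in zip(coords, log_weights)]
        ens = cls(confs, locus, params, seed, run_ids=run_ids)
        ens._coords = np.asarray(coords, dtype=float)
        return ens


def grow_chain(n_beads: int, params: ChainParams | None = None,
               rng: np.random.Generator | int | None = None) -> Conformation:
    """Grow a single self-avoiding confined chain.

    Raises :class:`GrowthError` if the chain traps itself (no feasible
    placement at some step). Population growth with resampling
    (:func:`generate_null_ensemble`) is the robust route for ensembles.
    """
    params = params or ChainParams()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    coords, log_w = grow_population(
        1, n_beads,
        bead_diameter=params.bead_diameter,
        bond_length=params.effective_bond_length,
        confinement_radius=params.radius_for(n_beads),
        n_trial_directions=params.n_trial_directions,
        checkpoint_interval=n_beads + 1,  # no resampling for a lone chain
        ess_threshold=params.ess_threshold,
        rng=rng,
    )
    return Conformation(coords[0], log_w[0], validate=False)


#: default population size of one independent null sampling run; runs are
#: the exchangeable unit for bootstrap statistics on the ensemble
DEFAULT_RUN_SIZE = 100


def generate_null_ensemble(n_conformations: int, n_beads: int,
                           params: ChainParams | None = None,
                           seed: int | None = None,
                           locus: LocusSpec | None = None,
                           run_size: int = DEFAULT_RUN_SIZE) -> ConformationEnsemble:
    """Sample an ensemble of random confined self-avoiding chains.

    The ensemble is assembled from ``ceil(n / run_size)`` statistically
    independent sampling runs. Within each run a population of partial
    chains grows in lockstep with systematic resampling at checkpoints
    whenever weight degeneracy (Kish ESS) or chain failures demand it;
    conformations within a run therefore share resampling ancestry, and
    downstream bootstrap procedures resample runs, not conformations.
    Fully reproducible from ``seed``.
    """
    if n_conformations < 1:
        raise ValueError("n_conformations must be >= 1")
    params = params or ChainParams()
    run_size = min(run_size, n_conformations)
    n_runs = -(-n_conformations // run_size)
    seeds = np.random.SeedSequence(seed).spawn(n_runs)
    all_coords, all_logw, all_runs = [], [], []
    for r in range(n_runs):
        size = min(run_size, n_conformations - r * run_size)
        coords, log_w = grow_population(
            size, n_beads,
            bead_diameter=params.bead_diameter,
            bond_length=params.effective_bond_length,
            confinement_radius=params.radius_for(n_beads),
            n_trial_directions=params.n_trial_directions,
            checkpoint_interval=params.checkpoint_interval,
            ess_threshold=params.ess_threshold,
            rng=np.random.default_rng(seeds[r]),
        )
        all_coords.append(coords)
        all_logw.append(log_w)
        all_runs.append(np.full(size, r))
    return ConformationEnsemble.from_arrays(
        np.concatenate(all_coords), np.concatenate(all_logw), locus, params,
        seed, run_ids=np.concatenate(all_runs))


def contact_frequency_matrix(ensemble: ConformationEnsemble,
                             threshold: float = CONTACT_THRESHOLD_NM,
                             locus: LocusSpec | None = None,
                             chunk: int = 256) -> ContactMatrix:
    """Weighted fraction of conformations with bead-pair distance < threshold.

    Entry (i, j) is the importance-weighted contact probability of the pair;
    the diagonal is 1 by convention.
    """
    if threshold <= 0:
        raise ValueError("contact threshold must be positive")
    X = ensemble.coords_array()
    W = ensemble.weights()
    n = ensemble.n_beads
    M = np.zeros((n, n))
    t2 = threshold * threshold
    for lo in range(0, len(ensemble), chunk):
        xc = X[lo:lo + chunk]
        d2 = ((xc[:, :, None, :] - xc[:, None, :, :]) ** 2).sum(axis=-1)
        M += np.einsum("c,cij->ij", W[lo:lo + chunk], (d2 < t2).astype(float))
    M = (M + M.T) / 2.0
    np.fill_diagonal(M, 1.0)
    np.clip(M, 0.0, 1.0, out=M)
    locus = locus or ensemble.locus or _dummy_locus(n)
    return ContactMatrix(locus, M, kind="probability")


def _dummy_locus(n_beads: int, resolution: int = 5000) -> LocusSpec:
    """Anonymous locus for ensembles not tied to genome coordinates."""
    return LocusSpec("chrN", 0, n_beads * resolution, resolution)
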