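"""Fitness, resource competition, and density-dependent Poisson reproduction.

Each generation every niche is replenished with resource ``R``, which is
partitioned among the individuals competing there in proportion to their
competitive fitness w.  Births follow a saturating Michaelis-Menten function
of the per-capita resource, deaths occur with probability ``d``, and the next
generation's genotype counts are independent Poisson draws around the
expected offspring numbers.  All expectations are computed in closed form per
genotype class; stochasticity enters only through the Poisson draws (and the
binomial tie-splits and recombination sampling elsewhere).
"""

from __future__ import annotations

from typing import Callable, Dict

import numpy as np

from .genotypes import GenotypeSpace, PopulationState, niche_loads
from .params import ModelParams, calibrate_R0

__all__ = [
    "fitness",
    "allocate_resources",
    "birth_rate",
    "expected_offspring",
    "reproduce",
    "calibrate_R0",
    "FITNESS_FUNCTIONS",
]


def _additive_fitness(space: GenotypeSpace, s: float) -> np.ndarray:
    # w_{i,j} = 1 - s * (1 - f_{i,j}): linear in the niche-matched fraction.
    # Only the genotype's competing niche is ever evaluated by the engine.
    return 1.0 - s * (1.0 - space.fmat)


def _step_fitness(space: GenotypeSpace, s: float) -> np.ndarray:
    # Optimal genotypes (f1 in {0,1}) have w=1; every intermediate pays the
    # identical niche-switching cost s, in both niches.
    w = np.where((space.f1 == 0.0) | (space.f1 == 1.0), 1.0, 1.0 - s)
    return np.stack([w, w])


#: Pluggable fitness interface: name -> (space, s) -> w of shape (2, size).
FITNESS_FUNCTIONS: Dict[str, Callable[[GenotypeSpace, float], np.ndarray]] = {
    "additive": _additive_fitness,
    "step": _step_fitness,
}


def fitness(space: GenotypeSpace, params: ModelParams) -> np.ndarray:
    """Per-genotype-per-niche competitive fitness, shape ``(2, size)``."""
    return FITNESS_FUNCTIONS[params.fitness_model](space, params.s)


def allocate_resources(
    state: PopulationState,
    w: np.ndarray,
    params: ModelParams,
    space: GenotypeSpace,
) -> np.ndarray:
    """Mean resource per individual.

    Additive model: each individual draws only from its assigned niche; the
    per-individual share in niche j is ``R * w_{i,j} / sum_k N_{k,j} w_{k,j}``
    and the returned array has shape ``(2, size)`` (zero rows for empty
    niches, resource unconsumed there).

    Step model: each individual draws from both niches in proportion to its
    genotype, so its per-capita total is ``sum_j f_{i,j} * share_{i,j}`` with
    the niche population sizes being the fractional loads; returns shape
    ``(size,)``.
    """
    R = params.R
    if params.fitness_model == "additive":
        nn = state.niche_counts
        if nn is None:
            raise ValueError("additive model requires a niche assignment")
        denom = (nn * w).sum(axis=1)  # (2,)
        x = np.zeros_like(w)
        for j in (0, 1):
            if denom[j] > 0:
                x[j] = R * w[j] / denom[j]
        return x
    loads = niche_loads(state, space)  # (2, size)
    denom = (loads * w).sum(axis=1)
    share = np.zeros_like(w)
    for j in (0, 1):
        if denom[j] > 0:
            share[j] = R * w[j] / denom[j]
    return (space.fmat * share).sum(axis=0)


def birth_rate(allocation: np.ndarray, params: ModelParams) -> np.ndarray:
    """Saturating Michaelis-Menten birth rate b = b_max * x / (x + R_0)."""
    x = np.asarray(allocation, dtype=float)
    if np.any(x < 0):
        raise ValueError("per-capita resource allocation must be non-negative")
    return params.b_max * x / (x + params.R_0)


def expected_offspring(b: np.ndarray, params: ModelParams) -> np.ndarray:
    """Expected offspring per individual: survival plus births,
    ``nu = (1 - d) + b``; nu = 1 exactly when b = d (stationarity)."""
    return (1.0 - params.d) + np.asarray(b, dtype=float)


def reproduce(
    counts: np.ndarray, nu: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Next-generation counts: independent ``Poisson(N_i * nu_i)`` draws per
    genotype class; classes at count 0 stay 0."""
    return rng.poisson(counts * nu)
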