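"""Built-in invariant checks for the `nichesim validate` subcommand.

Fast, small-population sanity checks of the model's exact invariants:
resource conservation, count conservation under recombination, allele
non-creation, r=0 genotype-set closure, and rerun determinism.  The full
statistical test suite lives in the package's pytest tests; this is a quick
field check.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

from .dynamics import allocate_resources, fitness
from .engine import Simulation
from .genotypes import GenotypeSpace, PopulationState, _assign
from .params import ModelParams
from .recombination import recombine_batch, recombine_sequential
from .experiments import run_appearance


def run_validation(seed: int = 0) -> List[Tuple[str, str]]:
    failures: List[Tuple[str, str]] = []

    def check(name: str, cond: bool, msg: str = "") -> None:
        if not cond:
            failures.append((name, msg))

    rng = np.random.default_rng(seed)
    params = ModelParams(L=3, s=0.1, fitness_model="additive", r=1e-3, K=1000)
    space = GenotypeSpace(params.L, params.B)

    # resource conservation per occupied niche
    counts = rng.integers(0, 200, size=space.size).astype(np.int64)
    state = PopulationState(0, counts, _assign(counts, space, rng))
    w = fitness(space, params)
    x = allocate_resources(state, w, params, space)
    for j in (0, 1):
        used = float((state.niche_counts[j] * x[j]).sum())
        if state.niche_counts[j].sum() > 0:
            check("resource_conservation", abs(used - params.R) < 1e-9,
                  f"niche {j} allocated {used} != R={params.R}")

    # N conservation + allele non-creation under both recombination modes
    for mode, fn in (("batch", recombine_batch), ("sequential", recombine_sequential)):
        c = counts.copy()
        c[space.idx_niche1] = 0  # remove all genotypes majority-adapted to niche 1
        before_alleles = space.bits @ c
        out = fn(c, 50, space, np.random.default_rng(seed + 1))
        check(f"N_conserved_{mode}", int(out.sum()) == int(c.sum()),
              f"{int(out.sum())} != {int(c.sum())}")
        after_alleles = space.bits @ out
        zero_before = before_alleles == 0
        check(f"no_allele_creation_{mode}",
              bool((after_alleles[zero_before] == 0).all()),
              "allele created from empty pool")

    # r=0: the set of present genotypes never grows
    p0 = params.replace(r=0.0, K=2000)
    st = PopulationState(0, counts.copy(), None)
    sim = Simulation(p0, st, rng=np.random.default_rng(seed + 2), space=space)
    present0 = set(np.where(counts > 0)[0])
    for _ in range(20):
        sim.step()
    present1 = set(np.where(sim.state.counts > 0)[0])
    check("r0_closure", present1 <= present0, "new genotype without recombination")

    # determinism: identical outcome from the same seed
    p1 = params.replace(K=500, max_generations=50)
    o1 = run_appearance(p1, seed=seed + 3)
    o2 = run_appearance(p1, seed=seed + 3)
    check("determinism", o1.to_dict() == o2.to_dict(), "rerun differs")

    return failures
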