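"""Generation loop: growth/selection, sympatric recombination, niche return.

One generation applies, in order: (i) fitness-weighted resource partition and
density-dependent Poisson reproduction within each niche (additive model) or
via pooled per-capita totals (step model); (ii) gene-conversion recombination
in the common sympatric pool of both niches; (iii) individuals return to the
niche their genotype is best adapted to (additive model only; ties split
binomially).
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .dynamics import fitness
from .genotypes import GenotypeSpace, PopulationState, _assign
from .params import ModelParams
from .recombination import recombine_batch, recombine_sequential

__all__ = ["Simulation", "step_generation"]


class Simulation:
    """Mutable simulation holding precomputed per-genotype tables.

    The population state lives in ``self.state``; :meth:`step` advances it by
    one generation.  Summary statistics used by the experiments (niche-1
    allele counts, optimal-genotype frequency, background-allele frequency
    per niche) are exposed as cheap methods over the count vectors.
    """

    def __init__(
        self,
        params: ModelParams,
        state: PopulationState,
        rng: Optional[np.random.Generator] = None,
        space: Optional[GenotypeSpace] = None,
    ):
        self.params = params
        self.space = space or GenotypeSpace(params.L, params.B)
        self.rng = rng if rng is not None else np.random.default_rng(params.seed)
        self.w = fitness(self.space, params)
        self.R0 = params.R_0
        self.additive = params.fitness_model == "additive"
        self.sequential = params.recombination_mode == "sequential"
        self.state = state
        if self.additive and state.niche_counts is None:
            state.niche_counts = _assign(state.counts, self.space, self.rng)
        # step model: fitness identical in both niches; keep the 1-D vector
        self._w_step = self.w[0]
        self._bg = self.space.background_bits[0].astype(np.float64)

    # ------------------------------------------------------------------ step

    def step(self) -> PopulationState:
        """Advance one generation in place and return the state."""
        p = self.params
        sp = self.space
        rng = self.rng
        st = self.state

        if self.additive:
            nn = st.niche_counts
            w = self.w
            x = np.zeros_like(w)
            for j in (0, 1):
                denom = nn[j] @ w[j]
                if denom > 0:
                    x[j] = (p.R / denom) * w[j]
            b = p.b_max * x / (x + self.R0)
            nu = (1.0 - p.d) + b
            nn = rng.poisson(nn * nu)
            counts = nn.sum(axis=0)
        else:
            counts = st.counts
            loads = counts * sp.fmat
            w = self._w_step
            x = np.zeros(sp.size)
            for j in (0, 1):
                denom = loads[j] @ w
                if denom > 0:
                    x += sp.fmat[j] * ((p.R / denom) * w)
            b = p.b_max * x / (x + self.R0)
            nu = (1.0 - p.d) + b
            counts = rng.poisson(counts * nu)

        N = int(counts.sum())
        if p.r > 0 and N >= 2:
            m = rng.poisson(p.r * N * sp.n_loci)
            if m > 0:
                if self.sequential:
                    counts = recombine_sequential(counts, m, sp, rng)
                else:
                    counts = recombine_batch(counts, m, sp, rng)

        st.counts = counts
        st.niche_counts = _assign(counts, sp, rng) if self.additive else None
        st.generation += 1
        return st

    # ------------------------------------------------------------ statistics

    def allele1_counts(self) -> np.ndarray:
        """Pooled count of the niche-1 allele at each adaptive locus."""
        return self.space.adaptive_bits @ self.state.counts

    def derived_optimal_count(self) -> int:
        """Pooled count of the niche-1 optimal (all-1 adaptive) genotype."""
        return int(self.state.counts[self.space.opt1].sum())

    def optimal_frequency(self) -> float:
        """Pooled frequency of the two optimal genotypes (any background)."""
        c = self.state.counts
        N = c.sum()
        if N == 0:
            return 0.0
        return float((c[self.space.opt0].sum() + c[self.space.opt1].sum()) / N)

    def background_freq_by_niche(self) -> Tuple[float, float]:
        """Frequency of background allele 1 in each niche (NaN if empty).

        Additive model: over the discrete niche membership; step model: over
        the fractional niche loads.
        """
        if self.additive:
            nn = self.state.niche_counts
            sizes = nn.sum(axis=1)
            num = nn @ self._bg
        else:
            loads = self.state.counts * self.space.fmat
            sizes = loads.sum(axis=1)
            num = loads @ self._bg
        out = []
        for j in (0, 1):
            out.append(float(num[j] / sizes[j]) if sizes[j] > 0 else float("nan"))
        return out[0], out[1]

    def niche_sizes(self) -> Tuple[float, float]:
        if self.additive:
            sizes = self.state.niche_counts.sum(axis=1)
        else:
            sizes = (self.state.counts * self.space.fmat).sum(axis=1)
        return float(sizes[0]), float(sizes[1])


def step_generation(
    state: PopulationState,
    params: ModelParams,
    space: GenotypeSpace,
    rng: np.random.Generator,
) -> PopulationState:
    """Functional one-generation step (convenience wrapper over
    :class:`Simulation` for callers that do not hold a simulation object)."""
    sim = Simulation(params, state, rng=rng, space=space)
    return sim.step()
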