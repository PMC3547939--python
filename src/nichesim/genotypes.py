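"""Genotype space, niche assignment, and experimental initial states.

Genotypes are integer bitmasks: the low ``L`` bits are the adaptive loci
(bit value 1 = allele adapted to niche 1), the next ``B`` bits are neutral
background loci.  The population is stored as a dense count vector over all
``2**(L+B)`` genotype classes, which keeps the dynamics exact at carrying
capacities of 10^6 per niche while the state stays tiny (<= 2^12 classes for
realistic locus numbers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .params import ModelParams

__all__ = [
    "GenotypeSpace",
    "PopulationState",
    "niche_fraction",
    "assign_niche",
    "niche_loads",
    "initial_state_appearance",
    "initial_state_completeness",
]


class GenotypeSpace:
    """Enumeration of all ``2**(L+B)`` genotypes with precomputed niche data.

    Attributes
    ----------
    f1, f0 : ndarray of shape (size,)
        Fraction of adaptive loci matching niche 1 (resp. 0) per genotype;
        background bits never contribute.
    fmat : ndarray of shape (2, size)
        Rows ``(f0, f1)``.
    bits : ndarray of shape (L+B, size)
        Bit value of every locus for every genotype.
    idx_niche0, idx_niche1, idx_tie : ndarray
        Genotype indices preferring niche 0 (f1 < 0.5), niche 1 (f1 > 0.5),
        and the tie class (f1 == 0.5, possible only for even L).
    opt0, opt1 : ndarray
        Indices whose adaptive part is all-0 (resp. all-1), any background.
    """

    def __init__(self, L: int, B: int = 1):
        if L < 1 or B < 0:
            raise ValueError(f"need L >= 1 and B >= 0, got L={L}, B={B}")
        self.L = L
        self.B = B
        self.n_loci = L + B
        self.size = 1 << (L + B)
        g = np.arange(self.size, dtype=np.int64)
        self.bits = ((g[None, :] >> np.arange(L + B)[:, None]) & 1).astype(np.int64)
        self.adaptive_bits = self.bits[:L]  # (L, size)
        self.background_bits = self.bits[L:]  # (B, size)
        self.f1 = self.adaptive_bits.sum(axis=0) / L
        self.f0 = 1.0 - self.f1
        self.fmat = np.stack([self.f0, self.f1])
        self.adaptive_part = g & ((1 << L) - 1)
        self.idx_niche0 = np.where(self.f1 < 0.5)[0]
        self.idx_niche1 = np.where(self.f1 > 0.5)[0]
        self.idx_tie = np.where(self.f1 == 0.5)[0]
        self.opt0 = np.where(self.adaptive_part == 0)[0]
        self.opt1 = np.where(self.adaptive_part == (1 << L) - 1)[0]
        # per-locus genotype indices with the bit clear, and their images
        # under setting the bit (used by the batch recombination sampler)
        self.idx_bit_clear = [np.where(self.bits[l] == 0)[0] for l in range(L + B)]
        self.idx_bit_set = [idx + (1 << l) for l, idx in enumerate(self.idx_bit_clear)]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenotypeSpace(L={self.L}, B={self.B}, size={self.size})"


@dataclass
class PopulationState:
    """Per-genotype abundances at one generation.

    ``counts`` is the pooled count vector over all genotype classes.  For the
    additive model, ``niche_counts`` (shape ``(2, size)``) records where each
    genotype's individuals currently sit; rows sum to ``counts``.  The step
    model has no discrete niche membership (individuals shuttle), so
    ``niche_counts`` is None and fractional niche loads are derived on demand
    via :func:`niche_loads`.
    """

    generation: int
    counts: np.ndarray
    niche_counts: Optional[np.ndarray] = None

    @property
    def N_total(self) -> int:
        return int(self.counts.sum())

    def copy(self) -> "PopulationState":
        return PopulationState(
            self.generation,
            self.counts.copy(),
            None if self.niche_counts is None else self.niche_counts.copy(),
        )


def niche_fraction(genotype: int, space: GenotypeSpace, niche: int) -> float:
    """Fraction of adaptive loci in ``genotype`` carrying alleles adapted to
    ``niche``; background bits are ignored.

    E.g. with L=5 the genotype 11100 (bitmask 0b00111) has fraction 3/5 for
    niche 1.
    """
    if not (0 <= genotype < space.size):
        raise ValueError(
            f"genotype index {genotype} outside space of size {space.size}"
        )
    if niche not in (0, 1):
        raise ValueError(f"niche must be 0 or 1, got {niche}")
    f1 = float(space.f1[genotype])
    return f1 if niche == 1 else 1.0 - f1


def assign_niche(
    state: PopulationState, space: GenotypeSpace, rng: np.random.Generator
) -> PopulationState:
    """Place every individual in the niche its genotype prefers (additive).

    Genotypes with f1 > 0.5 go to niche 1, f1 < 0.5 to niche 0; at exactly
    0.5 the class is split by an unbiased binomial draw, redrawn every
    generation (the state carries no lineage memory).
    """
    state.niche_counts = _assign(state.counts, space, rng)
    return state


def _assign(
    counts: np.ndarray, space: GenotypeSpace, rng: np.random.Generator
) -> np.ndarray:
    nn = np.zeros((2, space.size), dtype=np.int64)
    nn[0, space.idx_niche0] = counts[space.idx_niche0]
    nn[1, space.idx_niche1] = counts[space.idx_niche1]
    tie = space.idx_tie
    if tie.size:
        to1 = rng.binomial(counts[tie], 0.5)
        nn[1, tie] = to1
        nn[0, tie] = counts[tie] - to1
    return nn


def niche_loads(state: PopulationState, space: GenotypeSpace) -> np.ndarray:
    """Fractional per-niche loads for the step model, shape ``(2, size)``.

    Genotype i contributes ``count_i * f_{i,j}`` to niche j's population
    size: one individual of 010 (L=3) adds 2/3 of a count to niche 0 and 1/3
    to niche 1.  Loads over both niches sum to the total population size.
    """
    return state.counts[None, :] * space.fmat


def _apportion(total: int, n_classes: int) -> np.ndarray:
    """Split ``total`` into ``n_classes`` near-equal integers: floor, then the
    remainder goes one each to the lowest-index classes (round-robin)."""
    base, rem = divmod(int(total), int(n_classes))
    out = np.full(n_classes, base, dtype=np.int64)
    out[:rem] += 1
    return out


def initial_state_appearance(
    params: ModelParams, space: Optional[GenotypeSpace] = None
) -> PopulationState:
    """Experiment-1 start: the derived niche has just appeared and is empty.

    Niche 0 holds K individuals: 95% the ancestral optimal (all-0) genotype,
    5% carrying a niche-1 allele at a single adaptive locus, spread equally
    over the L loci (integer remainder assigned round-robin in genotype-index
    order).  Background bits are all 0.
    """
    space = space or GenotypeSpace(params.L, params.B)
    K = int(params.K)
    if K < 20 * params.L:
        warnings.warn(
            f"K={K} is small relative to L={params.L}: single-mutant classes "
            "hold fewer than ~20 cells each, so the 95%/5% split is coarse",
            stacklevel=2,
        )
    n_mut = int(round(0.05 * K))
    counts = np.zeros(space.size, dtype=np.int64)
    counts[0] = K - n_mut
    singles = np.array([1 << l for l in range(params.L)], dtype=np.int64)
    counts[singles] = _apportion(n_mut, params.L)
    # everyone starts in the ancestral niche, including f=0.5 ties (even L)
    nn = np.zeros((2, space.size), dtype=np.int64)
    nn[0] = counts
    return PopulationState(generation=0, counts=counts, niche_counts=nn)


def initial_state_completeness(
    params: ModelParams,
    with_background_association: bool = False,
    space: Optional[GenotypeSpace] = None,
    rng: Optional[np.random.Generator] = None,
) -> PopulationState:
    """Experiment-2/3 start: speciation fast-forwarded past drift escape.

    The pooled population of size 2K holds 95% ancestral optimal (all-0),
    1% derived optimal (all-1), and 4% spread uniformly over the 2^L - 2
    intermediate adaptive genotypes.  With ``with_background_association``
    every individual's background bit equals its assigned niche (allele 0 in
    niche 0 only, allele 1 in niche 1 only); tie genotypes get the bit of
    their drawn niche.  Otherwise background bits are all 0.
    """
    space = space or GenotypeSpace(params.L, params.B)
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    total = 2 * int(params.K)
    n_classes = (1 << params.L) - 2
    n_anc = int(round(0.95 * total))
    n_der = int(round(0.01 * total))
    n_int = total - n_anc - n_der
    if n_classes > n_int:
        # smallest K for which every intermediate class gets >= 1 cell
        k_min = -(-n_classes // 2) / 0.04  # ceil(n_classes/2) / 0.04
        raise ValueError(
            f"{n_classes} intermediate genotypes cannot be spread over "
            f"{n_int} cells (4% of 2K={total}); smallest feasible K is "
            f"about {int(np.ceil(k_min))}"
        )
    L = params.L
    all1 = (1 << L) - 1
    adaptive = np.zeros(1 << L, dtype=np.int64)
    adaptive[0] = n_anc
    adaptive[all1] = n_der
    adaptive[1:all1] = _apportion(n_int, n_classes)

    counts = np.zeros(space.size, dtype=np.int64)
    nn = np.zeros((2, space.size), dtype=np.int64)
    bg_mask = ((1 << params.B) - 1) << L
    for a in range(1 << L):
        n = int(adaptive[a])
        if n == 0:
            continue
        f1 = bin(a).count("1") / L
        if f1 > 0.5:
            split = (0, n)
        elif f1 < 0.5:
            split = (n, 0)
        else:
            to1 = int(rng.binomial(n, 0.5))
            split = (n - to1, to1)
        for niche, cnt in enumerate(split):
            if cnt == 0:
                continue
            g = a | (bg_mask if (with_background_association and niche == 1) else 0)
            counts[g] += cnt
            nn[niche, g] += cnt
    return PopulationState(generation=0, counts=counts, niche_counts=nn)
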