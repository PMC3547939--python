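"""Sympatric gene-conversion recombination.

After growth all microbes enter a common pool, regardless of niche, and
recombine at random with rate ``r`` per individual per locus, giving an
expected ``r * N * (B+L)`` events per generation.  Each event picks a
donor/acceptor pair and one locus uniformly at random and copies the donor's
allele over the acceptor's (non-reciprocal gene conversion): population size
is invariant, per-locus allele frequencies are martingales, and an allele
absent from the pool can never be created.

Two samplers are provided: an exact event-by-event oracle
(:func:`recombine_sequential`) and a statistically faithful aggregated
sampler (:func:`recombine_batch`) that handles the ~10^5 events per
generation arising at high recombination rates without looping over
individuals.
"""

from __future__ import annotations

import warnings

import numpy as np

from .genotypes import GenotypeSpace

__all__ = ["event_count", "recombine_sequential", "recombine_batch"]


def event_count(
    r: float, N: int, L: int, B: int, rng: np.random.Generator
) -> int:
    """Number of gene-conversion events this generation,
    ``m ~ Poisson(r * N * (B + L))``.

    The per-individual-per-locus rate reading makes the count Poisson with
    the stated expectation r*N*(B+L); r=0 gives m=0 always.
    """
    if N < 0:
        raise ValueError("population size must be non-negative")
    lam = r * N * (L + B)
    if lam == 0:
        return 0
    return int(rng.poisson(lam))


def recombine_sequential(
    counts: np.ndarray, m: int, space: GenotypeSpace, rng: np.random.Generator
) -> np.ndarray:
    """Exact oracle: apply ``m`` conversion events one at a time.

    For each event an acceptor and a donor individual are drawn uniformly
    from the current pool (self-donation allowed, a silent no-op) and one of
    the B+L loci is drawn uniformly; the acceptor's allele at that locus is
    set to the donor's.  The donor is unchanged and N is conserved.
    """
    new = counts.astype(np.int64).copy()
    for _ in range(int(m)):
        N = int(new.sum())
        if N < 2:
            warnings.warn(
                "recombination skipped: fewer than 2 individuals in the pool",
                stacklevel=2,
            )
            break
        cum = np.cumsum(new)
        ga = int(np.searchsorted(cum, rng.integers(N), side="right"))
        gd = int(np.searchsorted(cum, rng.integers(N), side="right"))
        locus = int(rng.integers(space.n_loci))
        donor_allele = (gd >> locus) & 1
        g2 = (ga & ~(1 << locus)) | (donor_allele << locus)
        new[ga] -= 1
        new[g2] += 1
    return new


def recombine_batch(
    counts: np.ndarray, m: int, space: GenotypeSpace, rng: np.random.Generator
) -> np.ndarray:
    """Aggregated sampler, statistically equivalent to the sequential oracle
    up to O(m/N) within-generation ordering effects.

    The ``m`` events are allocated to (locus, acceptor-genotype) cells by a
    single multinomial draw with locus uniform and acceptors weighted by the
    genotype frequencies frozen at phase start; each event's donor allele is
    1 with probability equal to the frozen pool-wide allele-1 frequency at
    that locus.  Events whose donor allele equals the acceptor's are silent.
    """
    counts = counts.astype(np.int64)
    N = int(counts.sum())
    if m == 0:
        return counts.copy()
    if N < 2:
        warnings.warn(
            "recombination skipped: fewer than 2 individuals in the pool",
            stacklevel=2,
        )
        return counts.copy()
    n_loci = space.n_loci
    freq = counts / N
    p1 = (space.bits @ counts) / N  # frozen allele-1 frequency per locus
    probs = np.broadcast_to(freq / n_loci, (n_loci, space.size)).ravel()
    events = rng.multinomial(int(m), probs).reshape(n_loci, space.size)
    donor1 = rng.binomial(events, np.broadcast_to(p1[:, None], events.shape))
    donor0 = events - donor1
    new = counts.copy()
    for l in range(n_loci):
        src0 = space.idx_bit_clear[l]  # acceptors with the bit clear
        dst1 = space.idx_bit_set[l]
        # donor allele 1 converts bit-clear acceptors; clamp to what remains
        mv = np.minimum(donor1[l, src0], new[src0])
        new[src0] -= mv
        new[dst1] += mv
        # donor allele 0 converts bit-set acceptors
        mv = np.minimum(donor0[l, dst1], new[dst1])
        new[dst1] -= mv
        new[src0] += mv
    return new


def recombine(
    counts: np.ndarray,
    m: int,
    space: GenotypeSpace,
    rng: np.random.Generator,
    mode: str = "batch",
) -> np.ndarray:
    """Dispatch on ``mode`` ('batch' or 'sequential')."""
    if mode == "batch":
        return recombine_batch(counts, m, space, rng)
    if mode == "sequential":
        return recombine_sequential(counts, m, space, rng)
    raise ValueError(f"unknown recombination mode {mode!r}")
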