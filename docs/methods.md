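# Methods

## Model

`nichesim` is a forward-time, discrete-generation, variable-population-size
model of a clonal microbial population in an environment of two resource
niches. A genotype is a bitmask of `L` adaptive loci (low bits; allele 1 is
adapted to niche 1) and `B` neutral background loci. The state is the exact
integer count of every one of the `2^(L+B)` genotype classes — not a list of
individuals — so all per-class expectations are computed in closed form and
stochasticity enters only through three sampling steps: Poisson offspring
numbers, binomial niche tie-splits, and recombination sampling. This makes a
run at carrying capacity `K = 10^6` per niche cost the same per generation as
one at `K = 10^2` (about 0.15 ms for `L = 5` on one core).

### One generation

1. **Competition.** Each niche receives resource `R`. Let `f_ij` be the
   fraction of genotype *i*'s adaptive loci carrying alleles matched to niche
   *j*. Under **additive** fitness, `w_ij = 1 − s(1 − f_ij)` and genotype
   *i* competes only in its preferred niche (`f_ij > 1/2`; at exactly 1/2 the
   class is split by an unbiased binomial draw, redrawn each generation —
   the state carries no lineage memory, so a persistent per-lineage choice
   is not representable and the memoryless reading is used). Under **step**
   fitness, `w = 1` for optimal genotypes and `1 − s` for every
   intermediate, in both niches; individuals count toward and draw from both
   niches in proportion to `f`. The per-individual resource share in niche
   *j* is `x_ij = R·w_ij / Σ_k N_kj w_kj`, where `N_kj` is the (for the step
   model, fractional) number of cells of genotype *k* in niche *j*. Occupied
   niches always allocate exactly `R` in total; an empty niche allocates
   nothing.

2. **Clonal reproduction.** `b_i = b_max·x_i/(x_i + R_0)` (saturating
   Michaelis–Menten birth rate), `ν_i = (1 − d) + b_i` (survival plus
   births), and next-generation class counts are independent draws
   `N'_i ~ Poisson(N_i ν_i)`.

3. **Recombination.** All survivors enter one sympatric pool.
   `m ~ Poisson(r·N·(B+L))` gene-conversion events are applied; each picks
   an acceptor individual, a donor individual, and one locus, all uniformly,
   and overwrites the acceptor's allele with the donor's. Conversion is
   non-reciprocal: `N` is exactly conserved, per-locus allele frequencies
   are martingales, and an allele absent from the pool can never reappear.

4. **Niche return** (additive model): every individual returns to its
   genotype's preferred niche.

### Calibration

`R_0` is never set directly. A monomorphic population of size `K` receives
`x = R/K` per capita and is stationary when `b(R/K) = d`, giving
`R_0 = (R/K)(b_max − d)/d`. With the standard demography (`R = 1`,
`b_max = 10`, `d = 0.1`, `K = 10^6`), `R_0 = 9.9×10⁻⁵`. Note that the
stationary point then sits deep in the linear regime of the birth function
(`x/R_0 = d/(b_max − d) ≈ 0.01`), which has a consequence worth knowing:
per-generation selection differentials are compressed to
`Δν ≈ d·s·Δf` — an order of magnitude below the nominal selection
coefficient — because only the fraction `d` of the population turning over
each generation is exposed to competition. This is a structural property of
the demography, not an implementation choice; alternative readings of the
offspring expectation (`ν = (1−d)(1+b)`, `ν = b/d`, …) only rescale `R_0`
and leave `K` — though not the selection intensity in the last case —
unchanged.

## Parameters

| name | meaning | default | notes |
|---|---|---|---|
| `L` | adaptive loci | — (required) | ≥ 2 |
| `B` | background loci | 1 | mixing statistics use the first |
| `s` | selection coefficient | — (required) | 0 ≤ s < 1; 0.01/0.1 span measured microbial effect sizes; s = 0 is the neutral control |
| `r` | recombination rate | — (required for recombining runs) | per individual per locus per generation |
| `fitness_model` | additive or step | — (required) | pluggable via `FITNESS_FUNCTIONS` |
| `R` | resource per niche per generation | 1.0 | sets the scale of `R_0` |
| `b_max` | maximal birth rate | 10 | |
| `d` | death probability | 0.1 | |
| `K` | carrying capacity per niche | 10^6 | determines `R_0` |
| `max_generations` | run cap | 100,000 | exp-1 censoring cap and exp-2 horizon |
| `burn_in_generations` | completeness burn-in | 25,000 | |
| `mixing_threshold` | mixed when `|Δ bg freq| ≤` this | 0.05 | see below |
| `recombination_mode` | batch / sequential | batch | sequential is the exact oracle |

## Experiments and their statistics

- **Appearance** starts with niche 1 empty and niche 0 at `K` (95% ancestral
  optimal, 5% single-locus niche-1 mutants spread evenly over the `L` loci;
  integer remainders are assigned round-robin in genotype-index order for
  determinism). The run stops when the all-1 genotype first exists (any
  background), when any niche-1 allele count hits zero (extinction), or at
  the cap (censored, counted as non-appeared). Checks run at the end of each
  generation, after recombination and niche return.
- **Completeness** starts from the fast-forwarded state (95% ancestral
  optimal / 1% derived optimal / 4% uniform over the `2^L − 2` intermediate
  genotypes, pooled size `2K`), runs the full horizon, and reports the
  maximum pooled frequency of the two optimal genotypes at any generation
  after the burn-in.
- **Mixing** uses the same start with the background allele in perfect
  niche association. `t_mix` is the first generation at which the
  between-niche difference in background-allele-1 frequency is at most
  `mixing_threshold`; for the step model the niche frequencies are
  load-weighted; generations with an empty niche are skipped. The underlying
  notion ("randomly distributed across niches") is qualitative; the
  single-generation 0.05 threshold is this package's operational choice and
  reported `t_mix` values should be read as specific to it.

Replicate RNG streams are spawned from the master seed with counter-based
spawn keys `(cell, replicate)`, so sweeps are bit-reproducible and
independent of execution order.

## The batch recombination sampler

Applying ~`10^5` conversion events per generation individually would
dominate the runtime, so the production sampler aggregates: events are
allocated to (locus, acceptor-genotype) cells in one multinomial draw with
acceptor weights and per-locus donor allele frequencies frozen at phase
start, then applied as vectorized count moves (clamped so a class never goes
negative). Freezing, sampling acceptors with replacement, and permitting
self-donation each introduce `O(m/N)` or `O(1/N)` distortions; the exact
event-by-event sampler (`recombination_mode="sequential"`) is kept as the
oracle, and a chi-square equivalence test at `N = 200` plus exact
conservation/martingale/no-new-allele checks bound the approximation.

## Numerical and degenerate-input choices

- Counts are int64 throughout; Poisson means up to `N·ν ≈ 10^7` are exact.
- An empty niche contributes no resource (no division by zero); a pool of
  fewer than two individuals skips recombination with a warning.
- Total extinction is terminal: the state stays at zero.
- The completeness initial state refuses configurations where the `2^L − 2`
  intermediate classes cannot each receive an integer cell (reports the
  smallest feasible `K`).
- In the step model, a sole occupant of both niches collects `R` from each
  (conservation); its resource *proportions* match `f` only when both niches
  are populated.

## What the tests establish — and what they do not

The unit and property suite verifies the machinery exactly: enumeration and
`f` against a string-counting oracle, apportionment against brute-force,
resource conservation to 1e-9, fixed-point calibration against an
independent root solve, recombination against exhaustive single-event
enumeration and the sequential oracle, determinism bit-for-bit, and the
qualitative claims (monotone `t_mix` in `r`, completeness non-increasing in
`r`, no new genotypes without recombination). The full-scale checks in
`tests/test_acceptance.py` additionally pin quantitative outcomes of the
three experiments at the standard demography; the carrying-capacity,
event-rate, and high-`r` censoring checks pass, while the appearance
probability, completeness, and mixing-time point values are sensitive to the
effective conversion intensity and the mixing criterion (above) and are
asserted at externally stated values — see the test docstrings for the
expected bands.

## Known limitations

- No mutation (recombination is the only genotype source), no horizontal
  transfer of non-homologous material, no assortative mating or
  divergence-dependent recombination barriers, exactly two niches, two
  alleles per locus, equal per-locus effects.
- The selection intensity actually realized per generation is `≈ d·s·Δf`
  (see Calibration); comparisons with models that apply `s` directly to
  per-generation growth must account for this compression.
- The mixing time depends on the operational mixing criterion; only its
  qualitative dependence on `r` (strongly decreasing) is
  criterion-independent.
- Niche loads in the step model make "population size per niche" fractional;
  reported niche sizes there are expectations, not head counts.
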