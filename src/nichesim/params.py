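"""Model parameters and demographic calibration.

A two-niche environment is described by a small set of constants: each niche
is replenished with resource ``R`` every generation, cells divide at a
resource-saturating rate capped at ``b_max``, die with probability ``d``, and
the half-saturation constant ``R_0`` of the birth function is always derived
from the target carrying capacity ``K`` (the steady-state population size per
niche) rather than set directly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


def calibrate_R0(K: float, R: float = 1.0, b_max: float = 10.0, d: float = 0.1) -> float:
    """Half-saturation constant that makes a monomorphic population of size
    ``K`` stationary.

    At the steady state each of the ``K`` identical cells receives ``R/K``
    resource, and stationarity requires births to balance deaths,
    ``b(R/K) = d``.  Solving ``b_max * x / (x + R_0) = d`` at ``x = R/K``
    gives ``R_0 = (R/K) * (b_max - d) / d``.

    Raises
    ------
    ValueError
        If ``b_max <= d`` (no stationary size exists), or ``d <= 0`` or
        ``K <= 0`` or ``R <= 0``.
    """
    if K <= 0:
        raise ValueError(f"carrying capacity K must be positive, got {K}")
    if R <= 0:
        raise ValueError(f"resource R must be positive, got {R}")
    if d <= 0:
        raise ValueError(f"death rate d must be positive to calibrate R_0, got {d}")
    if b_max <= d:
        raise ValueError(
            f"b_max ({b_max}) must exceed the death rate d ({d}); otherwise "
            "no positive steady-state population size exists"
        )
    return (R / K) * (b_max - d) / d


FITNESS_MODELS = ("additive", "step")


@dataclass
class ModelParams:
    """All constants and switches of one simulation configuration.

    Parameters
    ----------
    L : int
        Number of biallelic adaptive loci (>= 2).
    s : float
        Selection coefficient, 0 < s < 1.
    fitness_model : str
        ``"additive"`` (fitness linear in the niche-matched fraction f,
        competition confined to the preferred niche) or ``"step"`` (all
        intermediates pay the identical cost s and draw resources from both
        niches).
    B : int
        Number of neutral background loci (default 1).
    r : float
        Recombination rate per individual per locus per generation (>= 0).
    R : float
        Resource amount supplied to each niche per generation.
    b_max : float
        Maximal per-cell birth rate.
    d : float
        Death probability per generation, 0 <= d < 1.
    K : int
        Target carrying capacity per niche; fixes R_0 via :func:`calibrate_R0`.
    max_generations : int
        Hard cap on the generation loop.
    burn_in_generations : int
        Generations excluded from the completeness statistic.
    mixing_threshold : float
        Between-niche background-allele frequency difference at or below which
        the population counts as mixed.
    seed : int
        Master RNG seed.
    recombination_mode : str
        ``"batch"`` (aggregated sampler, production) or ``"sequential"``
        (event-by-event oracle, for tests and small N).
    trajectory_every : int
        Record a trajectory sample every this many generations (0 = off).
    """

    L: int
    s: float
    fitness_model: str
    B: int = 1
    r: float = 0.0
    R: float = 1.0
    b_max: float = 10.0
    d: float = 0.1
    K: int = 1_000_000
    max_generations: int = 100_000
    burn_in_generations: int = 25_000
    mixing_threshold: float = 0.05
    seed: int = 0
    recombination_mode: str = "batch"
    trajectory_every: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.L < 2:
            raise ValueError(f"L must be >= 2, got {self.L}")
        if self.B < 1:
            raise ValueError(f"B must be >= 1, got {self.B}")
        if self.r < 0:
            raise ValueError(f"r must be >= 0, got {self.r}")
        # s = 0 admitted as the neutral control
        if not (0 <= self.s < 1):
            raise ValueError(f"s must satisfy 0 <= s < 1, got {self.s}")
        if not (0 <= self.d < 1):
            raise ValueError(f"d must satisfy 0 <= d < 1, got {self.d}")
        if self.b_max <= self.d:
            raise ValueError(f"b_max ({self.b_max}) must exceed d ({self.d})")
        if self.fitness_model not in FITNESS_MODELS:
            raise ValueError(
                f"fitness_model must be one of {FITNESS_MODELS}, got "
                f"{self.fitness_model!r}"
            )
        if self.recombination_mode not in ("batch", "sequential"):
            raise ValueError(
                f"recombination_mode must be 'batch' or 'sequential', got "
                f"{self.recombination_mode!r}"
            )
        if self.K <= 0:
            raise ValueError(f"K must be positive, got {self.K}")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if not (0 < self.mixing_threshold < 1):
            raise ValueError("mixing_threshold must lie in (0, 1)")
        # raises on infeasible demography
        calibrate_R0(self.K, self.R, self.b_max, self.d)

    @property
    def R_0(self) -> float:
        """Half-saturation constant derived from K (never set directly)."""
        return calibrate_R0(self.K, self.R, self.b_max, self.d)

    @property
    def n_loci(self) -> int:
        return self.L + self.B

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["R_0"] = self.R_0
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        d = {k: v for k, v in d.items() if k in _FIELD_NAMES}
        return cls(**d)


_FIELD_NAMES = {f.name for f in dataclasses.fields(ModelParams)}
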