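"""The three in-model experiments and (L, r) parameter sweeps.

Experiment 1 (appearance): from an ancestral niche at carrying capacity
seeded with rare single-locus niche-1 alleles, how often and how fast does
recombination assemble the derived optimal genotype before any niche-1
allele is lost?

Experiment 2 (completeness): once the derived species has escaped drift (1%
of the pool), what is the maximum pooled frequency of optimal genotypes
after an equilibration burn-in — i.e. how complete is speciation?

Experiment 3 (mixing): starting from perfect association of a neutral
background allele with niche, how long until recombination randomizes the
background allele across niches (t_mix)?
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .engine import Simulation
from .genotypes import (
    GenotypeSpace,
    initial_state_appearance,
    initial_state_completeness,
)
from .params import ModelParams

__all__ = ["ReplicateOutcome", "SweepResult", "run_appearance",
           "run_completeness", "run_mixing", "sweep", "EXPERIMENTS"]


@dataclass
class ReplicateOutcome:
    """Summary of one replicate simulation."""

    experiment: str
    seed: int
    appeared: bool = False
    appearance_generation: Optional[int] = None
    extinct: bool = False
    extinction_generation: Optional[int] = None
    censored: bool = False
    completeness: Optional[float] = None
    t_mix: Optional[int] = None
    generations_run: int = 0
    trajectory: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        d = {
            "experiment": self.experiment,
            "seed": self.seed,
            "appeared": self.appeared,
            "appearance_generation": self.appearance_generation,
            "extinct": self.extinct,
            "extinction_generation": self.extinction_generation,
            "censored": self.censored,
            "completeness": self.completeness,
            "t_mix": self.t_mix,
            "generations_run": self.generations_run,
        }
        return d


def _resolve_rng(params: ModelParams, seed: Optional[int]) -> Tuple[int, np.random.Generator]:
    s = params.seed if seed is None else int(seed)
    return s, np.random.default_rng(s)


class _Trajectory:
    """Down-sampled per-generation summaries (every ``trajectory_every``)."""

    def __init__(self, every: int):
        self.every = every
        self.rows: List[dict] = []

    def maybe_record(self, sim: Simulation) -> None:
        if self.every <= 0 or sim.state.generation % self.every != 0:
            return
        n0, n1 = sim.niche_sizes()
        bg0, bg1 = sim.background_freq_by_niche()
        self.rows.append(
            {
                "generation": sim.state.generation,
                "N_niche0": n0,
                "N_niche1": n1,
                "optimal_frequency": sim.optimal_frequency(),
                "bg1_freq_niche0": bg0,
                "bg1_freq_niche1": bg1,
            }
        )

    def frame(self) -> Optional[pd.DataFrame]:
        return pd.DataFrame(self.rows) if self.rows else None


def run_appearance(params: ModelParams, seed: Optional[int] = None) -> ReplicateOutcome:
    """Experiment 1: run until the niche-1 optimal genotype appears, any
    niche-1 allele is lost (extinction), or the generation cap is hit
    (censored; counts as non-appeared)."""
    seed, rng = _resolve_rng(params, seed)
    space = GenotypeSpace(params.L, params.B)
    sim = Simulation(params, initial_state_appearance(params, space), rng=rng, space=space)
    out = ReplicateOutcome(experiment="appearance", seed=seed)
    traj = _Trajectory(params.trajectory_every)
    traj.maybe_record(sim)
    for _ in range(params.max_generations):
        sim.step()
        traj.maybe_record(sim)
        if sim.derived_optimal_count() >= 1:
            out.appeared = True
            out.appearance_generation = sim.state.generation
            break
        if (sim.allele1_counts() == 0).any():
            out.extinct = True
            out.extinction_generation = sim.state.generation
            break
    else:
        out.censored = True
    out.generations_run = sim.state.generation
    out.trajectory = traj.frame()
    return out


def run_completeness(params: ModelParams, seed: Optional[int] = None) -> ReplicateOutcome:
    """Experiment 2: run exactly ``max_generations`` from the fast-forwarded
    state and record the maximum pooled optimal-genotype frequency at any
    generation after ``burn_in_generations``."""
    seed, rng = _resolve_rng(params, seed)
    space = GenotypeSpace(params.L, params.B)
    state = initial_state_completeness(params, space=space, rng=rng)
    sim = Simulation(params, state, rng=rng, space=space)
    out = ReplicateOutcome(experiment="completeness", seed=seed)
    traj = _Trajectory(params.trajectory_every)
    traj.maybe_record(sim)
    best = 0.0
    for _ in range(params.max_generations):
        sim.step()
        traj.maybe_record(sim)
        if sim.state.generation > params.burn_in_generations:
            f = sim.optimal_frequency()
            if f > best:
                best = f
        if sim.state.N_total == 0:
            out.extinct = True
            out.extinction_generation = sim.state.generation
            break
    out.completeness = best
    out.generations_run = sim.state.generation
    out.trajectory = traj.frame()
    return out


def run_mixing(params: ModelParams, seed: Optional[int] = None) -> ReplicateOutcome:
    """Experiment 3: from perfect background/niche association, t_mix is the
    first generation at which the between-niche background-allele-1 frequency
    difference is at most ``mixing_threshold``; censored at the cap.
    Generations with an empty niche are skipped by the criterion."""
    seed, rng = _resolve_rng(params, seed)
    space = GenotypeSpace(params.L, params.B)
    state = initial_state_completeness(
        params, with_background_association=True, space=space, rng=rng
    )
    sim = Simulation(params, state, rng=rng, space=space)
    out = ReplicateOutcome(experiment="mixing", seed=seed)
    traj = _Trajectory(params.trajectory_every)
    traj.maybe_record(sim)
    thr = params.mixing_threshold
    for _ in range(params.max_generations):
        sim.step()
        traj.maybe_record(sim)
        bg0, bg1 = sim.background_freq_by_niche()
        if math.isnan(bg0) or math.isnan(bg1):
            if sim.state.N_total == 0:
                out.extinct = True
                out.extinction_generation = sim.state.generation
                break
            continue
        if abs(bg1 - bg0) <= thr:
            out.t_mix = sim.state.generation
            break
    if out.t_mix is None and not out.extinct:
        out.censored = True
    out.generations_run = sim.state.generation
    out.trajectory = traj.frame()
    return out


EXPERIMENTS = {
    "appearance": run_appearance,
    "completeness": run_completeness,
    "mixing": run_mixing,
}


@dataclass
class SweepResult:
    """Tidy per-replicate table plus per-(L, r) cell summaries."""

    experiment: str
    replicates: pd.DataFrame
    summary: pd.DataFrame
    metadata: Dict = field(default_factory=dict)

    def matrix(self, stat: str) -> pd.DataFrame:
        """Pivot a summary statistic to an L-by-r matrix (both ascending)."""
        return (
            self.summary.pivot(index="L", columns="r", values=stat)
            .sort_index()
            .sort_index(axis=1)
        )


def _child_seed(master_seed: int, cell: int, rep: int) -> int:
    ss = np.random.SeedSequence(master_seed, spawn_key=(cell, rep))
    return int(ss.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF


def sweep(
    grid: Sequence[Tuple[int, float]],
    params: ModelParams,
    replicates: int,
    experiment: str,
    master_seed: Optional[int] = None,
    progress: bool = False,
) -> SweepResult:
    """Run ``replicates`` independent simulations of ``experiment`` for every
    (L, r) cell of ``grid``, using ``params`` as the template.

    Child RNG seeds are derived per (cell, replicate) from the master seed by
    counter-based spawning, so results are reproducible and independent of
    execution order.  A failing replicate is recorded with its error message
    and the sweep continues.
    """
    if not grid:
        raise ValueError("grid must contain at least one (L, r) cell")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment!r}; choose from {sorted(EXPERIMENTS)}")
    run = EXPERIMENTS[experiment]
    master = params.seed if master_seed is None else int(master_seed)

    rows: List[dict] = []
    for ci, (L, r) in enumerate(grid):
        cell_params = params.replace(L=int(L), r=float(r))
        for rep in range(replicates):
            child = _child_seed(master, ci, rep)
            row = {"L": int(L), "r": float(r), "replicate": rep}
            try:
                outcome = run(cell_params, seed=child)
                row.update(outcome.to_dict())
            except Exception as exc:  # noqa: BLE001 - sweep must continue
                row.update({"error": f"{type(exc).__name__}: {exc}", "seed": child})
            rows.append(row)
            if progress:
                print(f"[sweep] L={L} r={r:g} replicate {rep + 1}/{replicates}", flush=True)
    rep_df = pd.DataFrame(rows)

    summaries = []
    for (L, r), cell in rep_df.groupby(["L", "r"]):
        ok = cell[cell["error"].isna()] if "error" in cell.columns else cell
        n = len(ok)
        appeared = ok["appeared"].fillna(False).astype(bool) if "appeared" in ok else pd.Series(dtype=bool)
        times = ok["appearance_generation"].dropna()
        comp = ok["completeness"].dropna()
        tmix = ok["t_mix"].dropna()
        summaries.append(
            {
                "L": L,
                "r": r,
                "n_replicates": n,
                "n_failed": len(cell) - n,
                "p_appearance": float(appeared.mean()) if n else float("nan"),
                "mean_appearance_time": float(times.mean()) if len(times) else float("nan"),
                "sd_appearance_time": float(times.std(ddof=1)) if len(times) > 1 else float("nan"),
                "mean_completeness": float(comp.mean()) if len(comp) else float("nan"),
                "sd_completeness": float(comp.std(ddof=1)) if len(comp) > 1 else float("nan"),
                "mean_t_mix": float(tmix.mean()) if len(tmix) else float("nan"),
                "sd_t_mix": float(tmix.std(ddof=1)) if len(tmix) > 1 else float("nan"),
                "n_censored": int(ok["censored"].fillna(False).sum()) if "censored" in ok else 0,
            }
        )
    summary = pd.DataFrame(summaries)
    meta = {
        "experiment": experiment,
        "master_seed": master,
        "replicates": replicates,
        "params": params.to_dict(),
    }
    return SweepResult(experiment=experiment, replicates=rep_df, summary=summary, metadata=meta)
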