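"""Parameter fitting by two-objective least squares with NSGA-II.

The behavioural data being fitted are the two engagement curves (lever and
magazine, probability per 50-trial block).  Each candidate parameter vector
is simulated for a small number of repetition agents, the repetition-mean
curves are compared to the target curves, and the summed squared per-block
differences for the two stimuli form two *independent* objectives — lever
probabilities are systematically easier to fit than magazine probabilities,
so collapsing them into one score would trade one off against the other
silently.

NSGA-II (elitist non-dominated sorting with crowding distance, simulated
binary crossover and polynomial mutation) searches the box-bounded parameter
space.  Candidate evaluation is stochastic, so all candidates share the same
repetition seeds (common random numbers) and the whole fit is deterministic
given its seed.  The representative individual is chosen automatically as
the front member minimising the sum of min--max-normalised objectives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._fastsim import HAVE_NUMBA, simulate_agent_curves, simulate_group_curves
from .protocols import BLOCK_TRIALS, AgentConfig, GroupSpec, Schedule, _run_group

__all__ = [
    "TargetCurves",
    "GAConfig",
    "FitResult",
    "FITTABLE_BOUNDS",
    "objectives",
    "fit_nsga2",
    "recovery_report",
]


@dataclass(frozen=True)
class TargetCurves:
    """Target engagement probabilities per block, one curve per stimulus."""

    lever: tuple[float, ...]
    magazine: tuple[float, ...]
    block_trials: int = BLOCK_TRIALS

    def __post_init__(self) -> None:
        if len(self.lever) != len(self.magazine):
            raise ValueError("lever and magazine curves must have equal length")
        for v in (*self.lever, *self.magazine):
            if not 0.0 <= v <= 1.0:
                raise ValueError("target probabilities must lie in [0, 1]")

    @property
    def n_blocks(self) -> int:
        return len(self.lever)


#: Conservative box bounds for every fittable parameter.
FITTABLE_BOUNDS: dict[str, tuple[float, float]] = {
    "omega": (0.0, 1.0),
    "alpha": (0.01, 1.0),
    "gamma": (0.0, 0.995),
    "beta": (0.01, 2.0),
    "u": (0.0, 1.0),
    "v0_magazine": (0.0, 1.0),
    "v0_food": (0.0, 1.0),
    "q0": (0.0, 1.0),
}


@dataclass(frozen=True)
class GAConfig:
    population: int = 200
    generations: int = 1000
    mutation_rate: float = 0.1
    crossover_rate: float = 0.5
    mutation_eta: float = 20.0
    crossover_eta: float = 15.0
    reps: int = 14
    draws_per_generation: int = 3
    seed: int = 0
    bounds: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(FITTABLE_BOUNDS))

    def __post_init__(self) -> None:
        if self.population % 2:
            raise ValueError("population size must be even")
        for r in (self.mutation_rate, self.crossover_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")


@dataclass
class FitResult:
    param_names: tuple[str, ...]
    front_params: np.ndarray      # (n_front, n_params)
    front_objectives: np.ndarray  # (n_front, 2)
    representative: dict[str, float]
    representative_objectives: tuple[float, float]
    history: list[float]          # per-generation best summed-normalised objective


def _simulated_curves(config: AgentConfig, schedule: Schedule, reps: int,
                      seed: int, block_trials: int = BLOCK_TRIALS
                      ) -> tuple[np.ndarray, np.ndarray]:
    lev, mag = _per_agent_curves(config, schedule, reps, seed, block_trials)
    return lev.mean(axis=0), mag.mean(axis=0)


def _per_agent_curves(config: AgentConfig, schedule: Schedule, reps: int,
                      seed: int, block_trials: int = BLOCK_TRIALS
                      ) -> tuple[np.ndarray, np.ndarray]:
    if HAVE_NUMBA and config.variant == "model":
        return simulate_agent_curves(config, reps, schedule.n_sessions,
                                     schedule.trials_per_session, [seed],
                                     block_trials)
    spec = GroupSpec("fit", reps, config)
    res = _run_group(spec, schedule, [seed], collect_rpes=False)
    n_blocks = res.lever.shape[1] // block_trials
    out = []
    for flags in (res.lever, res.magazine):
        out.append(flags[:, : n_blocks * block_trials]
                   .reshape(flags.shape[0], n_blocks, block_trials).mean(axis=2))
    return out[0], out[1]


def _default_schedule(target: TargetCurves) -> Schedule:
    total = target.n_blocks * target.block_trials
    tps = min(25, target.block_trials)
    return Schedule(n_sessions=max(1, total // tps), trials_per_session=tps)


def _debiased_objectives(candidate: AgentConfig, target: TargetCurves,
                         schedule: Schedule | None, reps: int,
                         seed: int) -> tuple[float, float]:
    """Unbiased estimate of the *population* curve distance.

    The plain squared error of a ``reps``-agent mean curve has expectation
    bias^2 + Var(mean); the variance term depends on the candidate (curves
    saturating at 0 or 1 have almost no across-agent variance), which would
    systematically pull a noisy search toward saturated regimes.  Subtracting
    the sample-variance estimate removes that tilt; the result can be
    slightly negative under noise, which is harmless inside the genetic
    search.
    """
    schedule = schedule or _default_schedule(target)
    lev, mag = _per_agent_curves(candidate, schedule, reps, seed, target.block_trials)
    out = []
    for sim, ref in ((lev, target.lever), (mag, target.magazine)):
        mean = sim.mean(axis=0)
        var = sim.var(axis=0, ddof=1) / reps if reps > 1 else np.zeros_like(mean)
        out.append(float(np.sum((mean - np.asarray(ref)) ** 2 - var)))
    return out[0], out[1]


def objectives(candidate: AgentConfig, target: TargetCurves,
               schedule: Schedule | None = None, reps: int = 14,
               seed: int = 0) -> tuple[float, float]:
    """Least-squares distance of repetition-mean curves to the target.

    Returns ``(lever_lsq, magazine_lsq)``: the sums of squared per-block
    differences, each stimulus scored separately.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    schedule = schedule or _default_schedule(target)
    lev, mag = _simulated_curves(candidate, schedule, reps, seed, target.block_trials)
    if len(lev) != target.n_blocks:
        raise ValueError(
            f"curve length mismatch: simulation has {len(lev)} blocks, target {target.n_blocks}"
        )
    lever_lsq = float(np.sum((lev - np.asarray(target.lever)) ** 2))
    mag_lsq = float(np.sum((mag - np.asarray(target.magazine)) ** 2))
    return lever_lsq, mag_lsq


# ----------------------------------------------------------------------
# NSGA-II machinery
# ----------------------------------------------------------------------

def _dominates(f1: np.ndarray, f2: np.ndarray) -> bool:
    return bool(np.all(f1 <= f2) and np.any(f1 < f2))


def fast_non_dominated_sort(F: np.ndarray) -> list[list[int]]:
    """Indices grouped into Pareto fronts (front 0 first)."""
    n = len(F)
    S: list[list[int]] = [[] for _ in range(n)]
    dominated_count = np.zeros(n, dtype=int)
    fronts: list[list[int]] = [[]]
    for p in range(n):
        for q in range(n):
            if p == q:
                continue
            if _dominates(F[p], F[q]):
                S[p].append(q)
            elif _dominates(F[q], F[p]):
                dominated_count[p] += 1
        if dominated_count[p] == 0:
            fronts[0].append(p)
    i = 0
    while fronts[i]:
        nxt: list[int] = []
        for p in fronts[i]:
            for q in S[p]:
                dominated_count[q] -= 1
                if dominated_count[q] == 0:
                    nxt.append(q)
        i += 1
        fronts.append(nxt)
    return fronts[:-1]


def crowding_distance(F: np.ndarray) -> np.ndarray:
    n, m = F.shape
    d = np.zeros(n)
    for j in range(m):
        order = np.argsort(F[:, j], kind="stable")
        d[order[0]] = d[order[-1]] = np.inf
        span = F[order[-1], j] - F[order[0], j]
        if span <= 0:
            continue
        for k in range(1, n - 1):
            d[order[k]] += (F[order[k + 1], j] - F[order[k - 1], j]) / span
    return d


def _sbx(p1: np.ndarray, p2: np.ndarray, lo: np.ndarray, hi: np.ndarray,
         eta: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    c1, c2 = p1.copy(), p2.copy()
    for j in range(len(p1)):
        if rng.random() < 0.5 and abs(p1[j] - p2[j]) > 1e-14:
            x1, x2 = sorted((p1[j], p2[j]))
            r = rng.random()
            beta = (2 * r) ** (1 / (eta + 1)) if r <= 0.5 else (1 / (2 * (1 - r))) ** (1 / (eta + 1))
            c1[j] = 0.5 * ((x1 + x2) - beta * (x2 - x1))
            c2[j] = 0.5 * ((x1 + x2) + beta * (x2 - x1))
    return np.clip(c1, lo, hi), np.clip(c2, lo, hi)


def _poly_mutation(x: np.ndarray, lo: np.ndarray, hi: np.ndarray, rate: float,
                   eta: float, rng: np.random.Generator) -> np.ndarray:
    y = x.copy()
    for j in range(len(x)):
        if rng.random() < rate:
            r = rng.random()
            span = hi[j] - lo[j]
            if span <= 0:
                continue
            if r < 0.5:
                delta = (2 * r) ** (1 / (eta + 1)) - 1
            else:
                delta = 1 - (2 * (1 - r)) ** (1 / (eta + 1))
            y[j] = np.clip(x[j] + delta * span, lo[j], hi[j])
    return y


def _tournament(rank: np.ndarray, crowd: np.ndarray, rng: np.random.Generator) -> int:
    i, j = rng.integers(len(rank)), rng.integers(len(rank))
    if rank[i] != rank[j]:
        return int(i if rank[i] < rank[j] else j)
    return int(i if crowd[i] >= crowd[j] else j)


def fit_nsga2(
    target: TargetCurves,
    ga: GAConfig,
    param_names: Sequence[str] = ("omega",),
    base_config: AgentConfig | None = None,
    schedule: Schedule | None = None,
) -> FitResult:
    """Fit the named parameters to the target curves.

    Parameters not named keep the values of ``base_config``.  Candidate
    evaluations reuse one fixed set of repetition seeds, so the objective
    surface is a deterministic function of the genome and the returned
    result is fully reproducible from ``ga.seed``.
    """
    base = base_config or AgentConfig()
    for name in param_names:
        if name not in ga.bounds:
            raise ValueError(f"no bounds configured for parameter {name!r}")
    lo = np.array([ga.bounds[n][0] for n in param_names])
    hi = np.array([ga.bounds[n][1] for n in param_names])
    rng = np.random.default_rng([ga.seed, 0xF17])
    # one evaluation seed per generation: all candidates of a generation share
    # repetition streams (common random numbers, a fair within-generation
    # comparison), while re-evaluation across generations averages the
    # Monte-Carlo noise so persistent survivors are good under many draws
    gen_seeds = rng.integers(2**31 - 1, size=ga.generations + 1)
    seen: dict[tuple, set] = {}
    acc: dict[tuple, np.ndarray] = {}

    def evaluate(x: np.ndarray, eval_seed: int) -> tuple[float, float]:
        """Running-mean fitness: each genome accumulates one fresh evaluation
        per generation it survives, so veterans' scores approach their
        expectation and selection is not driven by a single noise draw."""
        key = tuple(np.round(x, 12))
        if key not in seen:
            seen[key] = set()
            acc[key] = np.zeros(3)
        if eval_seed not in seen[key]:
            seen[key].add(eval_seed)
            cfg = replace(base, **dict(zip(param_names, map(float, x))))
            for d in range(ga.draws_per_generation):
                f = _debiased_objectives(cfg, target, schedule, reps=ga.reps,
                                         seed=(eval_seed + 7919 * d) % (2**31 - 1))
                acc[key] += (f[0], f[1], 1.0)
        sums = acc[key]
        return sums[0] / sums[2], sums[1] / sums[2]

    pop = lo + rng.random((ga.population, len(param_names))) * (hi - lo)
    F = np.array([evaluate(x, int(gen_seeds[0])) for x in pop])
    history: list[float] = []

    def ranks_and_crowding(Fm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        fronts = fast_non_dominated_sort(Fm)
        rank = np.empty(len(Fm), dtype=int)
        crowd = np.empty(len(Fm))
        for r, front in enumerate(fronts):
            rank[front] = r
            crowd[front] = crowding_distance(Fm[front])
        return rank, crowd

    rank, crowd = ranks_and_crowding(F)
    for gen in range(ga.generations):
        children = []
        while len(children) < ga.population:
            a = pop[_tournament(rank, crowd, rng)]
            b = pop[_tournament(rank, crowd, rng)]
            if rng.random() < ga.crossover_rate:
                c1, c2 = _sbx(a, b, lo, hi, ga.crossover_eta, rng)
            else:
                c1, c2 = a.copy(), b.copy()
            children.append(_poly_mutation(c1, lo, hi, ga.mutation_rate, ga.mutation_eta, rng))
            children.append(_poly_mutation(c2, lo, hi, ga.mutation_rate, ga.mutation_eta, rng))
        child_pop = np.array(children[: ga.population])
        merged = np.vstack([pop, child_pop])
        gseed = int(gen_seeds[gen + 1])
        merged_F = np.array([evaluate(x, gseed) for x in merged])
        fronts = fast_non_dominated_sort(merged_F)
        keep: list[int] = []
        for front in fronts:
            if len(keep) + len(front) <= ga.population:
                keep.extend(front)
            else:
                cd = crowding_distance(merged_F[front])
                order = np.argsort(-cd, kind="stable")
                keep.extend(np.array(front)[order[: ga.population - len(keep)]])
                break
        pop, F = merged[keep], merged_F[keep]
        rank, crowd = ranks_and_crowding(F)
        history.append(_best_summed(F))

    front_idx = [i for i in range(len(pop)) if rank[i] == 0]
    front_params = pop[front_idx]
    front_F = F[front_idx]
    rep_idx = _representative_index(front_F)
    representative = dict(zip(param_names, map(float, front_params[rep_idx])))
    return FitResult(
        tuple(param_names),
        front_params,
        front_F,
        representative,
        tuple(map(float, front_F[rep_idx])),
        history,
    )


def _normalised(F: np.ndarray) -> np.ndarray:
    lo = F.min(axis=0)
    span = F.max(axis=0) - lo
    span[span <= 0] = 1.0
    return (F - lo) / span


def _best_summed(F: np.ndarray) -> float:
    return float(_normalised(F).sum(axis=1).min())


def _representative_index(front_F: np.ndarray) -> int:
    return int(np.argmin(_normalised(front_F).sum(axis=1)))


def recovery_report(true_params: dict[str, float], fit: FitResult) -> list[dict[str, float]]:
    """Recovered-vs-true table: one row per fitted parameter.

    Reports the representative's estimate, its bias, and the span of the
    parameter over the Pareto front (an identifiability interval: a wide
    span at similar objective values means the data do not pin the
    parameter down).
    """
    rows = []
    for j, name in enumerate(fit.param_names):
        col = fit.front_params[:, j]
        est = fit.representative[name]
        row = {
            "parameter": name,
            "estimate": float(est),
            "front_min": float(col.min()),
            "front_max": float(col.max()),
        }
        if name in true_params:
            row["truth"] = float(true_params[name])
            row["bias"] = float(est - true_params[name])
        rows.append(row)
    return rows
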