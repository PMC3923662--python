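"""Synthetic target curves for fitting and testing.

The behavioural curves the model was built against exist only as published
figures, so this module generates stand-ins: either *model-generated*
targets (simulated from a known parameter vector, optionally noised — the
ground truth for parameter-recovery experiments) or *shape* targets
(logistic rise / decay curves that merely look like acquisition data and owe
nothing to the simulator, for end-to-end smoke tests of the fitting
pipeline).  Everything here is synthetic and is labelled as such.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fitting import TargetCurves, _simulated_curves
from .protocols import BLOCK_TRIALS, AgentConfig, Schedule

__all__ = [
    "SyntheticTargetSpec",
    "make_target",
    "make_shape_target",
    "write_target_csv",
    "read_target_csv",
]


@dataclass(frozen=True)
class SyntheticTargetSpec:
    """Recipe for a model-generated synthetic target with known truth."""

    config: AgentConfig = field(default_factory=AgentConfig)
    n_agents: int = 14
    schedule: Schedule = field(default_factory=Schedule)
    block_trials: int = BLOCK_TRIALS
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def make_target(spec: SyntheticTargetSpec) -> TargetCurves:
    """Simulate the generating configuration and add truncated Gaussian noise.

    With ``noise_sd == 0`` the curves equal the noiseless group means at the
    same seed; noise is added per block and clipped to [0, 1].  Curves come
    from the same engine the fitting objectives use, so recovery experiments
    are free of cross-engine bias.
    """
    lev, mag = _simulated_curves(spec.config, spec.schedule, spec.n_agents,
                                 spec.seed, spec.block_trials)
    if spec.noise_sd > 0:
        rng = np.random.default_rng([spec.seed, 0x7A7])
        lev = np.clip(lev + rng.normal(0, spec.noise_sd, lev.shape), 0, 1)
        mag = np.clip(mag + rng.normal(0, spec.noise_sd, mag.shape), 0, 1)
    return TargetCurves(tuple(map(float, lev)), tuple(map(float, mag)),
                        spec.block_trials)


def make_shape_target(phenotype: str, n_blocks: int = 4,
                      block_trials: int = BLOCK_TRIALS) -> TargetCurves:
    """Logistic-shaped smoke target: a rising curve for the phenotype's
    favoured stimulus and a decaying one for the other.

    ``"ST"`` and ``"GT"`` are mirror assignments of the same two curves.
    These curves are *not* produced by the simulator, so fitting them
    exercises the pipeline without trusting the component under test.
    """
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    if phenotype not in ("ST", "GT"):
        raise ValueError("phenotype must be 'ST' or 'GT'")
    x = np.linspace(-2.0, 3.0, n_blocks)
    rising = 1.0 / (1.0 + np.exp(-2.0 * x))
    decaying = 0.5 / (1.0 + np.exp(2.0 * x)) + 0.05
    rising = tuple(map(float, np.clip(rising, 0, 1)))
    decaying = tuple(map(float, np.clip(decaying, 0, 1)))
    if phenotype == "ST":
        return TargetCurves(rising, decaying, block_trials)
    return TargetCurves(decaying, rising, block_trials)


def write_target_csv(target: TargetCurves, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["block", "lever", "magazine", "block_trials"])
        for i, (lv, mg) in enumerate(zip(target.lever, target.magazine)):
            w.writerow([i, lv, mg, target.block_trials])


def read_target_csv(path: str | Path) -> TargetCurves:
    lever, magazine, bt = [], [], BLOCK_TRIALS
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            lever.append(float(row["lever"]))
            magazine.append(float(row["magazine"]))
            bt = int(row.get("block_trials", bt))
    return TargetCurves(tuple(lever), tuple(magazine), bt)
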