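"""Simulated flupentixol: RPE attenuation and softmax-temperature elevation.

A dopamine antagonist is modelled by two dose-proportional effects:

* every reward-prediction error consumed by a model-free-type learner is
  shrunk toward zero by ``eta_rpe`` without ever changing sign (learning
  effect — blocked phasic dopamine);
* under *systemic* administration the softmax temperature is multiplied by
  ``1 + eta_temp``, flattening choice toward uniform (expression effect —
  lowered tonic dopamine favouring exploration).

Local (intra-accumbens) administration activates only the RPE effect: the
feature-value learner is taken to live in the accumbens core while action
selection does not.  Model-based learning is never touched by either effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

__all__ = ["Site", "DrugCondition", "attenuate_rpe", "elevate_temperature"]


class Site(str, Enum):
    NONE = "none"
    SYSTEMIC = "systemic"
    LOCAL_NACC = "local_NAcc"


@dataclass(frozen=True)
class DrugCondition:
    """One administration condition.

    ``k_rpe`` and ``k_temp`` map the (arbitrary-unit) dose to the two effect
    magnitudes; they are calibration constants of the protocol, not fitted
    quantities.
    """

    dose: float = 0.0
    site: Site = Site.NONE
    k_rpe: float = 1.0
    k_temp: float = 10.0

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be non-negative")

    @property
    def eta_rpe(self) -> float:
        return 0.0 if self.site is Site.NONE else self.k_rpe * self.dose

    @property
    def eta_temp(self) -> float:
        return self.k_temp * self.dose if self.site is Site.SYSTEMIC else 0.0


NO_DRUG = DrugCondition()


def attenuate_rpe(delta: float, c: DrugCondition) -> float:
    """Shrink an RPE toward zero: delta' = sign(delta) * max(0, |delta| - eta).

    The additive clamp can at most *block* learning, never reverse it: a
    positive error stays non-negative under any dose (a multiplicative
    shrink, by contrast, only slows learning down and cannot block it).
    Negative errors are clamped symmetrically.
    """
    eta = c.eta_rpe
    if eta <= 0.0:
        return delta
    if delta >= 0.0:
        return max(0.0, delta - eta)
    return min(0.0, delta + eta)


def elevate_temperature(beta: float, c: DrugCondition) -> float:
    """beta' = beta * (1 + eta_temp) under systemic administration, else beta."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    return beta * (1.0 + c.eta_temp)
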