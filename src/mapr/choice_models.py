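"""Choice and response probability kernels for the model family.

The package covers one family of pairwise-judgment models that differ only
in how the comparison is parameterized:

* Thurstone's Law of Comparative Judgment (complete form and Case V):
  probit kernels, P = Phi((v_s - v_t) / comparative dispersion).
* Conditional logit (McFadden): softmax over the values of a choice set;
  for two alternatives it collapses to the logistic of the value
  difference.
* Rasch: the same two-alternative logistic, with one alternative's value
  replaced by the respondent's own location theta, so
  P(presented state judged better than own) = logistic(v_s - theta_r).
* MAPR: the Rasch kernel with the state value linearly restricted to the
  attribute decrements, v_s = z_s . gamma.

All kernels are numerically stable (log-sum-exp / expit forms), accept
scalars or arrays, and return probabilities strictly inside (0, 1) for
finite inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, log_softmax
from scipy.special import ndtr  # standard normal CDF, vectorized

from .state_space import StateProfile, ValueFunction, state_value

__all__ = [
    "DegenerateDispersionError",
    "ThurstoneSpec",
    "ModelParams",
    "UtilityDraw",
    "thurstone_lcj_prob",
    "thurstone_case5_prob",
    "clogit_prob",
    "rasch_prob",
    "mapr_prob",
]


class DegenerateDispersionError(ValueError):
    """The comparative dispersion of a Thurstone comparison is zero."""


@dataclass(frozen=True)
class ThurstoneSpec:
    """Discriminal dispersions and correlation of a Thurstone comparison."""

    sigma_s: float = 1.0
    sigma_t: float = 1.0
    rho: float = 0.0

    def __post_init__(self):
        if not (self.sigma_s > 0 and self.sigma_t > 0):
            raise ValueError("discriminal dispersions must be positive")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")

    @property
    def comparative_dispersion(self) -> float:
        """sqrt(sigma_s^2 + sigma_t^2 - 2 rho sigma_s sigma_t) >= 0."""
        var = (
            self.sigma_s**2
            + self.sigma_t**2
            - 2.0 * self.rho * self.sigma_s * self.sigma_t
        )
        return math.sqrt(max(var, 0.0))


@dataclass
class ModelParams:
    """State values, person locations, and the identification rule in force."""

    v: np.ndarray
    theta: np.ndarray | None = None
    constraint: str = "ref"

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float)
        if self.theta is not None:
            self.theta = np.asarray(self.theta, dtype=float)
        if self.constraint not in ("ref", "sumzero"):
            raise ValueError("constraint must be 'ref' or 'sumzero'")


@dataclass(frozen=True)
class UtilityDraw:
    """One random-utility realization U = v + epsilon."""

    systematic: float
    error: float

    @property
    def total(self) -> float:
        return self.systematic + self.error


def thurstone_lcj_prob(v_s, v_t, spec: ThurstoneSpec):
    """Complete-form LCJ probability that state s is judged better than t.

    P = Phi((v_s - v_t) / sqrt(sigma_s^2 + sigma_t^2 - 2 rho sigma_s sigma_t)).
    """
    disp = spec.comparative_dispersion
    if disp <= 1e-300:
        raise DegenerateDispersionError(
            "comparative dispersion is zero (sigma_s == sigma_t and rho == 1)"
        )
    d = np.asarray(v_s, dtype=float) - np.asarray(v_t, dtype=float)
    out = ndtr(d / disp)
    return float(out) if out.ndim == 0 else out


def thurstone_case5_prob(v_s, v_t, unit_stimulus_dispersions: bool = False):
    """Case V LCJ probability.

    By default the comparative dispersion is normalized to 1, i.e.
    P = Phi(v_s - v_t); the scale unit is arbitrary under Case V.  With
    ``unit_stimulus_dispersions=True`` each stimulus has unit dispersion
    instead, giving P = Phi((v_s - v_t) / sqrt(2)).
    """
    d = np.asarray(v_s, dtype=float) - np.asarray(v_t, dtype=float)
    if unit_stimulus_dispersions:
        d = d / math.sqrt(2.0)
    out = ndtr(d)
    return float(out) if out.ndim == 0 else out


def clogit_prob(values) -> np.ndarray:
    """Conditional-logit (softmax) choice probabilities over a choice set.

    For K = 2 the first component is computed directly as
    logistic(v_0 - v_1) -- the two-alternative form the Rasch kernel shares
    -- and the second as its complement, so pairwise complementarity and the
    logistic-difference identity hold exactly.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("a choice set needs K >= 2 alternatives")
    if not np.all(np.isfinite(v)):
        raise ValueError("choice-set values must be finite")
    if v.size == 2:
        p = expit(v[0] - v[1])
        return np.array([p, 1.0 - p])
    return np.exp(log_softmax(v))


def rasch_prob(theta, v):
    """P(presented state judged better than own) = logistic(v - theta).

    Strictly increasing in the state value ``v`` and strictly decreasing in
    the person location ``theta``; theta = v is the indifference point.
    """
    out = expit(np.asarray(v, dtype=float) - np.asarray(theta, dtype=float))
    return float(out) if np.ndim(out) == 0 else out


def mapr_prob(own_theta, profile: StateProfile, vf: ValueFunction):
    """MAPR response probability: the Rasch kernel with v_s = z_s . gamma.

    ``own_theta`` may be a scalar person location ("free" mode) or a
    StateProfile, in which case the location is the value of that own state
    under ``vf`` ("structured" mode, theta_r = z_own . gamma).
    """
    if isinstance(own_theta, StateProfile) or isinstance(own_theta, str):
        own_theta = state_value(own_theta, vf)
    return rasch_prob(own_theta, state_value(profile, vf))
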