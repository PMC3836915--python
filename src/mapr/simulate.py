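"""Synthetic-response engine.

The model this package implements was proposed without an accompanying
empirical dataset, so simulated patients are the data source for every
fit in the test-bench: respondents are scattered over the latent
severity continuum (estimation degrades badly if they cluster at one
location), each is assigned the enumerated state whose value sits nearest
its latent location as the first-stage self-classification, and each then
judges presented states against that own state with Bernoulli draws from
the Rasch/MAPR kernel.

Also here: random-utility choice simulation (Gumbel errors reproduce the
conditional logit, normal errors the Thurstone probit) and deterministic
Guttman data (response 1 iff v_s > theta_r), whose scalogram is perfect by
construction.

Everything is seed-deterministic; MAPR response streams are drawn per
respondent so a record's draw does not depend on the ordering of other
respondents' choice sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .choice_models import clogit_prob
from .designs import ChoiceSet, mapr_binary_design
from .state_space import (
    AttributeSystem,
    StateProfile,
    ValueFunction,
    enumerate_states,
)

__all__ = [
    "Population",
    "sample_population",
    "simulate_mapr_responses",
    "simulate_rum_choices",
    "simulate_guttman_deterministic",
]


@dataclass
class Population:
    """Simulated respondents: ids, latent locations, own-state profiles."""

    ids: np.ndarray
    theta: np.ndarray
    own_profiles: list | None = None

    @property
    def n(self) -> int:
        return self.theta.size

    def own_code(self, rid) -> str:
        i = int(np.flatnonzero(self.ids == rid)[0])
        return self.own_profiles[i].code


def _parse_dist(theta_dist):
    if isinstance(theta_dist, (tuple, list)):
        fam, *args = theta_dist
        if fam == "normal":
            d = {"family": "normal", "loc": args[0], "scale": args[1]}
        elif fam == "uniform":
            d = {"family": "uniform", "low": args[0], "high": args[1]}
        else:
            d = {"family": fam}
    elif isinstance(theta_dist, dict):
        d = dict(theta_dist)
    else:
        raise ValueError(f"cannot interpret distribution spec {theta_dist!r}")
    fam = d.get("family")
    if fam == "normal":
        if not float(d.get("scale", 1.0)) > 0:
            raise ValueError("normal scale must be > 0")
    elif fam == "uniform":
        if not float(d.get("high", 1.0)) > float(d.get("low", 0.0)):
            raise ValueError("uniform needs high > low")
    else:
        raise ValueError(f"unknown distribution family {fam!r}")
    return d


def sample_population(
    n: int,
    theta_dist=("normal", 0.0, 1.0),
    seed: int = 0,
    system: AttributeSystem | None = None,
    vf: ValueFunction | None = None,
) -> Population:
    """Draw a respondent sample spanning the severity continuum.

    ``theta_dist`` is ``("normal", loc, scale)``, ``("uniform", low, high)``
    or the equivalent dict. If a value function is supplied, each
    respondent's own state is the enumerated state whose value is nearest
    its latent theta (ties broken toward the milder state), keeping the
    first-stage self-classification consistent with the latent location.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    d = _parse_dist(theta_dist)
    rng = np.random.default_rng(seed)
    if d["family"] == "normal":
        theta = rng.normal(float(d.get("loc", 0.0)), float(d.get("scale", 1.0)), n)
    else:
        theta = rng.uniform(float(d["low"]), float(d["high"]), n)
    own = None
    if vf is not None:
        system = system or vf.system
        states = enumerate_states(system)
        values = vf.values(states)
        own = []
        for t in theta:
            dist = np.abs(values - t)
            tied = np.flatnonzero(dist == dist.min())
            # milder = higher value among exact ties
            own.append(states[tied[int(np.argmax(values[tied]))]])
    return Population(ids=np.arange(n), theta=theta, own_profiles=own)


def _alternative_utility(alt, role, theta, vf, dead_value, cache):
    if role == "own":
        return theta
    if role == "dead":
        if dead_value is None:
            raise ValueError("design contains a dead state but no dead_value given")
        return float(dead_value)
    code = alt.code
    if code not in cache:
        cache[code] = vf.value(alt)
    return cache[code]


def simulate_mapr_responses(
    pop: Population,
    design,
    vf: ValueFunction,
    seed: int = 0,
    theta_mode: str = "free",
    dead_value: float | None = None,
) -> pd.DataFrame:
    """Bernoulli responses under the MAPR kernel, one draw per choice set.

    ``design`` is either a list of choice sets (each tagged with a
    respondent id present in ``pop``; id ``None`` replicates the set for
    every respondent) or a plain list of states, meaning every respondent
    judges every state against their own state.

    In ``free`` mode the respondent's latent theta drives the response; in
    ``structured`` mode theta is the value of the own state itself
    (theta_r = z_own . gamma, the two-stage classification).

    Output is a long table with two rows per choice set (the own anchor and
    the presented state); ``response`` is the chosen-flag: 1 on the
    presented row means it was judged better than the own state.
    """
    if theta_mode not in ("free", "structured"):
        raise ValueError("theta_mode must be 'free' or 'structured'")
    if pop.n and pop.own_profiles is None:
        raise ValueError("population has no own-state profiles")

    if design and not isinstance(design[0], ChoiceSet):
        sets = []
        for i, rid in enumerate(pop.ids):
            sets.extend(
                mapr_binary_design(pop.own_profiles[i], design, respondent_id=rid)
            )
    else:
        sets = []
        for cs in design:
            if cs.respondent_id is None:
                for i, rid in enumerate(pop.ids):
                    alts = [
                        ((pop.own_profiles[i], "own") if role == "own" else (s, role))
                        for s, role in cs.alternatives
                    ]
                    sets.append(
                        ChoiceSet(
                            alternatives=alts,
                            task_type=cs.task_type,
                            respondent_id=rid,
                            set_id=cs.set_id,
                        )
                    )
            else:
                sets.append(cs)

    id_to_pos = {rid: i for i, rid in enumerate(np.asarray(pop.ids).tolist())}
    # group sets per respondent, preserving order, for per-respondent streams
    per_resp: dict = {}
    for cs in sets:
        if cs.respondent_id not in id_to_pos:
            raise ValueError(
                f"respondent {cs.respondent_id!r} in design but not in population"
            )
        per_resp.setdefault(cs.respondent_id, []).append(cs)

    rows = []
    cache: dict = {}
    for rid, rsets in per_resp.items():
        i = id_to_pos[rid]
        if theta_mode == "free":
            theta = float(pop.theta[i])
        else:
            theta = vf.value(pop.own_profiles[i])
        rng = np.random.default_rng([int(seed), int(id_to_pos[rid])])
        u_draws = rng.random(len(rsets))
        for k, cs in enumerate(rsets):
            set_id = cs.set_id if cs.set_id is not None else k
            utils = np.array(
                [
                    _alternative_utility(s, role, theta, vf, dead_value, cache)
                    for s, role in cs.alternatives
                ]
            )
            probs = clogit_prob(utils)
            chosen = int(np.searchsorted(np.cumsum(probs), u_draws[k]))
            chosen = min(chosen, len(probs) - 1)
            for j, (s, role) in enumerate(cs.alternatives):
                code = s.code if isinstance(s, StateProfile) else "dead"
                rows.append(
                    {
                        "respondent_id": rid,
                        "choice_set_id": set_id,
                        "alternative_id": j,
                        "state_code": code,
                        "role": role,
                        "response": int(j == chosen),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "respondent_id",
            "choice_set_id",
            "alternative_id",
            "state_code",
            "role",
            "response",
        ],
    )


def simulate_rum_choices(
    values,
    error_family: str = "gumbel",
    n_draws: int = 1,
    seed: int = 0,
    scale: float = 1.0,
) -> np.ndarray:
    """Monte-Carlo choice frequencies under U = v + epsilon, argmax chosen.

    Gumbel(0, 1) errors make the frequencies converge to the conditional
    logit; IID standard normal errors make pairwise frequencies converge to
    the Thurstone probit Phi((v_s - v_t)/sqrt(2)). ``scale = 0`` is the
    zero-variance limit: always the maximal-value alternative.
    """
    v = np.asarray(values, dtype=float)
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if error_family not in ("gumbel", "normal"):
        raise ValueError(f"unknown error family {error_family!r}")
    rng = np.random.default_rng(seed)
    counts = np.zeros(v.size, dtype=np.int64)
    chunk = 200_000
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        if scale == 0.0:
            eps = np.zeros((m, v.size))
        elif error_family == "gumbel":
            eps = scale * rng.gumbel(size=(m, v.size))
        else:
            eps = scale * rng.standard_normal(size=(m, v.size))
        counts += np.bincount(np.argmax(v + eps, axis=1), minlength=v.size)
        done += m
    return counts / n_draws


def simulate_guttman_deterministic(
    pop: Population, states, vf: ValueFunction
) -> pd.DataFrame:
    """Deterministic cumulative data: response 1 iff v_s > theta_r.

    The resulting respondent x state matrix is a perfect Guttman
    scalogram; sorting it yields zero misfits by construction.
    """
    states = list(states)
    values = vf.values(states)
    if np.unique(values).size != values.size:
        raise ValueError("states must have distinct values")
    mat = (values[None, :] > pop.theta[:, None]).astype(int)
    return pd.DataFrame(
        mat, index=list(np.asarray(pop.ids)), columns=[s.code for s in states]
    )
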