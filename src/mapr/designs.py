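"""Judgment-task designs.

Four generators:

* full pairwise designs (every unordered pair of a state set once);
* own-state-anchored binary tasks, the MAPR response format: one choice
  set per (respondent, hypothetical state) pair, each containing the
  respondent's own state and one presented state;
* pivot designs, where the presented states deviate only slightly (by a
  bounded number of levels per attribute) from the respondent's own state;
* partial-profile attribute subsets, and adaptive next-item selection by
  maximal binary Fisher information p(1-p).

All generators are deterministic; any randomness sits behind an explicit
seed. Designs serialize to a long-format table (one row per alternative)
and round-trip losslessly.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .choice_models import rasch_prob
from .state_space import AttributeSystem, StateProfile, ValueFunction

__all__ = [
    "ChoiceSet",
    "PivotConfig",
    "full_pairwise_design",
    "mapr_binary_design",
    "pivot_design",
    "partial_profile_select",
    "adaptive_next_state",
    "design_to_frame",
    "frame_to_design",
]

ROLES = ("own", "hypothetical", "dead")
TASK_TYPES = ("paired", "rank", "mapr-binary")


@dataclass
class ChoiceSet:
    """One judgment task: K >= 2 role-tagged alternatives for a respondent.

    A ``mapr-binary`` set holds exactly the respondent's own state and one
    presented (hypothetical or dead) state.
    """

    alternatives: list  # [(StateProfile | "dead", role), ...]
    task_type: str = "mapr-binary"
    respondent_id: object = None
    set_id: object = None

    def __post_init__(self):
        if self.task_type not in TASK_TYPES:
            raise ValueError(f"unknown task type {self.task_type!r}")
        if len(self.alternatives) < 2:
            raise ValueError("a choice set needs K >= 2 alternatives")
        roles = [r for _, r in self.alternatives]
        for r in roles:
            if r not in ROLES:
                raise ValueError(f"unknown role {r!r}")
        if roles.count("own") > 1 or roles.count("dead") > 1:
            raise ValueError("at most one 'own' and one 'dead' per choice set")
        if self.task_type == "mapr-binary":
            if len(self.alternatives) != 2 or roles.count("own") != 1:
                raise ValueError(
                    "a mapr-binary set is the own state versus exactly one "
                    "presented state"
                )


@dataclass(frozen=True)
class PivotConfig:
    """Pivot-design knobs.

    radius:
        Maximum per-attribute level deviation from the own state (>= 0).
    n_alternatives:
        Optional cap on the number of presented states (first n in the
        deterministic generation order).
    include_own:
        Whether choice sets carry the own state (MAPR binary format).
    multi_attribute:
        If True, enumerate every state within the per-attribute radius
        (Chebyshev ball); default is single-attribute deviations only,
        the closest reading of "deviate slightly".
    """

    radius: int = 1
    n_alternatives: int | None = None
    include_own: bool = True
    multi_attribute: bool = False

    def __post_init__(self):
        if self.radius < 0:
            raise ValueError("radius must be >= 0")


def full_pairwise_design(states) -> list:
    """All unordered pairs of distinct states, each once, in input order."""
    codes = [s.code if isinstance(s, StateProfile) else str(s) for s in states]
    if len(codes) != len(set(codes)):
        raise ValueError("duplicate states in pairwise design")
    if len(codes) < 2:
        raise ValueError("need at least 2 distinct states")
    out = []
    for k, (a, b) in enumerate(itertools.combinations(states, 2)):
        out.append(
            ChoiceSet(
                alternatives=[(a, "hypothetical"), (b, "hypothetical")],
                task_type="paired",
                set_id=k,
            )
        )
    return out


def mapr_binary_design(own: StateProfile, presented, respondent_id=None) -> list:
    """One mapr-binary choice set per presented state, anchored on ``own``."""
    out = []
    for k, s in enumerate(presented):
        role = "dead" if (isinstance(s, str) and s == "dead") else "hypothetical"
        out.append(
            ChoiceSet(
                alternatives=[(own, "own"), (s, role)],
                task_type="mapr-binary",
                respondent_id=respondent_id,
                set_id=k,
            )
        )
    return out


def _pivot_neighbors(own: StateProfile, system: AttributeSystem, cfg: PivotConfig):
    own = system.profile(own)
    if cfg.radius == 0:
        warnings.warn("pivot radius 0 generates an empty design", stacklevel=3)
        return []
    neighbors = []
    if cfg.multi_attribute:
        ranges = [
            [
                lvl
                for lvl in range(max(1, l0 - cfg.radius), min(n, l0 + cfg.radius) + 1)
            ]
            for l0, n in zip(own.levels, system.n_levels)
        ]
        for combo in itertools.product(*ranges):
            if combo != own.levels:
                neighbors.append(system.profile("".join(map(str, combo))))
    else:
        for a, (l0, n) in enumerate(zip(own.levels, system.n_levels)):
            for delta in range(-cfg.radius, cfg.radius + 1):
                lvl = l0 + delta
                if delta != 0 and 1 <= lvl <= n:
                    levels = list(own.levels)
                    levels[a] = lvl
                    neighbors.append(system.profile("".join(map(str, levels))))
    if cfg.n_alternatives is not None:
        neighbors = neighbors[: cfg.n_alternatives]
    return neighbors


def pivot_design(
    own: StateProfile,
    system: AttributeSystem,
    cfg: PivotConfig | None = None,
    respondent_id=None,
) -> list:
    """MAPR binary sets pivoted on the own state.

    Every presented state differs from ``own`` in at least one attribute and
    by at most ``cfg.radius`` levels in any attribute; the own state itself
    never appears in the presented pool.
    """
    cfg = cfg or PivotConfig()
    own = system.profile(own)
    neighbors = _pivot_neighbors(own, system, cfg)
    if cfg.include_own:
        return mapr_binary_design(own, neighbors, respondent_id=respondent_id)
    # pairwise tasks among the neighbors (no own anchor)
    return full_pairwise_design(neighbors)


def partial_profile_select(candidate_domains, k: int, seed: int):
    """Choose ``k`` of the candidate attributes, reproducibly under ``seed``.

    The selection keeps the original candidate order (so ``k == len``
    returns the identity). Attributes left out of a partial profile
    contribute no value: their dummies stay zero in the padded design
    vector.
    """
    candidates = list(candidate_domains)
    if k > len(candidates):
        raise ValueError(
            f"cannot select {k} domains from {len(candidates)} candidates"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=k, replace=False)
    return [candidates[i] for i in sorted(idx)]


def adaptive_next_state(theta_hat: float, candidates, vf: ValueFunction):
    """Most informative next presented state at the current location estimate.

    Binary Fisher information of the MAPR kernel is p(1-p), maximal (0.25)
    when the state value equals theta_hat, so the argmax is the candidate
    minimizing |v_s - theta_hat|; ties go to the lowest candidate index.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate states")
    values = vf.values(candidates)
    return candidates[int(np.argmin(np.abs(values - theta_hat)))]


def fisher_information(theta: float, v) -> np.ndarray:
    """p(1-p) of the Rasch/MAPR kernel at location theta and state values v."""
    p = rasch_prob(theta, np.asarray(v, dtype=float))
    return p * (1.0 - p)


# -- serialization ------------------------------------------------------


def design_to_frame(choice_sets) -> pd.DataFrame:
    """Long-format table: one row per alternative of each choice set."""
    rows = []
    for i, cs in enumerate(choice_sets):
        set_id = cs.set_id if cs.set_id is not None else i
        for j, (s, role) in enumerate(cs.alternatives):
            code = "dead" if role == "dead" and not isinstance(s, StateProfile) else (
                s.code if isinstance(s, StateProfile) else str(s)
            )
            rows.append(
                {
                    "respondent_id": cs.respondent_id,
                    "choice_set_id": set_id,
                    "alternative_id": j,
                    "role": role,
                    "state_code": code,
                    "task_type": cs.task_type,
                }
            )
    return pd.DataFrame(rows)


def frame_to_design(frame: pd.DataFrame, system: AttributeSystem) -> list:
    """Rebuild choice sets from a long-format design table."""
    out = []
    for (rid, sid), grp in frame.groupby(
        ["respondent_id", "choice_set_id"], dropna=False, sort=False
    ):
        grp = grp.sort_values("alternative_id")
        alts = []
        for _, row in grp.iterrows():
            if row["role"] == "dead" and row["state_code"] == "dead":
                alts.append(("dead", "dead"))
            else:
                alts.append((system.profile(row["state_code"]), row["role"]))
        rid = None if pd.isna(rid) else rid
        out.append(
            ChoiceSet(
                alternatives=alts,
                task_type=grp["task_type"].iloc[0],
                respondent_id=rid,
                set_id=sid,
            )
        )
    return out
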