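"""Multi-attribute health-state descriptive systems and their encodings.

A descriptive system (EQ-5D-like) consists of named attributes, each with a
small number of ordered levels; level 1 is the best level of each attribute.
A health state is written as a digit string with one digit per attribute,
e.g. ``"21121"`` for a five-attribute system.

States are dummy-coded against the best (level-1) reference of every
attribute, so the all-ones state maps to the all-zero design vector and is
the fixed zero point of any additive value function built on this coding.
This is the identification anchor used throughout the package: the value of
a state is the dot product of its design vector with a coefficient vector
``gamma`` holding one (typically negative) decrement per non-reference
attribute level.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "StateValidationError",
    "AttributeSystem",
    "StateProfile",
    "ValueFunction",
    "encode_profile",
    "state_value",
    "enumerate_states",
    "design_matrix",
    "load_system",
]


class StateValidationError(ValueError):
    """A state code is inconsistent with its descriptive system."""


@dataclass(frozen=True)
class StateProfile:
    """One health state: a level vector plus its compact digit code."""

    code: str
    levels: tuple

    def __post_init__(self):
        object.__setattr__(self, "levels", tuple(int(x) for x in self.levels))

    @classmethod
    def from_code(cls, code: str, system: "AttributeSystem") -> "StateProfile":
        return system.profile(code)


@dataclass(frozen=True)
class AttributeSystem:
    """Attributes x ordered levels, with level 1 the best of each attribute.

    Parameters
    ----------
    attributes:
        Ordered attribute names (unique).
    levels:
        One tuple of level labels per attribute, ordered best to worst.
        Every attribute needs at least 2 and at most 9 levels (single-digit
        state codes).
    """

    attributes: tuple
    levels: tuple

    def __post_init__(self):
        object.__setattr__(self, "attributes", tuple(str(a) for a in self.attributes))
        object.__setattr__(
            self, "levels", tuple(tuple(str(x) for x in lv) for lv in self.levels)
        )
        if not self.attributes:
            raise ValueError("a descriptive system needs at least one attribute")
        if len(self.attributes) != len(self.levels):
            raise ValueError("attributes and levels must have equal length")
        if len(set(self.attributes)) != len(self.attributes):
            raise ValueError("attribute names must be unique")
        for name, lv in zip(self.attributes, self.levels):
            if not 2 <= len(lv) <= 9:
                raise ValueError(
                    f"attribute {name!r} has {len(lv)} levels; need 2-9 "
                    "(codes are single digits, one per attribute)"
                )

    # -- basic geometry -------------------------------------------------

    @property
    def n_attributes(self) -> int:
        return len(self.attributes)

    @property
    def n_levels(self) -> tuple:
        return tuple(len(lv) for lv in self.levels)

    @property
    def n_states(self) -> int:
        return int(np.prod(self.n_levels))

    @property
    def design_length(self) -> int:
        return sum(n - 1 for n in self.n_levels)

    @property
    def design_columns(self) -> tuple:
        """Column names of the dummy coding, e.g. ``mobility:2``."""
        cols = []
        for name, n in zip(self.attributes, self.n_levels):
            cols.extend(f"{name}:{lvl}" for lvl in range(2, n + 1))
        return tuple(cols)

    @property
    def best_code(self) -> str:
        return "1" * self.n_attributes

    @property
    def worst_code(self) -> str:
        return "".join(str(n) for n in self.n_levels)

    # -- profiles -------------------------------------------------------

    def profile(self, code) -> StateProfile:
        """Validate a digit-string code and return its :class:`StateProfile`."""
        if isinstance(code, StateProfile):
            code = code.code
        code = str(code)
        if len(code) != self.n_attributes:
            raise StateValidationError(
                f"code {code!r} has {len(code)} digits; system has "
                f"{self.n_attributes} attributes"
            )
        levels = []
        for name, n, ch in zip(self.attributes, self.n_levels, code):
            if not ch.isdigit() or not 1 <= int(ch) <= n:
                raise StateValidationError(
                    f"attribute {name!r}: level digit {ch!r} outside 1..{n}"
                )
            levels.append(int(ch))
        return StateProfile(code=code, levels=tuple(levels))

    # -- serialization --------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "AttributeSystem":
        attrs = d["attributes"]
        if attrs and isinstance(attrs[0], dict):
            names = [a["name"] for a in attrs]
            levels = [a["levels"] for a in attrs]
        else:
            names = list(attrs)
            levels = list(d["levels"])
        return cls(attributes=tuple(names), levels=tuple(map(tuple, levels)))

    def to_dict(self) -> dict:
        return {
            "attributes": [
                {"name": a, "levels": list(lv)}
                for a, lv in zip(self.attributes, self.levels)
            ]
        }

    @classmethod
    def from_yaml(cls, path) -> "AttributeSystem":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def load_system(name_or_path) -> AttributeSystem:
    """Load an attribute system from a YAML path or a packaged name.

    ``load_system("eq5d3l")`` returns the packaged EQ-5D-like 5x3 system.
    """
    p = Path(str(name_or_path))
    if p.exists():
        return AttributeSystem.from_yaml(p)
    from importlib import resources

    ref = resources.files("mapr").joinpath(f"data/{name_or_path}.yaml")
    if not ref.is_file():
        raise FileNotFoundError(
            f"no such file or packaged system: {name_or_path!r}"
        )
    return AttributeSystem.from_dict(yaml.safe_load(ref.read_text()))


# -- encoding and values ------------------------------------------------


def encode_profile(profile, system: AttributeSystem) -> np.ndarray:
    """Dummy-code a profile: one 0/1 entry per non-reference attribute level.

    Reference (best) levels contribute no entries; the vector has length
    ``system.design_length`` and is all-zero exactly for the best state.
    """
    prof = system.profile(profile)
    z = np.zeros(system.design_length)
    offset = 0
    for lvl, n in zip(prof.levels, system.n_levels):
        if lvl > 1:
            z[offset + lvl - 2] = 1.0
        offset += n - 1
    return z


def design_matrix(profiles, system: AttributeSystem) -> np.ndarray:
    """Stack design vectors of several profiles into a 2-D array."""
    if len(profiles) == 0:
        return np.zeros((0, system.design_length))
    return np.vstack([encode_profile(p, system) for p in profiles])


@dataclass(frozen=True)
class ValueFunction:
    """Additive main-effects value function v(s) = z_s . gamma.

    ``gamma`` is aligned with ``system.design_columns``; coefficients for
    worse levels are conventionally negative (not enforced).
    """

    system: AttributeSystem
    gamma: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.gamma, dtype=float)
        if g.ndim != 1 or g.size != self.system.design_length:
            raise ValueError(
                f"gamma has length {g.size}; design length is "
                f"{self.system.design_length}"
            )
        object.__setattr__(self, "gamma", g)

    @classmethod
    def from_mapping(cls, system: AttributeSystem, coeffs: dict) -> "ValueFunction":
        """Build gamma from a ``{"attr:level": coefficient}`` mapping."""
        cols = system.design_columns
        unknown = set(coeffs) - set(cols)
        if unknown:
            raise ValueError(f"unknown design columns: {sorted(unknown)}")
        g = np.array([float(coeffs.get(c, 0.0)) for c in cols])
        return cls(system=system, gamma=g)

    def value(self, profile) -> float:
        return float(encode_profile(profile, self.system) @ self.gamma)

    def values(self, profiles) -> np.ndarray:
        return design_matrix(profiles, self.system) @ self.gamma


def state_value(profile, vf: ValueFunction) -> float:
    """Value of one state under an additive value function."""
    return vf.value(profile)


def enumerate_states(system: AttributeSystem):
    """All states of a system, in lexicographic code order, no duplicates."""
    out = []
    for combo in itertools.product(*(range(1, n + 1) for n in system.n_levels)):
        code = "".join(str(c) for c in combo)
        out.append(StateProfile(code=code, levels=combo))
    return out
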