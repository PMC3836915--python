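"""Scalogram diagnostics, dead-state anchoring, and invariance reports.

The response matrix of an error-free cumulative scale, sorted with
respondents by agreement count (descending) and states by agreement count
(descending), shows a perfect step structure: each row is a block of 1s
followed by 0s. Misfits are the cells that deviate from the step vector
implied by the row's total after that sorting (Goodman-style error
counting); probabilistic Rasch data shows a small number of them,
deterministic Guttman data none.

Latent state values are only identified up to location and scale; for
QALY/DALY use they are anchored by estimating "dead" as a pseudo-state in
the choice sets and mapping dead -> 0 and the best state -> 1 with an
affine transform. States worse than dead land below zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import FitResult

__all__ = [
    "SortedScalogram",
    "guttman_sort",
    "anchor_to_dead",
    "InvarianceReport",
    "invariance_check",
]


@dataclass
class SortedScalogram:
    """A Guttman-sorted binary matrix with its misfit cells."""

    matrix: pd.DataFrame
    row_order: list
    col_order: list
    misfits: int
    misfit_cells: list = field(default_factory=list)

    def report(self) -> str:
        lines = [
            f"respondents: {len(self.row_order)}",
            f"states: {len(self.col_order)}",
            f"misfits: {self.misfits}",
        ]
        for r, c in self.misfit_cells:
            lines.append(f"  misfit at respondent {r!r}, state {c!r}")
        return "\n".join(lines)


def guttman_sort(matrix) -> SortedScalogram:
    """Sort a binary respondent x state matrix into scalogram form.

    Rows are ordered by agreement count descending (respondents agreeing
    with every state on top), columns by agreement count descending (most
    agreed-to states on the left); ties break lexicographically by label,
    so the output is deterministic and sorting is idempotent. Misfit cells
    are those differing from the 1...10...0 step vector implied by each
    row's total under the sorted column order; the count is zero exactly
    for a perfect scalogram.
    """
    df = pd.DataFrame(matrix)
    arr = df.to_numpy()
    if arr.size and not np.all(np.isin(arr, (0, 1))):
        raise ValueError("scalogram input must be a binary (0/1) matrix")
    row_tot = df.sum(axis=1)
    col_tot = df.sum(axis=0)
    row_order = sorted(df.index, key=lambda r: (-row_tot[r], str(r)))
    col_order = sorted(df.columns, key=lambda c: (-col_tot[c], str(c)))
    sorted_df = df.loc[row_order, col_order]
    ncol = len(col_order)
    cells = []
    for r in row_order:
        k = int(sorted_df.loc[r].sum())
        ideal = np.zeros(ncol, dtype=int)
        ideal[:k] = 1
        for pos in np.flatnonzero(sorted_df.loc[r].to_numpy() != ideal):
            cells.append((r, col_order[pos]))
    return SortedScalogram(
        matrix=sorted_df,
        row_order=row_order,
        col_order=col_order,
        misfits=len(cells),
        misfit_cells=cells,
    )


def anchor_to_dead(values, dead_value: float, best_value: float):
    """Affine rescaling v' = (v - dead) / (best - dead).

    Dead maps to exactly 0 and the best state to exactly 1; the transform
    preserves order when best > dead and flips it (with a warning --
    a pathological estimate) when dead exceeds best. States worse than
    dead come out negative.
    """
    if dead_value == best_value:
        raise ValueError("dead and best anchors coincide; rescaling undefined")
    if dead_value > best_value:
        warnings.warn(
            "dead anchor exceeds the best-state anchor; the rescaled values "
            "reverse order (pathological estimate)",
            stacklevel=2,
        )
    if isinstance(values, pd.Series):
        return (values - dead_value) / (best_value - dead_value)
    return (np.asarray(values, dtype=float) - dead_value) / (
        best_value - dead_value
    )


@dataclass
class InvarianceReport:
    """Agreement of two recentered state-value fits."""

    mean_abs_diff: float
    max_abs_diff: float
    diff: pd.Series
    z: pd.Series

    def frac_within(self, k: float = 3.0) -> float:
        return float(np.mean(np.abs(self.z) <= k))

    def report(self) -> str:
        return (
            f"states compared: {self.z.size}\n"
            f"mean |diff| after recentering: {self.mean_abs_diff:.4f}\n"
            f"max  |diff| after recentering: {self.max_abs_diff:.4f}\n"
            f"fraction with |z| <= 3: {self.frac_within(3.0):.3f}"
        )


def invariance_check(fit_a: FitResult, fit_b: FitResult) -> InvarianceReport:
    """Compare state values from two fits after recentering.

    Both estimate vectors are recentered to mean zero over the common
    states (values are identified only up to location), then the per-state
    differences are scored against the combined standard errors,
    z = (va - vb) / sqrt(se_a^2 + se_b^2). Under invariance the two fits
    estimate the same quantities, so essentially all |z| stay below 3.
    """
    va, vb = fit_a.estimates["v"], fit_b.estimates["v"]
    common = [s for s in va.index if s in set(vb.index)]
    if not common:
        raise ValueError("fits share no states")
    a = va[common] - va[common].mean()
    b = vb[common] - vb[common].mean()
    diff = a - b
    denom = np.sqrt(fit_a.se["v"][common] ** 2 + fit_b.se["v"][common] ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = diff / denom
    z = z.where(denom > 0, other=np.where(np.abs(diff) < 1e-12, 0.0, np.inf))
    return InvarianceReport(
        mean_abs_diff=float(diff.abs().mean()),
        max_abs_diff=float(diff.abs().max()),
        diff=diff,
        z=z,
    )
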