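"""Response-table file format and fit serialization.

Responses travel as long-format CSV (UTF-8, comma, mandatory header), one
row per (respondent, choice set, alternative):

    respondent_id, choice_set_id, alternative_id, state_code, role, response

``role`` is one of ``own``, ``hypothetical``, ``dead``; ``response`` is the
binary chosen-flag. Validation errors name the offending rows (1-based file
line numbers, header = line 1). Fit results serialize to JSON.
"""

from __future__ import annotations

import json

import pandas as pd

from .estimation import FitResult

__all__ = ["read_responses", "write_responses", "validate_responses", "fit_to_json"]

REQUIRED_COLUMNS = [
    "respondent_id",
    "choice_set_id",
    "alternative_id",
    "state_code",
    "role",
    "response",
]
ROLES = {"own", "hypothetical", "dead"}
KEY = ["respondent_id", "choice_set_id", "alternative_id"]


def validate_responses(df: pd.DataFrame) -> pd.DataFrame:
    """Check the response-table contract; returns the validated frame."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"response table missing columns: {missing}")

    def lines(idx):
        return [int(i) + 2 for i in idx]  # header is file line 1

    dup = df.duplicated(subset=KEY, keep=False)
    if dup.any():
        raise ValueError(
            f"duplicate (respondent, choice set, alternative) keys at rows "
            f"{lines(df.index[dup])}"
        )
    bad_role = ~df["role"].isin(ROLES)
    if bad_role.any():
        raise ValueError(
            f"unknown roles {sorted(set(df.loc[bad_role, 'role']))} at rows "
            f"{lines(df.index[bad_role])}"
        )
    resp = pd.to_numeric(df["response"], errors="coerce")
    bad_resp = ~resp.isin([0, 1])
    if bad_resp.any():
        raise ValueError(
            f"non-binary responses at rows {lines(df.index[bad_resp])}"
        )
    df = df.assign(response=resp.astype(int))
    # a set containing an own row is an own-anchored task: exactly one own
    n_own = df.assign(is_own=df["role"] == "own").groupby(
        ["respondent_id", "choice_set_id"], sort=False
    )["is_own"].sum()
    bad = n_own[n_own > 1]
    if len(bad):
        raise ValueError(
            f"choice sets with more than one own-role row: {list(bad.index)}"
        )
    return df


def read_responses(path) -> pd.DataFrame:
    """Read and validate a long-format response CSV."""
    df = pd.read_csv(path, dtype={"state_code": str, "role": str})
    return validate_responses(df)


def write_responses(table: pd.DataFrame, path) -> None:
    """Validate and write a response table; write-then-read is lossless."""
    validate_responses(pd.DataFrame(table)).to_csv(path, index=False)


def fit_to_json(fit: FitResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(fit.to_dict(), fh, indent=2)
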