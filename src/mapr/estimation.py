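"""Maximum-likelihood estimation for the model family.

Four fitters, all with analytic gradients and Newton-type optimizers:

``fit_clogit_pairs``
    Pairwise conditional logit (Bradley-Terry form) for state values from
    paired-comparison data.
``fit_rasch_cml``
    Conditional ML for Rasch state values: the conditional likelihood
    given each person's raw score is free of theta, computed through
    elementary symmetric functions (log-domain sum recursion). This is the
    estimation route behind the invariance property -- state estimates do
    not depend on the respondent sample's theta distribution.
``fit_rasch_jml``
    Joint (unconditional) ML over state values and person locations.
    JML carries the usual incidental-parameter bias for short response
    strings; it is provided because the MAPR joint fit is of this type and
    the two must agree when the design matrix is saturated.
``fit_mapr``
    The MAPR fit: state values linearly restricted to attribute
    decrements, v = Z gamma. ``theta_mode="free"`` estimates one location
    per respondent jointly with gamma; ``theta_mode="structured"`` sets
    theta_r = z_own . gamma from the first-stage self-classification,
    which reduces the problem to a logistic regression on design-vector
    differences. A presented "dead" pseudo-state gets its own free value
    parameter, estimated alongside gamma.

Identification: values enter only as differences, so either a reference
state is fixed at 0 (``ref``; for MAPR the best state is the zero of the
scale by the dummy coding itself) or the values sum to zero (``sumzero``).
Separation and non-estimable parameters are surfaced, never patched with
epsilon corrections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .state_space import AttributeSystem, design_matrix, encode_profile

__all__ = [
    "EstimationError",
    "FitResult",
    "fit_clogit_pairs",
    "fit_rasch_cml",
    "fit_rasch_jml",
    "fit_mapr",
    "loglik_and_gradient",
    "log_esf",
]

GRAD_TOL = 1e-8
MAX_ITER = 500


class EstimationError(RuntimeError):
    """Estimation cannot proceed (separation, rank deficiency, no data)."""


@dataclass
class FitResult:
    """Estimates, observed-information standard errors, and diagnostics."""

    model: str
    estimates: dict
    se: dict
    loglik: float
    converged: bool
    n_iter: int
    constraint: str
    excluded: list = field(default_factory=list)

    def to_dict(self) -> dict:
        def ser(x):
            if isinstance(x, pd.Series):
                return {str(k): (None if not np.isfinite(v) else float(v))
                        if isinstance(v, (int, float, np.floating)) else v
                        for k, v in x.items()}
            return x

        return {
            "model": self.model,
            "estimates": {k: ser(v) for k, v in self.estimates.items()},
            "se": {k: ser(v) for k, v in self.se.items()},
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "constraint": self.constraint,
            "excluded": [list(map(str, e)) for e in self.excluded],
        }


# ----------------------------------------------------------------------
# small numerical helpers


def _constraint_basis(J: int, constraint: str, ref_index: int = 0) -> np.ndarray:
    """Basis A with v = A u realizing the identification rule."""
    if constraint == "ref":
        return np.delete(np.eye(J), ref_index, axis=1)
    if constraint == "sumzero":
        return np.vstack([np.eye(J - 1), -np.ones((1, J - 1))])
    raise ValueError(f"unknown constraint {constraint!r}")


def _fd_hessian(grad_fn, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian from an analytic gradient."""
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        e = np.zeros(n)
        e[i] = h
        H[i] = (grad_fn(x + e) - grad_fn(x - e)) / (2.0 * h)
    return 0.5 * (H + H.T)


def _run_newton(nll_grad, x0, tol, max_iter, hess=None):
    """Damped Newton iteration on a convex NLL, tracking the gradient norm.

    Near the optimum the NLL itself changes by less than machine resolution
    while the gradient is still ~1e-6, so line searches on the function
    value stall; damping on the gradient norm instead drives max|grad|
    below ``tol`` (quadratic convergence for these concave likelihoods).
    """
    x = np.asarray(x0, dtype=float)
    g = nll_grad(x)[1]
    n_iter = 0
    while np.max(np.abs(g)) > tol and n_iter < max_iter:
        H = hess(x)
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, -g, rcond=None)[0]
        t, gn = 1.0, np.linalg.norm(g)
        while True:
            g_new = nll_grad(x + t * step)[1]
            if np.linalg.norm(g_new) <= (1.0 - 1e-4 * t) * gn or t < 1e-10:
                break
            t *= 0.5
        if t < 1e-10:
            break
        x = x + t * step
        g = g_new
        n_iter += 1
    return x, bool(np.max(np.abs(g)) <= tol), n_iter


def _block_newton(nll_grad, blocks_fn, x0, p, tol, max_iter):
    """Newton iteration for [beta, theta] likelihoods with diagonal
    theta-block Hessian, solved through the Schur complement.

    ``blocks_fn(x)`` returns ``(Hbb, B, D)`` of the NLL Hessian: the dense
    beta block (p x p), the cross block (p x R), and the diagonal of the
    theta block (R,).
    """
    x = np.asarray(x0, dtype=float)
    g = nll_grad(x)[1]
    n_iter = 0
    while np.max(np.abs(g)) > tol and n_iter < max_iter:
        Hbb, B, D = blocks_fn(x)
        gb, gt = g[:p], g[p:]
        Bd = B / D
        S = Hbb - Bd @ B.T
        try:
            db = np.linalg.solve(S, -(gb - Bd @ gt))
        except np.linalg.LinAlgError:
            db = np.linalg.lstsq(S, -(gb - Bd @ gt), rcond=None)[0]
        dt = (-gt - B.T @ db) / D
        step = np.concatenate([db, dt])
        t, gn = 1.0, np.linalg.norm(g)
        while True:
            g_new = nll_grad(x + t * step)[1]
            if np.linalg.norm(g_new) <= (1.0 - 1e-4 * t) * gn or t < 1e-10:
                break
            t *= 0.5
        if t < 1e-10:
            break
        x = x + t * step
        g = g_new
        n_iter += 1
    return x, bool(np.max(np.abs(g)) <= tol), n_iter


# ----------------------------------------------------------------------
# elementary symmetric functions (log domain)


def log_esf(log_eps: np.ndarray) -> np.ndarray:
    """log of the elementary symmetric functions of exp(log_eps).

    Returns ``lg`` of length J+1 with ``lg[r] = log gamma_r``, computed by
    the standard sum recursion run in the log domain for stability.
    """
    log_eps = np.asarray(log_eps, dtype=float)
    J = log_eps.size
    lg = np.full(J + 1, -np.inf)
    lg[0] = 0.0
    for j in range(J):
        lg[1 : j + 2] = np.logaddexp(lg[1 : j + 2], lg[: j + 1] + log_eps[j])
    return lg


# ----------------------------------------------------------------------
# Rasch CML


def _as_matrix(matrix):
    if isinstance(matrix, pd.DataFrame):
        labels = [str(c) for c in matrix.columns]
        persons = list(matrix.index)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        if X.ndim != 2:
            raise ValueError("response matrix must be 2-D (persons x states)")
        labels = [str(j) for j in range(X.shape[1])]
        persons = list(range(X.shape[0]))
    if X.size == 0:
        raise EstimationError("empty response matrix")
    vals = X[~np.isnan(X)]
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValueError("responses must be binary (0/1, NaN for missing)")
    return X, persons, labels


def _cml_structure(X, persons, labels):
    """Drop uninformative persons and non-estimable items, iterating to a
    fixed point, then group persons by missingness pattern."""
    keep_items = np.ones(X.shape[1], dtype=bool)
    excluded = []
    while True:
        ans = ~np.isnan(X[:, keep_items])
        scores = np.nansum(X[:, keep_items], axis=1)
        informative = (scores > 0) & (scores < ans.sum(axis=1))
        changed = False
        for j in np.flatnonzero(keep_items):
            col = X[informative, j]
            col = col[~np.isnan(col)]
            if col.size == 0 or np.all(col == col[0]):
                keep_items[j] = False
                excluded.append(("state", labels[j]))
                changed = True
        if not changed:
            break
    for i in np.flatnonzero(~informative):
        excluded.append(("respondent", persons[i]))
    Xi = X[informative][:, keep_items]
    item_idx = np.flatnonzero(keep_items)
    if Xi.shape[0] == 0 or Xi.shape[1] < 2:
        raise EstimationError(
            "no informative responses left after removing extreme persons "
            "and non-estimable states"
        )
    groups = []
    masks = ~np.isnan(Xi)
    uniq, inv = np.unique(masks, axis=0, return_inverse=True)
    for g in range(uniq.shape[0]):
        rows = np.flatnonzero(inv == g)
        items = np.flatnonzero(uniq[g])
        sub = Xi[np.ix_(rows, items)]
        scores = sub.sum(axis=1).astype(int)
        s_j = sub.sum(axis=0)
        r_vals, n_r = np.unique(scores, return_counts=True)
        groups.append((items, s_j, r_vals, n_r))
    return groups, item_idx, excluded


def _cml_nll_grad(v_kept: np.ndarray, groups):
    """Negative conditional log-likelihood and gradient in kept-item space."""
    nll = 0.0
    g = np.zeros_like(v_kept)
    for items, s_j, r_vals, n_r in groups:
        lv = v_kept[items]
        lg = log_esf(lv)
        nll += -float(s_j @ lv) + float(n_r @ lg[r_vals])
        g[items] -= s_j
        for jj in range(items.size):
            lg_loo = log_esf(np.delete(lv, jj))
            # P(x_j = 1 | score r) = eps_j * gamma_{r-1}^{(j)} / gamma_r
            pj = np.exp(lv[jj] + lg_loo[r_vals - 1] - lg[r_vals])
            g[items[jj]] += float(n_r @ pj)
    return nll, g


def fit_rasch_cml(
    matrix,
    constraint: str = "ref",
    ref_state=None,
    tol: float = GRAD_TOL,
    max_iter: int = MAX_ITER,
) -> FitResult:
    """Conditional ML for Rasch state values; theta is never estimated.

    ``matrix`` is a binary persons x states table (DataFrame or array,
    NaN = missing). Persons with all-0 or all-1 response strings carry no
    conditional information and are dropped (their removal leaves the
    estimates unchanged); states answered identically by every informative
    person are non-estimable and reported in ``excluded``.
    """
    X, persons, labels = _as_matrix(matrix)
    groups, item_idx, excluded = _cml_structure(X, persons, labels)
    kept_labels = [labels[j] for j in item_idx]
    J = len(kept_labels)
    ref_index = 0 if ref_state is None else kept_labels.index(str(ref_state))
    A = _constraint_basis(J, constraint, ref_index)

    def nll_grad_u(u):
        nll, g = _cml_nll_grad(A @ u, groups)
        return nll, A.T @ g

    hess = lambda u: _fd_hessian(lambda x: nll_grad_u(x)[1], u)
    u_hat, converged, n_iter = _run_newton(
        nll_grad_u, np.zeros(J - 1), tol, max_iter, hess=hess
    )
    v_hat = A @ u_hat
    H = hess(u_hat)
    cov_u = np.linalg.pinv(H)
    cov_v = A @ cov_u @ A.T
    se_v = np.sqrt(np.clip(np.diag(cov_v), 0.0, None))
    nll, _ = _cml_nll_grad(v_hat, groups)
    return FitResult(
        model="rasch_cml",
        estimates={"v": pd.Series(v_hat, index=kept_labels)},
        se={"v": pd.Series(se_v, index=kept_labels)},
        loglik=-nll,
        converged=converged,
        n_iter=n_iter,
        constraint=constraint,
        excluded=excluded,
    )


# ----------------------------------------------------------------------
# Rasch JML


def _jml_structure(X, persons, labels):
    keep_items = np.ones(X.shape[1], dtype=bool)
    keep_persons = np.ones(X.shape[0], dtype=bool)
    excluded = []
    while True:
        changed = False
        sub = X[np.ix_(keep_persons, keep_items)]
        scores = np.nansum(sub, axis=1)
        n_ans = (~np.isnan(sub)).sum(axis=1)
        extreme = (scores == 0) | (scores == n_ans)
        if extreme.any():
            for i in np.flatnonzero(keep_persons)[extreme]:
                keep_persons[i] = False
                excluded.append(("respondent", persons[i]))
            changed = True
        sub = X[np.ix_(keep_persons, keep_items)]
        for jj, j in enumerate(np.flatnonzero(keep_items)):
            col = sub[:, jj]
            col = col[~np.isnan(col)]
            if col.size == 0 or np.all(col == col[0]):
                keep_items[j] = False
                excluded.append(("state", labels[j]))
                changed = True
        if not changed:
            break
    return keep_persons, keep_items, excluded


def fit_rasch_jml(
    matrix,
    constraint: str = "ref",
    ref_state=None,
    tol: float = GRAD_TOL,
    max_iter: int = 2000,
) -> FitResult:
    """Joint ML over state values and person locations.

    Extreme persons (all 0 / all 1) and degenerate states are removed
    first; their parameters sit at infinity. The joint log-likelihood is
    concave in (v, theta), so the trust-region Newton iteration converges
    to the unique constrained optimum.
    """
    X, persons, labels = _as_matrix(matrix)
    keep_p, keep_i, excluded = _jml_structure(X, persons, labels)
    Xi = X[np.ix_(keep_p, keep_i)]
    kept_labels = [labels[j] for j in np.flatnonzero(keep_i)]
    kept_persons = [persons[i] for i in np.flatnonzero(keep_p)]
    if Xi.shape[0] == 0 or Xi.shape[1] < 2:
        raise EstimationError("no estimable responses left")
    rows, cols = np.nonzero(~np.isnan(Xi))
    y = Xi[rows, cols]
    J, R = Xi.shape[1], Xi.shape[0]
    ref_index = 0 if ref_state is None else kept_labels.index(str(ref_state))
    A = _constraint_basis(J, constraint, ref_index)

    def unpack(x):
        return A @ x[: J - 1], x[J - 1 :]

    def nll_grad(x):
        v, theta = unpack(x)
        eta = v[cols] - theta[rows]
        nll = -float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        resid = y - expit(eta)
        gv = np.zeros(J)
        np.add.at(gv, cols, -resid)
        gt = np.zeros(R)
        np.add.at(gt, rows, resid)
        return nll, np.concatenate([A.T @ gv, gt])

    def blocks(x):
        v, theta = unpack(x)
        eta = v[cols] - theta[rows]
        w = expit(eta)
        w = w * (1.0 - w)
        Wv = np.zeros(J)
        np.add.at(Wv, cols, w)
        Wt = np.zeros(R)
        np.add.at(Wt, rows, w)
        M = np.zeros((J, R))
        np.add.at(M, (cols, rows), -w)
        return A.T @ (Wv[:, None] * A), A.T @ M, np.maximum(Wt, 1e-12)

    x0 = np.zeros(J - 1 + R)
    x_hat, converged, n_iter = _block_newton(
        nll_grad, blocks, x0, J - 1, tol, max_iter
    )
    v_hat, theta_hat = unpack(x_hat)

    # observed-information SEs for v via the Schur complement over theta
    eta = v_hat[cols] - theta_hat[rows]
    w = expit(eta)
    w = w * (1.0 - w)
    Wv = np.zeros(J)
    np.add.at(Wv, cols, w)
    Wt = np.zeros(R)
    np.add.at(Wt, rows, w)
    M = np.zeros((J, R))
    np.add.at(M, (cols, rows), -w)
    H_uu = A.T @ (Wv[:, None] * A)
    H_ut = A.T @ M
    info_u = H_uu - (H_ut / Wt) @ H_ut.T
    cov_u = np.linalg.pinv(info_u)
    cov_v = A @ cov_u @ A.T
    se_v = np.sqrt(np.clip(np.diag(cov_v), 0.0, None))

    nll, _ = nll_grad(x_hat)
    return FitResult(
        model="rasch_jml",
        estimates={
            "v": pd.Series(v_hat, index=kept_labels),
            "theta": pd.Series(theta_hat, index=kept_persons),
        },
        se={
            "v": pd.Series(se_v, index=kept_labels),
            "theta": pd.Series(np.sqrt(1.0 / Wt), index=kept_persons),
        },
        loglik=-nll,
        converged=converged,
        n_iter=n_iter,
        constraint=constraint,
        excluded=excluded,
    )


# ----------------------------------------------------------------------
# pairwise conditional logit (Bradley-Terry form)


def _pair_counts(data, states):
    """Aggregate a winner/loser judgment table into directed pair counts."""
    df = pd.DataFrame(data)
    if not {"winner", "loser"} <= set(df.columns):
        raise ValueError("pairwise data needs 'winner' and 'loser' columns")
    if "count" not in df.columns:
        df = df.assign(count=1)
    agg = df.groupby(["winner", "loser"], sort=True)["count"].sum().reset_index()
    seen = sorted(set(agg["winner"]).union(agg["loser"]), key=str)
    if states is None:
        states = seen
    else:
        states = [str(s) for s in states]
        if len(states) != len(set(states)):
            raise ValueError("duplicate states")
        missing = set(seen) - set(states)
        if missing:
            raise ValueError(f"data mentions unknown states: {sorted(missing)}")
        lonely = [s for s in states if s not in seen]
        if lonely:
            raise EstimationError(f"states never compared: {lonely}")
    pos = {s: k for k, s in enumerate(states)}
    ii = agg["winner"].map(pos).to_numpy()
    jj = agg["loser"].map(pos).to_numpy()
    w = agg["count"].to_numpy(dtype=float)
    return states, ii, jj, w


def _check_connected(n, ii, jj):
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    adj = coo_matrix((np.ones(ii.size), (ii, jj)), shape=(n, n))
    ncomp, comp = connected_components(adj, directed=False)
    return ncomp, comp


def _pairs_nll_grad(v, ii, jj, w):
    d = v[ii] - v[jj]
    p = expit(d)
    nll = -float(np.sum(w * (d - np.logaddexp(0.0, d))))
    g = np.zeros_like(v)
    np.add.at(g, ii, -w * (1.0 - p))
    np.add.at(g, jj, w * (1.0 - p))
    return nll, g


def _pairs_hess(v, ii, jj, w, J):
    d = v[ii] - v[jj]
    p = expit(d)
    wt = w * p * (1.0 - p)
    H = np.zeros((J, J))
    np.add.at(H, (ii, ii), wt)
    np.add.at(H, (jj, jj), wt)
    np.add.at(H, (ii, jj), -wt)
    np.add.at(H, (jj, ii), -wt)
    return H


def fit_clogit_pairs(
    data,
    states=None,
    constraint: str = "ref",
    ref_state=None,
    tol: float = GRAD_TOL,
    max_iter: int = MAX_ITER,
) -> FitResult:
    """ML state values from paired-comparison data.

    ``data`` is a table with one judgment per row (``winner``, ``loser``
    state codes; optional ``count``). The comparison graph must be
    connected. States that never lose (or never win) are separated: their
    ML value sits at +/- infinity, which is reported as such (NaN standard
    error) while the remaining states are refit without those comparisons.

    For exactly two states the estimated difference has the closed form
    log(wins_st / wins_ts).
    """
    states, ii, jj, w = _pair_counts(data, states)
    J = len(states)
    ncomp, comp = _check_connected(J, ii, jj)
    if ncomp > 1:
        groups = [
            [states[k] for k in np.flatnonzero(comp == c)] for c in range(ncomp)
        ]
        raise EstimationError(f"comparison graph disconnected; components: {groups}")

    # peel off separated states iteratively
    active = np.ones(J, dtype=bool)
    sep_sign = {}
    while True:
        wins = np.zeros(J)
        losses = np.zeros(J)
        mask = active[ii] & active[jj]
        np.add.at(wins, ii[mask], w[mask])
        np.add.at(losses, jj[mask], w[mask])
        newly = []
        for k in np.flatnonzero(active):
            if losses[k] == 0:
                newly.append((k, 1))
            elif wins[k] == 0:
                newly.append((k, -1))
        if not newly:
            break
        for k, sgn in newly:
            active[k] = False
            sep_sign[k] = sgn
    excluded = [("state", states[k]) for k in sorted(sep_sign)]
    if excluded:
        warnings.warn(
            f"separation: states at the likelihood bound: "
            f"{[states[k] for k in sorted(sep_sign)]}",
            stacklevel=2,
        )

    v_full = np.full(J, np.nan)
    se_full = np.full(J, np.nan)
    for k, sgn in sep_sign.items():
        v_full[k] = sgn * np.inf

    act_idx = np.flatnonzero(active)
    loglik, converged, n_iter = 0.0, True, 0
    if act_idx.size >= 2:
        remap = -np.ones(J, dtype=int)
        remap[act_idx] = np.arange(act_idx.size)
        mask = active[ii] & active[jj]
        ai, aj, aw = remap[ii[mask]], remap[jj[mask]], w[mask]
        Ja = act_idx.size
        ncomp_a, _ = _check_connected(Ja, ai, aj)
        if ncomp_a > 1:
            raise EstimationError(
                "comparison graph disconnected after removing separated states"
            )
        kept_labels = [states[k] for k in act_idx]
        ref_index = (
            0 if ref_state is None else kept_labels.index(str(ref_state))
        )
        A = _constraint_basis(Ja, constraint, ref_index)

        def nll_grad_u(u):
            nll, g = _pairs_nll_grad(A @ u, ai, aj, aw)
            return nll, A.T @ g

        hess = lambda u: A.T @ _pairs_hess(A @ u, ai, aj, aw, Ja) @ A
        u_hat, converged, n_iter = _run_newton(
            nll_grad_u, np.zeros(Ja - 1), tol, max_iter, hess=hess
        )
        v_act = A @ u_hat
        cov_u = np.linalg.pinv(hess(u_hat))
        cov_v = A @ cov_u @ A.T
        v_full[act_idx] = v_act
        se_full[act_idx] = np.sqrt(np.clip(np.diag(cov_v), 0.0, None))
        loglik = -_pairs_nll_grad(v_act, ai, aj, aw)[0]
    elif act_idx.size == 1:
        v_full[act_idx[0]] = 0.0
        se_full[act_idx[0]] = 0.0

    return FitResult(
        model="clogit_pairs",
        estimates={"v": pd.Series(v_full, index=states)},
        se={"v": pd.Series(se_full, index=states)},
        loglik=loglik,
        converged=converged,
        n_iter=n_iter,
        constraint=constraint,
        excluded=excluded,
    )


# ----------------------------------------------------------------------
# MAPR joint fit


def _extract_binary_tasks(responses: pd.DataFrame) -> pd.DataFrame:
    """Reduce a long response table to one row per own-vs-presented task."""
    df = pd.DataFrame(responses)
    need = {"respondent_id", "choice_set_id", "state_code", "role", "response"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"response table missing columns: {sorted(missing)}")
    if not len(df):
        raise EstimationError("no responses")
    key = ["respondent_id", "choice_set_id"]
    agg = df.assign(is_own=df["role"] == "own").groupby(key, sort=False).agg(
        n=("role", "size"), n_own=("is_own", "sum")
    )
    bad = agg[(agg["n"] != 2) | (agg["n_own"] != 1)]
    if len(bad):
        raise ValueError(
            "choice sets that are not own-vs-presented binary tasks: "
            f"{list(bad.index[:5])}"
        )
    own = df[df["role"] == "own"]
    other = df[df["role"] != "own"]
    merged = own.merge(other, on=key, suffixes=("_own", ""))
    return pd.DataFrame(
        {
            "respondent_id": merged["respondent_id"],
            "own_code": merged["state_code_own"].astype(str),
            "code": merged["state_code"].astype(str),
            "role": merged["role"],
            "y": merged["response"].astype(int),
        }
    )


def _mapr_design(tasks: pd.DataFrame, system: AttributeSystem):
    cols = list(system.design_columns)
    dead = (tasks["role"] == "dead").to_numpy()
    p = len(cols) + (1 if dead.any() else 0)
    X = np.zeros((len(tasks), p))
    Zown = np.zeros((len(tasks), p))
    enc: dict = {}

    def z(code):
        if code not in enc:
            enc[code] = encode_profile(code, system)
        return enc[code]

    own_codes = tasks["own_code"].to_numpy()
    codes = tasks["code"].to_numpy()
    for i in range(len(tasks)):
        Zown[i, : len(cols)] = z(own_codes[i])
        if dead[i]:
            X[i, -1] = 1.0
        else:
            X[i, : len(cols)] = z(codes[i])
    names = cols + (["dead"] if dead.any() else [])
    return X, Zown, names


def _check_rank(M: np.ndarray, names):
    from scipy.linalg import qr

    if M.shape[0] < M.shape[1] or np.linalg.matrix_rank(M) < M.shape[1]:
        _, R, piv = qr(M, pivoting=True, mode="economic")
        diag = np.abs(np.diag(R)) if R.size else np.zeros(0)
        thresh = (diag[0] if diag.size else 0.0) * max(M.shape) * np.finfo(float).eps
        bad = [names[piv[k]] for k in range(len(names)) if k >= diag.size or diag[k] <= thresh]
        raise EstimationError(
            f"design matrix rank-deficient; collinear or empty columns: {bad}"
        )


def fit_mapr(
    responses,
    system: AttributeSystem,
    theta_mode: str = "free",
    tol: float = GRAD_TOL,
    max_iter: int = MAX_ITER,
) -> FitResult:
    """Joint ML for the MAPR model: gamma (and theta in free mode).

    ``responses`` is a long-format table of own-vs-presented binary tasks
    (see :mod:`mapr.io`). The best state is the fixed zero of the value
    scale through the dummy coding, so no extra constraint is needed on
    gamma. With a saturated design matrix (one dummy per non-reference
    state) the free-theta fit reproduces the joint Rasch fit exactly.
    """
    if theta_mode not in ("free", "structured"):
        raise ValueError("theta_mode must be 'free' or 'structured'")
    tasks = _extract_binary_tasks(responses)
    X, Zown, names = _mapr_design(tasks, system)
    y = tasks["y"].to_numpy(dtype=float)

    if theta_mode == "structured":
        D = X - Zown
        _check_rank(D, names)

        def nll_grad(b):
            eta = D @ b
            nll = -float(np.sum(y * eta - np.logaddexp(0.0, eta)))
            return nll, -D.T @ (y - expit(eta))

        def hess(b):
            w = expit(D @ b)
            w = w * (1.0 - w)
            return D.T @ (w[:, None] * D)

        b_hat, converged, n_iter = _run_newton(
            nll_grad, np.zeros(len(names)), tol, max_iter, hess=hess
        )
        cov = np.linalg.pinv(hess(b_hat))
        se_b = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        loglik = -nll_grad(b_hat)[0]
        theta_hat, theta_se, excluded = None, None, []
        rid_order = list(dict.fromkeys(tasks["respondent_id"]))
        th = {}
        ng = len(system.design_columns)
        for rid in rid_order:
            own = tasks.loc[tasks["respondent_id"] == rid, "own_code"].iloc[0]
            th[rid] = float(encode_profile(own, system) @ b_hat[:ng])
        theta_hat = pd.Series(th)
    else:
        _check_rank(X, names)
        # drop respondents whose responses are all equal: their free theta
        # diverges (complete separation in the person dimension)
        excluded = []
        keep_rows = np.ones(len(tasks), dtype=bool)
        rid_order = []
        for rid, grp in tasks.groupby("respondent_id", sort=False):
            yy = grp["y"].to_numpy()
            if np.all(yy == yy[0]):
                excluded.append(("respondent", rid))
                keep_rows[grp.index.to_numpy()] = False
            else:
                rid_order.append(rid)
        if not rid_order:
            raise EstimationError(
                "every respondent has a perfect (all-0 or all-1) response "
                "string; free theta is non-estimable"
            )
        if excluded:
            warnings.warn(
                f"excluding {len(excluded)} perfect-response respondents "
                "from the free-theta fit",
                stacklevel=2,
            )
        Xk = X[keep_rows]
        yk = y[keep_rows]
        rpos = {rid: k for k, rid in enumerate(rid_order)}
        rindex = tasks.loc[keep_rows, "respondent_id"].map(rpos).to_numpy()
        p, R = Xk.shape[1], len(rid_order)

        def nll_grad(x):
            b, theta = x[:p], x[p:]
            eta = Xk @ b - theta[rindex]
            nll = -float(np.sum(yk * eta - np.logaddexp(0.0, eta)))
            resid = yk - expit(eta)
            gt = np.zeros(R)
            np.add.at(gt, rindex, resid)
            return nll, np.concatenate([-Xk.T @ resid, gt])

        def blocks(x):
            b, theta = x[:p], x[p:]
            w = expit(Xk @ b - theta[rindex])
            w = w * (1.0 - w)
            Hbb = Xk.T @ (w[:, None] * Xk)
            D = np.zeros(R)
            np.add.at(D, rindex, w)
            B = np.zeros((p, R))
            np.add.at(B.T, rindex, -(w[:, None] * Xk))
            return Hbb, B, np.maximum(D, 1e-12)

        x_hat, converged, n_iter = _block_newton(
            nll_grad, blocks, np.zeros(p + R), p, tol, max_iter
        )
        b_hat, th = x_hat[:p], x_hat[p:]
        # Schur-complement observed information for the gamma block
        w = expit(Xk @ b_hat - th[rindex])
        w = w * (1.0 - w)
        Awt = np.zeros(R)
        np.add.at(Awt, rindex, w)
        B = np.zeros((p, R))
        np.add.at(B.T, rindex, -(w[:, None] * Xk))
        info_b = Xk.T @ (w[:, None] * Xk) - (B / Awt) @ B.T
        cov = np.linalg.pinv(info_b)
        se_b = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        Bd = B / Awt
        theta_var = 1.0 / Awt + np.einsum("pr,pq,qr->r", Bd, cov, Bd)
        theta_hat = pd.Series(th, index=rid_order)
        theta_se = pd.Series(np.sqrt(np.clip(theta_var, 0.0, None)), index=rid_order)
        loglik = -nll_grad(x_hat)[0]

    # implied state values for the presented states (delta-method SEs)
    ng = len(system.design_columns)
    uniq_codes = list(dict.fromkeys(tasks["code"]))
    v_vals, v_ses = {}, {}
    for code in uniq_codes:
        if code == "dead":
            v_vals[code] = float(b_hat[-1])
            v_ses[code] = float(se_b[-1])
        else:
            z = np.zeros(len(names))
            z[:ng] = encode_profile(code, system)
            v_vals[code] = float(z @ b_hat)
            v_ses[code] = float(np.sqrt(max(z @ cov @ z, 0.0)))

    estimates = {
        "gamma": pd.Series(b_hat, index=names),
        "v": pd.Series(v_vals),
        "theta": theta_hat,
    }
    se = {
        "gamma": pd.Series(se_b, index=names),
        "v": pd.Series(v_ses),
    }
    if theta_mode == "free":
        se["theta"] = theta_se
    return FitResult(
        model=f"mapr_{theta_mode}",
        estimates=estimates,
        se=se,
        loglik=loglik,
        converged=converged,
        n_iter=n_iter,
        constraint="ref",
        excluded=excluded,
    )


# ----------------------------------------------------------------------
# public log-likelihood / gradient dispatcher


def loglik_and_gradient(params, data, model: str):
    """Log-likelihood and analytic gradient at arbitrary parameter points.

    ``model`` selects the likelihood; ``params`` is the full (unconstrained)
    parameter vector:

    - ``"clogit_pairs"``: data ``{"pairs": winner/loser table, "states": [...]}``,
      params = state values v.
    - ``"rasch_cml"``: data = response matrix; params = v. The conditional
      likelihood given person scores (extreme persons contribute nothing).
    - ``"rasch_jml"``: data = response matrix; params = concat(v, theta)
      over all states and persons of the matrix.
    - ``"mapr_free"``: data = ``(responses, system)``; params =
      concat(gamma [, dead value], theta per respondent in order of first
      appearance).
    - ``"mapr_structured"``: data = ``(responses, system)``; params = gamma
      (plus the dead value if dead tasks occur).

    Returns ``(loglik, gradient_of_loglik)``.
    """
    params = np.asarray(params, dtype=float)
    if model == "clogit_pairs":
        states, ii, jj, w = _pair_counts(data["pairs"], data.get("states"))
        nll, g = _pairs_nll_grad(params, ii, jj, w)
        return -nll, -g
    if model == "rasch_cml":
        X, persons, labels = _as_matrix(data)
        scores = np.nansum(X, axis=1)
        n_ans = (~np.isnan(X)).sum(axis=1)
        informative = (scores > 0) & (scores < n_ans)
        Xi = X[informative]
        masks = ~np.isnan(Xi)
        uniq, inv = np.unique(masks, axis=0, return_inverse=True)
        groups = []
        for g_i in range(uniq.shape[0]):
            rows_g = np.flatnonzero(inv == g_i)
            items = np.flatnonzero(uniq[g_i])
            sub = Xi[np.ix_(rows_g, items)]
            sc = sub.sum(axis=1).astype(int)
            r_vals, n_r = np.unique(sc, return_counts=True)
            groups.append((items, sub.sum(axis=0), r_vals, n_r))
        nll, g = _cml_nll_grad(params, groups)
        return -nll, -g
    if model == "rasch_jml":
        X, persons, labels = _as_matrix(data)
        rows, cols = np.nonzero(~np.isnan(X))
        y = X[rows, cols]
        J = X.shape[1]
        v, theta = params[:J], params[J:]
        eta = v[cols] - theta[rows]
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        resid = y - expit(eta)
        gv = np.zeros(J)
        np.add.at(gv, cols, resid)
        gt = np.zeros(X.shape[0])
        np.add.at(gt, rows, -resid)
        return ll, np.concatenate([gv, gt])
    if model in ("mapr_free", "mapr_structured"):
        responses, system = data
        tasks = _extract_binary_tasks(responses)
        X, Zown, names = _mapr_design(tasks, system)
        y = tasks["y"].to_numpy(dtype=float)
        p = len(names)
        if model == "mapr_structured":
            D = X - Zown
            eta = D @ params
            ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
            return ll, D.T @ (y - expit(eta))
        rid_order = list(dict.fromkeys(tasks["respondent_id"]))
        rpos = {rid: k for k, rid in enumerate(rid_order)}
        rindex = tasks["respondent_id"].map(rpos).to_numpy()
        b, theta = params[:p], params[p:]
        eta = X @ b - theta[rindex]
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        resid = y - expit(eta)
        gt = np.zeros(len(rid_order))
        np.add.at(gt, rindex, -resid)
        return ll, np.concatenate([X.T @ resid, gt])
    raise ValueError(f"unknown model {model!r}")
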