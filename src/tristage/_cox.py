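"""Breslow partial-likelihood machinery for Cox proportional-hazards models.

Shared by the univariate screens, the AIC-stepwise Cox learner, the
componentwise likelihood-boosting learner and the cross-validated deviance
used for L1-path selection.  Everything here works on plain numpy arrays;
samples are sorted by follow-up time internally and tied event times are
handled with the Breslow approximation (every event at a tied time sees the
full risk set at that time).

The vectorised univariate Newton solver exists so that screening thousands
of features stays cheap; its answers are cross-checked against lifelines in
the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "breslow_loglik",
    "univariate_cox",
    "cox_fit",
    "cox_score_info_at_offset",
    "CoxFitError",
]

# Newton iterations are damped and the coefficient clipped: with monotone
# likelihood (perfect separation) beta diverges, and a finite cap keeps the
# Wald statistic well defined without affecting regular fits.
_BETA_CAP = 15.0
_STEP_CAP = 2.0
_MAX_ITER = 40
_TOL = 1e-10


class CoxFitError(RuntimeError):
    """Raised when a Cox fit cannot be carried out (no events, singular
    information, empty design)."""


def _order(time, event):
    """Sort by time ascending; return order, sorted arrays and, per row, the
    first index of its tie group (the start of the Breslow risk set)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    o = np.argsort(time, kind="mergesort")
    t = time[o]
    d = event[o].astype(bool)
    group_first = np.searchsorted(t, t, side="left")
    return o, t, d, group_first


def _revcumsum(a):
    return np.cumsum(a[::-1], axis=0)[::-1]


def breslow_loglik(eta, time, event):
    """Breslow partial log-likelihood of a fixed linear predictor."""
    eta = np.asarray(eta, dtype=float)
    o, _, d, gf = _order(time, event)
    e = eta[o]
    if not d.any():
        raise CoxFitError("no events; partial likelihood undefined")
    m = e.max()
    s0 = _revcumsum(np.exp(e - m))
    return float(np.sum(e[d]) - np.sum(np.log(s0[gf][d]) + m))


def _score_info_1d(xs, w, d, gf):
    """Per-feature score and information for scalar coefficients.

    xs: (n, p) sorted feature matrix; w: (n, p) sorted relative risks.
    Returns (U, I), each (p,).
    """
    s0 = _revcumsum(w)
    s1 = _revcumsum(w * xs)
    s2 = _revcumsum(w * xs * xs)
    mu = s1[gf] / s0[gf]
    u = (xs[d] - mu[d]).sum(axis=0)
    info = (s2[gf][d] / s0[gf][d] - mu[d] ** 2).sum(axis=0)
    return u, info


def univariate_cox(X, time, event):
    """Fit one single-covariate Cox model per column of ``X``, all at once.

    Returns a dict with arrays ``beta``, ``se``, ``z``, ``p`` of length p.
    Constant columns get beta 0 and p exactly 1 (they carry no information
    and must never pass a screen).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")
    n, p = X.shape
    o, _, d, gf = _order(time, event)
    n_events = int(d.sum())
    if n_events == 0:
        raise CoxFitError("no events; cannot screen")
    xs = X[o]
    nonconst = np.ptp(xs, axis=0) > 0
    beta = np.zeros(p)
    info = np.zeros(p)
    for _ in range(_MAX_ITER):
        eta = xs * beta
        m = eta.max(axis=0)
        w = np.exp(eta - m)
        u, info = _score_info_1d(xs, w, d, gf)
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(info > 0, u / np.maximum(info, 1e-300), 0.0)
        step = np.clip(step, -_STEP_CAP, _STEP_CAP) * nonconst
        beta = np.clip(beta + step, -_BETA_CAP, _BETA_CAP)
        if np.max(np.abs(step), initial=0.0) < _TOL:
            break
    ok = nonconst & (info > 0)
    se = np.full(p, np.inf)
    se[ok] = 1.0 / np.sqrt(info[ok])
    z = np.where(ok, beta / se, 0.0)
    pval = np.where(ok, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    return {"beta": beta, "se": se, "z": z, "p": pval}


def cox_score_info_at_offset(X, offset, time, event):
    """Per-feature score and information of the partial likelihood evaluated
    at coefficient zero given a fixed offset (current linear predictor).

    This is the workhorse of componentwise likelihood boosting: the
    penalised update for feature j is U_j / (I_j + lambda).
    """
    X = np.asarray(X, dtype=float)
    offset = np.asarray(offset, dtype=float)
    o, _, d, gf = _order(time, event)
    xs = X[o]
    off = offset[o]
    w = np.exp(off - off.max())[:, None] * np.ones((1, xs.shape[1]))
    return _score_info_1d(xs, w, d, gf)


def cox_fit(X, time, event, max_iter=60, tol=1e-9):
    """Multivariate Cox fit by damped Newton-Raphson (Breslow ties).

    Returns (beta, loglik, cov).  Intended for the small designs of the
    stepwise learner (p of order tens); raises CoxFitError on an empty
    design or a persistently singular information matrix.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if p == 0:
        raise CoxFitError("empty design")
    o, _, d, gf = _order(time, event)
    if not d.any():
        raise CoxFitError("no events")
    xs = X[o]
    beta = np.zeros(p)
    ll = _mv_loglik(xs, beta, d, gf)
    for _ in range(max_iter):
        u, h = _mv_score_info(xs, beta, d, gf)
        try:
            step = np.linalg.solve(h + 1e-9 * np.eye(p), u)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise CoxFitError("singular information matrix") from exc
        norm = np.linalg.norm(step)
        if norm > _STEP_CAP * np.sqrt(p):
            step *= _STEP_CAP * np.sqrt(p) / norm
        # step halving: never accept a decrease of the partial likelihood
        for _half in range(30):
            cand = np.clip(beta + step, -_BETA_CAP, _BETA_CAP)
            ll_new = _mv_loglik(xs, cand, d, gf)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        moved = np.max(np.abs(cand - beta), initial=0.0)
        beta, ll = cand, ll_new
        if moved < tol:
            break
    _, h = _mv_score_info(xs, beta, d, gf)
    cov = np.linalg.pinv(h)
    return beta, ll, cov


def _mv_loglik(xs, beta, d, gf):
    e = xs @ beta
    m = e.max()
    s0 = _revcumsum(np.exp(e - m))
    return float(np.sum(e[d]) - np.sum(np.log(s0[gf][d]) + m))


def _mv_score_info(xs, beta, d, gf):
    n, p = xs.shape
    e = xs @ beta
    w = np.exp(e - e.max())
    s0 = _revcumsum(w)
    s1 = _revcumsum(w[:, None] * xs)
    outer = w[:, None, None] * (xs[:, :, None] * xs[:, None, :])
    s2 = np.cumsum(outer[::-1], axis=0)[::-1]
    mu = s1[gf] / s0[gf][:, None]
    u = (xs[d] - mu[d]).sum(axis=0)
    v = s2[gf][d] / s0[gf][d][:, None, None] - mu[d][:, :, None] * mu[d][:, None, :]
    return u, v.sum(axis=0)
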