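"""Post-matching treatment-effect estimators.

For continuous outcomes: an ordinary-least-squares suite of seven nested
outcome models (treatment only, up to the full model with quadratic and
interaction terms), returning the coefficient on treatment.  For binary
matched pairs: the McNemar discordant-pair odds ratio ``b/c``, the
Mantel-Haenszel common odds ratio over strata, and conditional logistic
regression for 1:1 pairs, fit in-repo by step-halving Newton iterations on
the pair-difference likelihood.  Conditional logistic regression with a
treatment-only term reduces analytically to the McNemar ratio, which serves
as a cross-check in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

from .cohorts import Cohort, _term_column
from .matching import MatchedPairs, StratumAssignment

__all__ = [
    "EstimateRecord",
    "OLS_MODELS",
    "ols_effect",
    "mcnemar_or",
    "mh_or",
    "clogit",
    "pair_differences",
]

#: The seven outcome-model term lists (an intercept is always included).
OLS_MODELS: dict[str, tuple[str, ...]] = {
    "M1": ("T",),
    "M2": ("T", "X1"),
    "M3": ("T", "X2"),
    "M4": ("T", "X1", "X2"),
    "M5": ("T", "X1", "X2", "X1*X2"),
    "M6": ("T", "X1", "X1^2", "X2"),
    "M7": ("T", "X1", "X1^2", "X2", "X1*X2"),
}


@dataclass
class EstimateRecord:
    """One estimator applied to one matched (or unmatched) dataset.

    ``status`` is ``"ok"``, ``"infinite"`` (e.g. McNemar with ``c = 0 <
    b``) or ``"undefined"`` (no information, e.g. no discordant pairs);
    non-ok records are excluded from replication averages and counted.
    """

    method: str
    terms: tuple[str, ...]
    estimate: float
    scale: str                    # "difference" or "odds_ratio"
    converged: bool = True
    status: str = "ok"
    n_used: int = 0
    b: int | None = None          # discordant pairs: treated event, control none
    c: int | None = None          # discordant pairs: control event, treated none

    @property
    def ok(self) -> bool:
        return self.status == "ok" and self.converged


def ols_effect(matched: Cohort, model_id: str) -> EstimateRecord:
    """Least-squares fit of Y on one of the seven models; coefficient on T.

    ``matched`` may be any cohort subset (both arms must be present).
    Raises on a rank-deficient design, naming the collinear terms.
    """
    terms = OLS_MODELS[model_id]
    if matched.n == 0:
        raise ValueError("empty sample")
    if matched.t.min() == matched.t.max():
        raise ValueError("both treatment arms must be present")
    X = np.column_stack(
        [np.ones(matched.n)]
        + [_term_column(tm, matched.x1, matched.x2, matched.t) for tm in terms]
    )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design ({rank} < {X.shape[1]}) among terms "
            f"{('1',) + terms}; drop collinear terms"
        )
    beta, *_ = np.linalg.lstsq(X, matched.y, rcond=None)
    est = float(beta[1 + terms.index("T")])
    return EstimateRecord(
        method=f"ols_{model_id}", terms=terms, estimate=est,
        scale="difference", n_used=matched.n,
    )


def _discordant(pairs: MatchedPairs, y: np.ndarray) -> tuple[np.ndarray, int, int]:
    yt = np.asarray(y)[pairs.treated_idx]
    yc = np.asarray(y)[pairs.control_idx]
    disc = yt != yc
    b = int(((yt == 1) & (yc == 0)).sum())
    c = int(((yt == 0) & (yc == 1)).sum())
    return disc, b, c


def mcnemar_or(pairs: MatchedPairs, y: np.ndarray) -> EstimateRecord:
    """McNemar odds ratio ``b/c`` over outcome-discordant matched pairs.

    No continuity correction: ``c = 0 < b`` yields an infinite-estimate
    flag, ``b = c = 0`` an undefined flag.
    """
    if not np.isin(y, (0, 1)).all():
        raise ValueError("y must be binary")
    _, b, c = _discordant(pairs, y)
    if b == 0 and c == 0:
        est, status = np.nan, "undefined"
    elif c == 0:
        est, status = np.inf, "infinite"
    else:
        est, status = b / c, "ok"
    return EstimateRecord(
        method="mcnemar", terms=("T",), estimate=float(est), scale="odds_ratio",
        status=status, n_used=pairs.n_pairs, b=b, c=c,
    )


def mh_or(sa: StratumAssignment, t: np.ndarray, y: np.ndarray) -> EstimateRecord:
    """Mantel-Haenszel common odds ratio over retained strata.

    ``sum_k a_k d_k / n_k`` over ``sum_k b_k c_k / n_k`` with ``a_k`` the
    treated events, ``b_k`` treated non-events, ``c_k`` control events,
    ``d_k`` control non-events in stratum ``k``.
    """
    t = np.asarray(t)
    y = np.asarray(y)
    num = 0.0
    den = 0.0
    n_used = 0
    for k in np.flatnonzero(sa.retained_strata):
        members = sa.stratum_index == k
        tk, yk = t[members], y[members]
        nk = len(tk)
        a = int(((tk == 1) & (yk == 1)).sum())
        bb = int(((tk == 1) & (yk == 0)).sum())
        cc = int(((tk == 0) & (yk == 1)).sum())
        d = int(((tk == 0) & (yk == 0)).sum())
        num += a * d / nk
        den += bb * cc / nk
        n_used += nk
    if den == 0.0:
        est = np.inf if num > 0 else np.nan
        status = "infinite" if num > 0 else "undefined"
    else:
        est, status = num / den, "ok"
    return EstimateRecord(
        method="mh", terms=("T",), estimate=float(est), scale="odds_ratio",
        status=status, n_used=n_used,
    )


def pair_differences(
    pairs: MatchedPairs, cohort: Cohort, terms: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Within-pair term differences (treated minus control) and case labels.

    Restricted to outcome-discordant pairs; ``z`` is 1 when the treated
    member is the case.  The ``T`` column is identically 1.  Used by
    :func:`clogit`.
    """
    disc, _, _ = _discordant(pairs, cohort.y)
    ti = pairs.treated_idx[disc]
    ci = pairs.control_idx[disc]
    cols = []
    for tm in terms:
        if tm == "T":
            cols.append(np.ones(len(ti)))
        else:
            vt = _term_column(tm, cohort.x1[ti], cohort.x2[ti], None)
            vc = _term_column(tm, cohort.x1[ci], cohort.x2[ci], None)
            cols.append(vt - vc)
    d = np.column_stack(cols) if cols else np.empty((len(ti), 0))
    z = (cohort.y[ti] == 1).astype(float)
    return d, z


def conditional_loglik(beta: np.ndarray, d: np.ndarray, z: np.ndarray) -> float:
    """1:1-pair conditional log-likelihood at ``beta``.

    Each discordant pair contributes ``log expit(s * d @ beta)`` where
    ``s = +1`` if the treated member is the case and ``-1`` otherwise;
    concordant pairs contribute nothing (they are already excluded from
    ``d``).  At ``beta = 0`` this is ``-D log 2`` for ``D`` discordant
    pairs.
    """
    s = 2.0 * z - 1.0
    return float(-np.logaddexp(0.0, -s * (d @ beta)).sum())


def clogit(
    pairs: MatchedPairs,
    cohort: Cohort,
    terms: Sequence[str] = ("T", "X1"),
    *,
    max_iter: int = 100,
) -> EstimateRecord:
    """Conditional logistic regression for 1:1 matched pairs.

    Maximizes the pair-conditional likelihood over outcome-discordant pairs
    by Newton iterations with step-halving (the likelihood never decreases
    across iterations); convergence when the largest score component falls
    below 1e-8.  The estimate is ``exp`` of the coefficient on ``T``
    (a conditional odds ratio).  Divergence of the coefficient vector
    (sup-norm above 1e3) is flagged as non-convergence/separation.

    Raises ``ValueError`` when some term has zero within-pair difference in
    every pair (e.g. an ``X2`` main effect under exact-``X2`` strata),
    naming the term; returns an undefined-status record when no pair is
    outcome-discordant.
    """
    terms = tuple(terms)
    if "T" not in terms:
        raise ValueError("terms must include 'T'")
    d, z = pair_differences(pairs, cohort, terms)
    n_disc = len(z)
    if n_disc == 0:
        return EstimateRecord(
            method="clogit", terms=terms, estimate=np.nan, scale="odds_ratio",
            converged=False, status="undefined", n_used=0, b=0, c=0,
        )
    for j, tm in enumerate(terms):
        if np.all(d[:, j] == 0.0):
            raise ValueError(
                f"term {tm!r} has zero within-pair difference everywhere; "
                "it is not identified in a pair-conditional likelihood"
            )
    if np.linalg.matrix_rank(d) < d.shape[1]:
        raise ValueError(f"collinear within-pair differences among terms {terms}")

    b = int(z.sum())
    c = n_disc - b
    beta = np.zeros(len(terms))
    ll = conditional_loglik(beta, d, z)
    converged = False
    status = "ok"
    for _ in range(max_iter):
        p = expit(d @ beta)
        score = d.T @ (z - p)
        if np.abs(score).max() < 1e-8:
            converged = True
            break
        w = p * (1.0 - p)
        hess = d.T @ (d * w[:, None])
        try:
            step = np.linalg.solve(hess, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, score, rcond=None)[0]
        scale = 1.0
        ll_new = ll
        for _ in range(40):
            ll_new = conditional_loglik(beta + scale * step, d, z)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll = ll_new
        if np.abs(beta).max() > 1e3:
            status = "separation"
            break
    est = float(np.exp(beta[terms.index("T")]))
    return EstimateRecord(
        method="clogit", terms=terms, estimate=est, scale="odds_ratio",
        converged=converged, status=status if status != "separation" else "undefined",
        n_used=n_disc, b=b, c=c,
    )
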