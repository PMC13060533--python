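"""Matching designs: exact, coarsened-exact, and propensity-score caliper.

Coarsened exact matching (CEM) bins covariates, forms strata of subjects
sharing a coarsened key, drops strata lacking either arm, and either weights
controls (``n1k/n0k``) or randomly 1:1-pairs within strata.  Exact matching
is CEM with identity coarsening.  Propensity-score matching fits a logistic
treatment model in-repo and greedily pairs each treated subject to its
nearest unused control on the logit propensity scale, subject to a caliper
expressed as a multiple of the logit-propensity standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.random import default_rng
from scipy.special import expit

from .cohorts import Cohort, _term_column

__all__ = [
    "SeparationError",
    "CoarseningScheme",
    "StratumAssignment",
    "MatchedPairs",
    "PSModelFit",
    "coarsen_equal_width",
    "apply_coarsening",
    "build_strata",
    "pair_within_strata",
    "fit_propensity",
    "match_nn_caliper",
]

PS_DEFAULT_TERMS = ("1", "X1", "X1^2", "X2", "X1*X2")


class SeparationError(RuntimeError):
    """Logistic fit diverged; the offending term is named in the message."""


@dataclass(frozen=True)
class CoarseningScheme:
    """Per-covariate coarsening rules.

    ``rules`` maps covariate name to one of ``("identity",)``,
    ``("equal_width", K)`` or ``("cutpoints", sequence)``.
    """

    rules: Mapping[str, tuple]

    def __post_init__(self) -> None:
        for name, rule in self.rules.items():
            kind = rule[0]
            if kind == "identity":
                continue
            if kind == "equal_width":
                if int(rule[1]) < 1:
                    raise ValueError(f"{name}: K must be >= 1")
            elif kind == "cutpoints":
                cuts = np.asarray(rule[1], float)
                if cuts.size and not (np.diff(cuts) > 0).all():
                    raise ValueError(f"{name}: cutpoints must be strictly increasing")
            else:
                raise ValueError(f"{name}: unknown rule {kind!r}")


def coarsen_equal_width(values: np.ndarray, k: int) -> np.ndarray:
    """Bin values into ``k`` equal-width bins over their observed range.

    Bins are left-closed/right-open with the last bin closed; indices run
    0..k-1 and are monotone in the value.  A constant input maps to bin 0.
    """
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("empty input")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    if int(k) < 1:
        raise ValueError("k must be >= 1")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros(values.shape, dtype=np.int64)
    idx = np.floor((values - lo) / (hi - lo) * k).astype(np.int64)
    return np.clip(idx, 0, k - 1)


def apply_coarsening(cohort: Cohort, scheme: CoarseningScheme) -> np.ndarray:
    """Coarsened key matrix (n, p), one column per covariate in the scheme."""
    cols = []
    values = {"X1": cohort.x1, "X2": cohort.x2}
    for name, rule in scheme.rules.items():
        v = values[name]
        if rule[0] == "identity":
            cols.append(np.asarray(v, float))
        elif rule[0] == "equal_width":
            cols.append(coarsen_equal_width(v, int(rule[1])).astype(float))
        else:
            cols.append(np.searchsorted(np.asarray(rule[1], float), v, side="right").astype(float))
    return np.column_stack(cols)


@dataclass
class StratumAssignment:
    """Subjects mapped to coarsened strata, with retention and weights.

    ``stratum_index`` gives each subject's stratum id (an index into
    ``stratum_keys``); a stratum is retained iff it contains at least one
    treated and one control subject.  Retained treated subjects get weight
    1, retained controls ``n1k/n0k``, dropped subjects 0 — so the weighted
    control total equals the treated total within every retained stratum.
    """

    stratum_index: np.ndarray      # (n,) int
    stratum_keys: np.ndarray       # (S, p)
    n1: np.ndarray                 # (S,) treated count per stratum
    n0: np.ndarray                 # (S,) control count per stratum
    retained_strata: np.ndarray    # (S,) bool
    retained: np.ndarray           # (n,) bool
    weights: np.ndarray            # (n,) float
    t: np.ndarray                  # (n,) 0/1

    @property
    def n_strata(self) -> int:
        return len(self.stratum_keys)

    @property
    def n_retained_strata(self) -> int:
        return int(self.retained_strata.sum())

    @property
    def all_dropped(self) -> bool:
        return self.n_retained_strata == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": np.arange(len(self.t)),
             "stratum": self.stratum_index,
             "role": np.where(self.t == 1, "treated", "control"),
             "retained": self.retained,
             "weight": self.weights}
        )


def build_strata(keys: np.ndarray, t: np.ndarray) -> StratumAssignment:
    """Group subjects by coarsened key and apply the retention rule.

    ``keys`` is an (n, p) matrix (or length-n vector) of coarsened values;
    rows equal elementwise share a stratum.  An all-dropped result is legal
    and flagged via :attr:`StratumAssignment.all_dropped`.
    """
    keys = np.asarray(keys)
    if keys.ndim == 1:
        keys = keys[:, None]
    t = np.asarray(t)
    if len(keys) != len(t):
        raise ValueError("keys and t must have equal length")
    uniq, inv = np.unique(keys, axis=0, return_inverse=True)
    inv = inv.ravel()
    s = len(uniq)
    treated = t == 1
    n1 = np.bincount(inv[treated], minlength=s)
    n0 = np.bincount(inv[~treated], minlength=s)
    retained_strata = (n1 > 0) & (n0 > 0)
    retained = retained_strata[inv]
    weights = np.zeros(len(t), float)
    weights[retained & treated] = 1.0
    ctrl = retained & ~treated
    with np.errstate(divide="ignore", invalid="ignore"):
        weights[ctrl] = (n1[inv] / n0[inv])[ctrl]
    return StratumAssignment(
        stratum_index=inv, stratum_keys=uniq, n1=n1, n0=n0,
        retained_strata=retained_strata, retained=retained,
        weights=weights, t=np.asarray(t, float),
    )


@dataclass
class MatchedPairs:
    """1:1 matched pairs: parallel arrays of treated and control indices."""

    treated_idx: np.ndarray
    control_idx: np.ndarray
    design: str
    stratum_of_pair: np.ndarray | None = None   # stratum id per pair (CEM/exact)
    distance: np.ndarray | None = None          # |logit ps| gap per pair (PSM)

    def __post_init__(self) -> None:
        if len(self.treated_idx) != len(self.control_idx):
            raise ValueError("pair arrays must have equal length")
        members = np.concatenate([self.treated_idx, self.control_idx])
        if len(np.unique(members)) != len(members):
            raise ValueError("a subject appears in more than one pair")

    @property
    def n_pairs(self) -> int:
        return len(self.treated_idx)

    def member_indices(self) -> np.ndarray:
        """Indices of all matched subjects (treated then controls)."""
        return np.concatenate([self.treated_idx, self.control_idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"pair": np.arange(self.n_pairs),
             "treated_id": self.treated_idx,
             "control_id": self.control_idx}
        )
        if self.stratum_of_pair is not None:
            df["stratum"] = self.stratum_of_pair
        if self.distance is not None:
            df["distance"] = self.distance
        return df


def pair_within_strata(sa: StratumAssignment, seed: int | None = None) -> MatchedPairs:
    """Randomly 1:1-pair treated and controls within each retained stratum.

    Within a stratum with ``n1`` treated and ``n0`` controls,
    ``min(n1, n0)`` pairs are drawn by independent uniform shuffles of both
    arms (pairing without replacement); surplus subjects stay unmatched.
    Deterministic given ``seed``.
    """
    if sa.all_dropped:
        raise ValueError("no retained strata to pair within")
    rng = default_rng(seed)
    order = np.argsort(sa.stratum_index, kind="stable")
    sorted_strata = sa.stratum_index[order]
    bounds = np.searchsorted(sorted_strata, np.arange(sa.n_strata + 1))
    t_pairs: list[np.ndarray] = []
    c_pairs: list[np.ndarray] = []
    strat_ids: list[np.ndarray] = []
    for k in np.flatnonzero(sa.retained_strata):
        members = order[bounds[k]:bounds[k + 1]]
        tr = members[sa.t[members] == 1]
        co = members[sa.t[members] == 0]
        m = min(len(tr), len(co))
        tr = rng.permutation(tr)[:m]
        co = rng.permutation(co)[:m]
        t_pairs.append(tr)
        c_pairs.append(co)
        strat_ids.append(np.full(m, k))
    return MatchedPairs(
        treated_idx=np.concatenate(t_pairs),
        control_idx=np.concatenate(c_pairs),
        design="cem",
        stratum_of_pair=np.concatenate(strat_ids),
    )


@dataclass
class PSModelFit:
    """Maximum-likelihood logistic treatment model."""

    terms: tuple[str, ...]
    coef: np.ndarray
    propensity: np.ndarray
    logit_ps: np.ndarray
    converged: bool
    n_iter: int


def _design_matrix(cohort: Cohort, terms: Sequence[str]) -> np.ndarray:
    return np.column_stack(
        [_term_column(term, cohort.x1, cohort.x2, cohort.t) for term in terms]
    )


def _logistic_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    return float((y * eta - np.logaddexp(0.0, eta)).sum())


def fit_propensity(
    cohort: Cohort,
    terms: Sequence[str] = PS_DEFAULT_TERMS,
    *,
    max_iter: int = 100,
) -> PSModelFit:
    """Fit the logistic treatment model by Newton-Raphson.

    Convergence: max |score component| < 1e-8, or relative log-likelihood
    change < 1e-10.  Raises :class:`SeparationError`, naming the runaway
    term, if coefficients diverge (sup-norm above 1e3), and ``ValueError``
    on a rank-deficient design.
    """
    X = _design_matrix(cohort, terms)
    y = np.asarray(cohort.t, float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError(f"rank-deficient design for terms {tuple(terms)}")
    beta = np.zeros(p)
    ll = _logistic_loglik(X @ beta, y)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        # diverging fit that classifies perfectly = separation
        if np.abs(eta).max() > 30 and np.all((eta > 0) == (y == 1)):
            bad = tuple(terms)[int(np.abs(beta).argmax())]
            raise SeparationError(
                f"perfect separation: coefficient on {bad!r} diverges"
            )
        score = X.T @ (y - mu)
        if np.abs(score).max() < 1e-8:
            converged = True
            break
        w = mu * (1.0 - mu)
        hess = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(hess, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, score, rcond=None)[0]
        # step-halving keeps the likelihood non-decreasing
        scale = 1.0
        for _ in range(40):
            ll_new = _logistic_loglik(X @ (beta + scale * step), y)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        if np.abs(beta).max() > 1e3:
            bad = tuple(terms)[int(np.abs(beta).argmax())]
            raise SeparationError(
                f"perfect separation suspected: coefficient on {bad!r} diverged"
            )
        if abs(ll_new - ll) < 1e-10 * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    eta = X @ beta
    if np.abs(eta).max() > 15 and np.all((eta > 0) == (y == 1)):
        bad = tuple(terms)[int(np.abs(beta).argmax())]
        raise SeparationError(
            f"perfect separation: coefficient on {bad!r} diverges"
        )
    return PSModelFit(
        terms=tuple(terms), coef=beta, propensity=expit(eta),
        logit_ps=eta, converged=converged, n_iter=it,
    )


def _nearest_alive(ptr: np.ndarray, dead: np.ndarray, j: int, step: int, lim: int) -> int:
    """Follow pointers (with path compression) to the nearest alive index."""
    path = []
    while 0 <= j < lim and dead[j]:
        path.append(j)
        j = ptr[j]
    for q in path:
        ptr[q] = j
    return j


def match_nn_caliper(
    fit: PSModelFit,
    t: np.ndarray,
    caliper_mult: float = 0.2,
    seed: int | None = None,
) -> MatchedPairs:
    """Greedy 1:1 nearest-neighbor caliper matching on the logit propensity.

    Treated subjects are processed in seeded random order; each takes its
    nearest not-yet-used control on the logit-propensity scale, provided the
    gap does not exceed ``caliper_mult`` times the sample SD of the logit
    propensity (computed over the whole cohort, both arms pooled).  Treated
    subjects with no admissible control are discarded.  Equidistant ties go
    to the lower control index.  Matching is without replacement.
    """
    if not fit.converged:
        raise ValueError("propensity fit did not converge")
    t = np.asarray(t)
    eta = np.asarray(fit.logit_ps, float)
    sd = float(eta.std(ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate propensity fit: zero SD of logit PS")
    caliper = caliper_mult * sd

    rng = default_rng(seed)
    treated_ids = np.flatnonzero(t == 1)
    control_ids = np.flatnonzero(t == 0)
    c_order = np.argsort(eta[control_ids], kind="stable")
    c_ids = control_ids[c_order]
    c_eta = eta[c_ids]
    m = len(c_ids)

    left = np.arange(m) - 1        # pointer toward smaller eta when dead
    right = np.arange(m) + 1       # pointer toward larger eta when dead
    dead = np.zeros(m, bool)

    pair_t: list[int] = []
    pair_c: list[int] = []
    dists: list[float] = []
    for i in rng.permutation(treated_ids):
        e = eta[i]
        pos = int(np.searchsorted(c_eta, e))
        lcand = _nearest_alive(left, dead, pos - 1, -1, m)
        rcand = _nearest_alive(right, dead, pos, +1, m)
        best = -1
        best_d = np.inf
        if 0 <= lcand < m:
            best, best_d = lcand, e - c_eta[lcand]
        if 0 <= rcand < m:
            d = c_eta[rcand] - e
            if d < best_d or (d == best_d and (best < 0 or c_ids[rcand] < c_ids[best])):
                best, best_d = rcand, d
        if best >= 0 and best_d <= caliper:
            dead[best] = True
            pair_t.append(int(i))
            pair_c.append(int(c_ids[best]))
            dists.append(float(best_d))
    return MatchedPairs(
        treated_idx=np.asarray(pair_t, dtype=np.int64),
        control_idx=np.asarray(pair_c, dtype=np.int64),
        design="psm",
        distance=np.asarray(dists, float),
    )
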