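"""Balance and retention diagnostics for matched designs.

Coarsening guarantees balance only on the coarsened scale; these routines
measure what is left on the original scale (per-stratum mean differences
and their treated-weighted aggregate) and how many subjects the retention
rule discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matching import StratumAssignment

__all__ = ["BalanceReport", "RetentionReport", "stratum_imbalance", "retention"]


@dataclass
class BalanceReport:
    """Residual covariate imbalance within retained strata.

    ``per_stratum`` has one row per retained stratum with the
    treated-minus-control mean of each original covariate; ``aggregate``
    weights those rows by treated count n1k.  ``smd_before``/``smd_after``
    hold the overall standardized mean difference computed on the full
    cohort and on the retained (weighted) sample.
    """

    per_stratum: pd.DataFrame
    aggregate: pd.Series
    smd_before: pd.Series
    smd_after: pd.Series


@dataclass
class RetentionReport:
    n_treated_before: int
    n_control_before: int
    n_treated_after: int
    n_control_after: int
    n_strata_formed: int
    n_strata_retained: int

    @property
    def treated_fraction_retained(self) -> float:
        if self.n_treated_before == 0:
            return float("nan")
        return self.n_treated_after / self.n_treated_before


def _smd(x: np.ndarray, t: np.ndarray, w: np.ndarray | None = None) -> float:
    # standardized mean difference with the pooled unweighted SD as scale
    if w is None:
        w = np.ones_like(x)
    m1 = np.average(x[t == 1], weights=w[t == 1]) if (t == 1).any() else np.nan
    m0 = np.average(x[t == 0], weights=w[t == 0]) if (t == 0).any() else np.nan
    s1 = x[t == 1].var(ddof=1) if (t == 1).sum() > 1 else np.nan
    s0 = x[t == 0].var(ddof=1) if (t == 0).sum() > 1 else np.nan
    pooled = np.sqrt((s1 + s0) / 2.0)
    return float((m1 - m0) / pooled) if pooled > 0 else float("nan")


def stratum_imbalance(sa: StratumAssignment, covariates: dict[str, np.ndarray]) -> BalanceReport:
    """Within-stratum mean differences of the original covariates.

    For each retained stratum, the treated-minus-control mean of each
    covariate; aggregated across strata with treated-count weights n1k
    (ATT orientation, matching the control-weighting scheme).
    """
    if sa.all_dropped:
        raise ValueError("no retained strata")
    t = sa.t
    rows = []
    for k in np.flatnonzero(sa.retained_strata):
        members = sa.stratum_index == k
        row: dict[str, float] = {"stratum": int(k), "n1": int(sa.n1[k]), "n0": int(sa.n0[k])}
        for name, x in covariates.items():
            x = np.asarray(x, float)
            row[name] = float(x[members & (t == 1)].mean() - x[members & (t == 0)].mean())
        rows.append(row)
    per_stratum = pd.DataFrame(rows)
    w = per_stratum["n1"].to_numpy(float)
    aggregate = pd.Series(
        {name: float(np.average(per_stratum[name], weights=w)) for name in covariates}
    )
    smd_before = pd.Series(
        {name: _smd(np.asarray(x, float), t) for name, x in covariates.items()}
    )
    smd_after = pd.Series(
        {
            name: _smd(
                np.asarray(x, float)[sa.retained], t[sa.retained],
                sa.weights[sa.retained],
            )
            for name, x in covariates.items()
        }
    )
    return BalanceReport(per_stratum, aggregate, smd_before, smd_after)


def retention(sa: StratumAssignment) -> RetentionReport:
    """Counts of subjects and strata surviving the both-arms retention rule."""
    t = sa.t
    return RetentionReport(
        n_treated_before=int((t == 1).sum()),
        n_control_before=int((t == 0).sum()),
        n_treated_after=int(((t == 1) & sa.retained).sum()),
        n_control_after=int(((t == 0) & sa.retained).sum()),
        n_strata_formed=sa.n_strata,
        n_strata_retained=sa.n_retained_strata,
    )
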