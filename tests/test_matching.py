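import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from coarsematch import (
    SeparationError,
    build_strata,
    coarsen_equal_width,
    fit_propensity,
    match_nn_caliper,
    pair_within_strata,
)
from coarsematch.matching import PSModelFit, _logistic_loglik

from .conftest import make_cohort


class TestCoarsenEqualWidth:
    @pytest.mark.parametrize(
        "values, k, expected",
        [
            ([0.0, 1.9, 2.0, 9.9, 10.0], 5, [0, 0, 1, 4, 4]),
            ([3.0, 3.0, 3.0], 7, [0, 0, 0]),       # degenerate range
            ([0.0, 10.0], 1, [0, 0]),
        ],
    )
    def test_examples(self, values, k, expected):
        assert coarsen_equal_width(np.array(values), k).tolist() == expected

    def test_discrete_support_full_resolution_is_relabeling(self):
        """K equal to the number of distinct equally-spaced values gives a
        strictly monotone relabeling (sort-and-rank oracle)."""
        rng = np.random.default_rng(0)
        values = rng.integers(0, 11, size=500).astype(float)
        bins = coarsen_equal_width(values, 11)
        ranks = np.searchsorted(np.unique(values), values)
        assert np.array_equal(bins, ranks)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50),
           st.integers(1, 20))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_in_value(self, values, k):
        v = np.asarray(values)
        bins = coarsen_equal_width(v, k)
        order = np.argsort(v, kind="stable")
        assert (np.diff(bins[order]) >= 0).all()
        assert bins.min() >= 0 and bins.max() <= k - 1

    def test_rejects_empty_and_nonfinite(self):
        with pytest.raises(ValueError):
            coarsen_equal_width(np.array([]), 3)
        with pytest.raises(ValueError):
            coarsen_equal_width(np.array([1.0, np.nan]), 3)


class TestBuildStrata:
    def test_toy_retention_and_weights(self):
        # treated keys (0,0),(0,0),(1,0); control keys (0,0),(2,1)
        keys = np.array([[0, 0], [0, 0], [1, 0], [0, 0], [2, 1]])
        t = np.array([1, 1, 1, 0, 0])
        sa = build_strata(keys, t)
        assert sa.n_retained_strata == 1
        k = np.flatnonzero(sa.retained_strata)[0]
        assert sa.n1[k] == 2 and sa.n0[k] == 1
        assert sa.weights[3] == pytest.approx(2.0)   # lone control weight n1/n0
        assert (~sa.retained).sum() == 2

    def test_all_treated_all_dropped(self):
        sa = build_strata(np.array([[0], [1]]), np.array([1, 1]))
        assert sa.all_dropped
        assert (sa.weights == 0).all()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_weighted_controls_equal_retained_treated(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 50)
        keys = rng.integers(0, 5, size=(n, 2))
        t = rng.integers(0, 2, size=n)
        sa = build_strata(keys, t)
        ctrl_total = sa.weights[(sa.t == 0)].sum()
        treated_total = (sa.retained & (sa.t == 1)).sum()
        assert ctrl_total == pytest.approx(float(treated_total))

    def test_matches_brute_force_groupby(self, rng):
        """Retention and weights re-derived by a dict-based group-by."""
        n = 40
        keys = rng.integers(0, 3, size=(n, 2))
        t = rng.integers(0, 2, size=n)
        sa = build_strata(keys, t)
        groups: dict[tuple, list[int]] = {}
        for i in range(n):
            groups.setdefault(tuple(keys[i]), []).append(i)
        for members in groups.values():
            n1 = sum(t[i] for i in members)
            n0 = len(members) - n1
            keep = n1 > 0 and n0 > 0
            for i in members:
                assert sa.retained[i] == keep
                expect_w = 0.0 if not keep else (1.0 if t[i] == 1 else n1 / n0)
                assert sa.weights[i] == pytest.approx(expect_w)


class TestPairWithinStrata:
    def test_forced_pair(self):
        sa = build_strata(np.zeros((2, 1)), np.array([1, 0]))
        pairs = pair_within_strata(sa, seed=0)
        assert pairs.n_pairs == 1
        assert pairs.treated_idx[0] == 0 and pairs.control_idx[0] == 1

    def test_min_rule_leaves_surplus_unmatched(self):
        t = np.array([1, 1, 0, 0, 0])
        sa = build_strata(np.zeros((5, 1)), t)
        pairs = pair_within_strata(sa, seed=3)
        assert pairs.n_pairs == 2
        assert len(set(pairs.control_idx)) == 2

    def test_uniform_pairing_frequencies(self):
        """In a 2 treated x 2 control stratum each of the two possible
        pairings appears in half the seeds (exhaustive enumeration gives
        probability 1/2 each)."""
        t = np.array([1, 1, 0, 0])
        sa = build_strata(np.zeros((4, 1)), t)
        hits = 0
        for seed in range(1000):
            pairs = pair_within_strata(sa, seed=seed)
            match = dict(zip(pairs.treated_idx, pairs.control_idx))
            if match[0] == 2:
                hits += 1
        assert abs(hits / 1000 - 0.5) < 0.05

    def test_deterministic_given_seed(self, study2_cohort):
        bins = coarsen_equal_width(study2_cohort.x1, 10)
        sa = build_strata(np.column_stack([bins, study2_cohort.x2]), study2_cohort.t)
        a = pair_within_strata(sa, seed=5)
        b = pair_within_strata(sa, seed=5)
        assert np.array_equal(a.treated_idx, b.treated_idx)
        assert np.array_equal(a.control_idx, b.control_idx)


class TestFitPropensity:
    def test_saturated_binary_closed_form(self):
        x1 = np.repeat([0.0, 1.0], 100)
        t = np.concatenate([np.repeat([1.0, 0.0], [30, 70]),
                            np.repeat([1.0, 0.0], [60, 40])])
        cohort = make_cohort(x1, np.zeros(200), t, np.zeros(200))
        fit = fit_propensity(cohort, terms=("1", "X1"))
        assert fit.converged
        assert fit.coef[0] == pytest.approx(np.log(30 / 70), abs=1e-8)
        assert fit.coef[1] == pytest.approx(np.log((60 / 40) / (30 / 70)), abs=1e-8)

    def test_intercept_only(self):
        t = np.repeat([1.0, 0.0], [300, 700])
        cohort = make_cohort(np.zeros(1000), np.zeros(1000), t, np.zeros(1000))
        fit = fit_propensity(cohort, terms=("1",))
        assert fit.coef[0] == pytest.approx(np.log(3 / 7), abs=1e-8)

    def test_matches_generic_numerical_maximizer(self, study2_calibrated):
        """Newton coefficients agree with a derivative-free optimizer of
        the same likelihood to 1e-6."""
        from coarsematch import generate_cohort
        from coarsematch.matching import _design_matrix

        cohort = generate_cohort(study2_calibrated, 2000, seed=8)
        fit = fit_propensity(cohort)
        X = _design_matrix(cohort, fit.terms)
        y = cohort.t

        def negll(beta):
            return -_logistic_loglik(X @ beta, y)

        res = minimize(negll, fit.coef + 0.05, method="Nelder-Mead",
                       options={"fatol": 1e-13, "xatol": 1e-9,
                                "maxiter": 50_000, "maxfev": 50_000})
        assert np.abs(res.x - fit.coef).max() < 1e-6

    def test_matches_statsmodels(self, study2_cohort):
        import statsmodels.api as sm
        from coarsematch.matching import _design_matrix

        fit = fit_propensity(study2_cohort)
        X = _design_matrix(study2_cohort, fit.terms)
        sm_fit = sm.Logit(study2_cohort.t, X).fit(disp=False)
        assert np.abs(sm_fit.params - fit.coef).max() < 1e-6

    def test_perfect_separation_raises(self):
        x1 = np.concatenate([np.full(20, -1.0), np.full(20, 1.0)])
        t = np.concatenate([np.zeros(20), np.ones(20)])
        cohort = make_cohort(x1, np.zeros(40), t, np.zeros(40))
        with pytest.raises(SeparationError, match="X1"):
            fit_propensity(cohort, terms=("1", "X1"))

    def test_rank_deficiency_raises(self):
        cohort = make_cohort(np.zeros(10), np.zeros(10),
                             np.tile([1.0, 0.0], 5), np.zeros(10))
        with pytest.raises(ValueError, match="rank"):
            fit_propensity(cohort, terms=("1", "X1"))


def _manual_fit(logits, t):
    n = len(logits)
    return PSModelFit(terms=("1",), coef=np.zeros(1),
                      propensity=1 / (1 + np.exp(-np.asarray(logits))),
                      logit_ps=np.asarray(logits, float),
                      converged=True, n_iter=0)


class TestCaliperMatching:
    def test_nearest_within_caliper(self):
        logits = np.array([0.0, 0.05, 0.5])
        t = np.array([1, 0, 0])
        fit = _manual_fit(logits, t)
        sd = logits.std(ddof=1)
        pairs = match_nn_caliper(fit, t, caliper_mult=0.1 / sd, seed=0)
        assert pairs.n_pairs == 1
        assert pairs.control_idx[0] == 1

    def test_treated_unmatched_beyond_caliper(self):
        logits = np.array([0.0, 0.5])
        t = np.array([1, 0])
        fit = _manual_fit(logits, t)
        sd = logits.std(ddof=1)
        pairs = match_nn_caliper(fit, t, caliper_mult=0.1 / sd, seed=0)
        assert pairs.n_pairs == 0

    def test_degenerate_fit_raises(self):
        t = np.array([1, 0])
        fit = _manual_fit(np.zeros(2), t)
        with pytest.raises(ValueError, match="zero SD"):
            match_nn_caliper(fit, t, seed=0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_distances_within_caliper_and_no_reuse(self, seed):
        """Property check against the exhaustive distance matrix."""
        rng = np.random.default_rng(seed)
        logits = rng.normal(size=300)
        t = (rng.random(300) < 0.4).astype(float)
        fit = _manual_fit(logits, t)
        pairs = match_nn_caliper(fit, t, caliper_mult=0.2, seed=seed)
        caliper = 0.2 * logits.std(ddof=1)
        gaps = np.abs(logits[pairs.treated_idx] - logits[pairs.control_idx])
        assert (gaps <= caliper + 1e-12).all()
        assert np.array_equal(gaps, pairs.distance)
        assert len(set(pairs.control_idx)) == pairs.n_pairs


class TestDesignEquivalences:
    def test_identity_coarsening_equals_exact_matching(self, rng):
        """CEM with identity coarsening on every covariate yields the
        strata of exact matching (same partition of subjects)."""
        x1 = rng.integers(0, 4, size=60).astype(float)
        x2 = rng.integers(0, 2, size=60).astype(float)
        t = rng.integers(0, 2, size=60).astype(float)
        exact = build_strata(np.column_stack([x1, x2]), t)
        # identity coarsening: one bin per distinct value via full-resolution
        b1 = coarsen_equal_width(x1, len(np.unique(x1)))
        cem = build_strata(np.column_stack([b1, x2]), t)
        # same partition: stratum labels are a bijection
        pair_labels = set(zip(exact.stratum_index, cem.stratum_index))
        assert len(pair_labels) == exact.n_strata == cem.n_strata
        assert np.array_equal(exact.retained, cem.retained)
        assert np.allclose(exact.weights, cem.weights)

    def test_retained_treated_nonincreasing_in_k(self, study2_cohort):
        """Nested dyadic refinements only ever split strata, so the
        retained treated count cannot grow with K."""
        counts = []
        for k in (5, 10, 20, 40):
            bins = coarsen_equal_width(study2_cohort.x1, k)
            sa = build_strata(np.column_stack([bins, study2_cohort.x2]),
                              study2_cohort.t)
            counts.append(int((sa.retained & (sa.t == 1)).sum()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))
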