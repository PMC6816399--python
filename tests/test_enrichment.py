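import math

import numpy as np
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from rtshift.class_profiles import ConditionProfile
from rtshift.enrichment import (
    EnrichmentRecord,
    enrichment,
    enrichment_sd,
    fit_all_regressions,
    fit_gc_regression,
    holm_adjust,
    pairwise_enrichment,
    significance_stars,
)
from rtshift.gc_content import ClassGc

nonneg = st.floats(min_value=0, max_value=1, allow_nan=False)
positive = st.floats(min_value=1e-6, max_value=1, allow_nan=False)


class TestEnrichment:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(0.25, 0.25, 0.0), (0.3, 0.0, 1.0), (0.0, 0.3, -1.0), (0.3, 0.1, 0.5)],
    )
    def test_anchor_values(self, a, b, expected):
        assert enrichment(a, b) == pytest.approx(expected, abs=1e-15)

    def test_undefined_when_both_absent(self):
        assert math.isnan(enrichment(0.0, 0.0))

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            enrichment(-0.1, 0.2)

    @given(a=nonneg, b=nonneg)
    @settings(max_examples=300, deadline=None)
    def test_antisymmetric_and_bounded(self, a, b):
        if a + b == 0:
            return
        e = enrichment(a, b)
        assert e == -enrichment(b, a)
        assert -1.0 <= e <= 1.0
        assert (e > 0) == (a > b) and (e == 0) == (a == b)

    @given(a=positive, b=positive, c=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=200, deadline=None)
    def test_scale_invariant(self, a, b, c):
        assert enrichment(c * a, c * b) == pytest.approx(enrichment(a, b), abs=1e-12)


class TestEnrichmentSd:
    def test_zero_dispersion_gives_zero(self):
        assert enrichment_sd(0.3, 0.2, 0.0, 0.0) == 0.0

    def test_symmetric_point_value(self):
        # 2*sqrt(0.25*0.01 + 0.25*0.01)/1
        assert enrichment_sd(0.5, 0.5, 0.1, 0.1) == pytest.approx(math.sqrt(2) / 10)

    def test_undefined_when_both_absent(self):
        assert math.isnan(enrichment_sd(0.0, 0.0, 0.1, 0.1))

    def test_argument_swap_symmetry(self):
        assert enrichment_sd(0.3, 0.1, 0.02, 0.05) == enrichment_sd(0.1, 0.3, 0.05, 0.02)

    def test_matches_symbolic_delta_method(self):
        # independent oracle: differentiate (A-B)/(A+B) with sympy
        A, B, dA, dB = sympy.symbols("A B dA dB", positive=True)
        f = (A - B) / (A + B)
        sd_expr = sympy.sqrt(sympy.diff(f, A) ** 2 * dA**2 + sympy.diff(f, B) ** 2 * dB**2)
        oracle = sympy.lambdify((A, B, dA, dB), sympy.simplify(sd_expr), "numpy")
        rng = np.random.default_rng(1)
        for _ in range(200):
            a, b = rng.uniform(0.01, 1, 2)
            da, db = rng.uniform(0, 0.2, 2)
            got = enrichment_sd(a, b, da, db)
            assert got == pytest.approx(float(oracle(a, b, da, db)), rel=1e-12)

    def test_matches_monte_carlo_sd(self):
        rng = np.random.default_rng(7)
        n = 100_000
        for a, b in [(0.3, 0.1), (0.2, 0.25), (0.05, 0.4)]:
            da = db = 0.01 * (a + b)
            av = a + rng.normal(0, da, n)
            bv = b + rng.normal(0, db, n)
            mc_sd = np.std((av - bv) / (av + bv), ddof=1)
            mc_err = mc_sd / math.sqrt(2 * n)
            assert abs(enrichment_sd(a, b, da, db) - mc_sd) < 3 * mc_err


def _profiles(cond_values: dict, sd=0.01, n=4):
    """cond_values: condition -> {class: mean}"""
    out = []
    for cond, classes in cond_values.items():
        for cls, mean in classes.items():
            out.append(ConditionProfile(cond, cls, mean, sd, n))
    return out


class TestPairwiseEnrichment:
    def test_four_conditions_give_six_pairs(self):
        conds = {(e, t): {"X": 0.5, "Y": 0.5} for e, t in
                 [("A", 42.0), ("A", 55.0), ("B", 55.0), ("C", 57.0)]}
        records = pairwise_enrichment(_profiles(conds))
        pairs = {(r.condition_a, r.condition_b) for r in records}
        assert len(pairs) == 6
        assert len(records) == 12

    def test_orientation_follows_condition_ordering(self):
        conds = {("B", 55.0): {"X": 0.2}, ("A", 42.0): {"X": 0.6}, ("A", 55.0): {"X": 0.2}}
        records = pairwise_enrichment(_profiles(conds))
        for r in records:
            assert r.condition_a < r.condition_b
        r = next(x for x in records if x.condition_b == ("B", 55.0)
                 and x.condition_a == ("A", 42.0))
        assert r.enrichment == pytest.approx(0.5)  # A=0.6 vs B=0.2

    def test_class_absent_from_both_is_undefined(self):
        conds = {("A", 42.0): {"X": 1.0, "Y": 0.0}, ("B", 55.0): {"X": 1.0, "Y": 0.0}}
        records = pairwise_enrichment(_profiles(conds))
        y = next(r for r in records if r.class_label == "Y")
        assert not y.defined

    def test_unclassified_excluded(self):
        conds = {("A", 42.0): {"X": 0.9, "Unclassified": 0.1},
                 ("B", 55.0): {"X": 0.9, "Unclassified": 0.1}}
        records = pairwise_enrichment(_profiles(conds))
        assert {r.class_label for r in records} == {"X"}


def _records(xs, ys, cond_a=("A", 42.0), cond_b=("B", 55.0)):
    return [
        EnrichmentRecord(f"C{i:02d}", cond_a, cond_b, 0.5, 0.5, 0.01, 0.01,
                         float(y), 0.01, True)
        for i, y in enumerate(ys)
    ], [ClassGc(f"C{i:02d}", float(x), 1, "test") for i, x in enumerate(xs)]


class TestGcRegression:
    def test_perfect_collinear_fit(self):
        xs = np.linspace(0.3, 0.7, 10)
        records, gc = _records(xs, 2 * xs - 1)
        rep = fit_gc_regression(records, gc)
        assert rep.adjusted_r2 == pytest.approx(1.0)
        assert rep.slope == pytest.approx(2.0)
        assert rep.p_value < 1e-10
        assert rep.n_classes == 10

    def test_recovers_known_ols_solution(self):
        # cross-check against scipy's independent linear regression
        from scipy.stats import linregress

        rng = np.random.default_rng(4)
        xs = rng.uniform(0.3, 0.7, 25)
        ys = -1.5 * xs + 0.4 + rng.normal(0, 0.1, 25)
        records, gc = _records(xs, ys)
        rep = fit_gc_regression(records, gc)
        ref = linregress(xs, ys)
        assert rep.slope == pytest.approx(ref.slope)
        assert rep.intercept == pytest.approx(ref.intercept)
        assert rep.p_value == pytest.approx(ref.pvalue)
        r2 = ref.rvalue**2
        assert rep.adjusted_r2 == pytest.approx(1 - (1 - r2) * 24 / 23)
        assert rep.adjusted_r2 <= r2

    def test_null_rejection_rate_is_nominal(self):
        # enrichment independent of GC: ~5% of fits reject at alpha = 0.05
        rng = np.random.default_rng(11)
        xs = np.linspace(0.3, 0.7, 20)
        hits = 0
        reps = 1000
        for _ in range(reps):
            records, gc = _records(xs, rng.normal(0, 0.2, xs.size))
            if fit_gc_regression(records, gc).p_value < 0.05 :
                hits += 1
        ci = 3 * math.sqrt(0.05 * 0.95 / reps)
        assert abs(hits / reps - 0.05) < ci

    def test_fewer_than_three_points_rejected(self):
        records, gc = _records([0.3, 0.5], [0.1, 0.2])
        with pytest.raises(ValueError, match="3"):
            fit_gc_regression(records, gc)

    def test_degenerate_covariate_rejected(self):
        records, gc = _records([0.5, 0.5, 0.5, 0.5], [0.1, 0.2, 0.3, 0.4])
        with pytest.raises(ValueError, match="degenerate"):
            fit_gc_regression(records, gc)

    def test_undefined_records_excluded_from_fit(self):
        xs = np.linspace(0.3, 0.7, 10)
        records, gc = _records(xs, 2 * xs - 1)
        records[0].defined = False
        assert fit_gc_regression(records, gc).n_classes == 9

    def test_mixed_pairs_rejected(self):
        r1, gc = _records([0.3, 0.5, 0.7], [0, 0, 0])
        r2, _ = _records([0.3, 0.5, 0.7], [0, 0, 0], cond_a=("C", 50.0))
        with pytest.raises(ValueError, match="pair"):
            fit_gc_regression(r1 + r2, gc)

    def test_assumption_flag_reflects_diagnostics(self):
        rng = np.random.default_rng(5)
        xs = np.linspace(0.3, 0.7, 40)
        # strongly heteroscedastic + heavy-tailed noise trips the diagnostics
        noise = rng.standard_cauchy(40) * (xs - 0.3) ** 2
        records, gc = _records(xs, 0.2 * xs + noise)
        rep = fit_gc_regression(records, gc)
        assert rep.assumptions_ok == (rep.normality_p >= 0.05 and rep.homoscedasticity_p >= 0.05)
        assert not rep.assumptions_ok


class TestSignificance:
    @pytest.mark.parametrize(
        "p, stars",
        [(0.0009, "***"), (0.02, "*"), (0.005, "**"), (0.05, ""), (0.3, ""), (0.001, "**")],
    )
    def test_star_thresholds(self, p, stars):
        assert significance_stars(p) == stars

    def test_holm_known_values(self):
        assert holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_holm_single_p_unchanged(self):
        assert holm_adjust([0.2]) == pytest.approx([0.2])

    def test_holm_all_ones(self):
        assert holm_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_holm_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(8)
        ps = rng.uniform(0, 1, 10).tolist()
        adj = holm_adjust(ps)
        assert all(a >= p for a, p in zip(adj, ps))
        order = np.argsort(ps)
        assert all(np.diff(np.asarray(adj)[order]) >= -1e-15)

    def test_holm_option_adjusts_reports(self):
        xs = np.linspace(0.3, 0.7, 12)
        rng = np.random.default_rng(3)
        recs = []
        for i, cb in enumerate([("B", 55.0), ("C", 57.0)]):
            r, gc = _records(xs, 1.5 * xs + rng.normal(0, 0.3, 12), cond_b=cb)
            recs += r
        raw = fit_all_regressions(recs, gc)
        adj = fit_all_regressions(recs, gc, holm=True)
        expected = multipletests([r.p_value for r in raw], method="holm")[1]
        assert [r.p_value for r in adj] == pytest.approx(list(expected))
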