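"""Counting statistics, KS comparison, overlap probability and the
censoring correction."""

import numpy as np
import pytest
from scipy.stats import binom

from smfspipe.polymer import BellEvansParams, LoadingContext, sample_rupture_forces
from smfspipe.simulate import SimulationConfig, sample_event_table
from smfspipe.stats import (
    EventCounts,
    biasing_report,
    censoring_weights,
    clopper_pearson_interval,
    correct_binding_mode_ratio,
    force_distribution_kde,
    ks_two_sample,
    overlap_probability,
)

from conftest import make_complex, make_domain


class TestClopperPearson:
    def test_boundary_cases(self):
        lo, hi = clopper_pearson_interval(0, 10)
        assert lo == 0.0 and hi < 1.0
        lo, hi = clopper_pearson_interval(10, 10)
        assert lo > 0.0 and hi == 1.0

    def test_symmetric_example(self):
        lo, hi = clopper_pearson_interval(5, 10, 0.05)
        assert lo == pytest.approx(0.187, abs=0.001)
        assert hi == pytest.approx(0.813, abs=0.001)

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint
        for k, n in [(3, 17), (0, 8), (8, 8), (25, 50)]:
            lo, hi = clopper_pearson_interval(k, n, 0.05)
            slo, shi = proportion_confint(k, n, 0.05, method="beta")
            assert lo == pytest.approx(slo, abs=1e-12)
            assert hi == pytest.approx(shi, abs=1e-12)

    def test_exact_coverage_at_n50(self):
        """Exhaustive binomial enumeration: coverage >= 95% at every p."""
        n = 50
        intervals = [clopper_pearson_interval(k, n, 0.05) for k in range(n + 1)]
        for p in np.arange(0.1, 0.91, 0.1):
            pmf = binom.pmf(np.arange(n + 1), n, p)
            cover = sum(pmf[k] for k in range(n + 1)
                        if intervals[k][0] <= p <= intervals[k][1])
            assert cover >= 0.95

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            clopper_pearson_interval(5, 4)
        with pytest.raises(ValueError):
            clopper_pearson_interval(1, 10, alpha=0.0)

    def test_event_counts_wrapper(self):
        c = EventCounts.from_counts(43, 57)
        assert c.n == 100
        assert c.ci_double[0] < c.p_double < c.ci_double[1]
        assert c.ci_single[0] < c.p_single < c.ci_single[1]


from hypothesis import given, settings, strategies as st


@settings(max_examples=100, deadline=None, derandomize=True)
@given(n=st.integers(1, 200), k_frac=st.floats(0.0, 1.0),
       alpha=st.floats(0.001, 0.5))
def test_clopper_pearson_properties(n, k_frac, alpha):
    """The exact interval always brackets the point estimate and narrows
    as alpha grows."""
    k = round(k_frac * n)
    lo, hi = clopper_pearson_interval(k, n, alpha)
    assert 0.0 <= lo <= k / n <= hi <= 1.0
    lo2, hi2 = clopper_pearson_interval(k, n, min(0.9, alpha * 2))
    assert lo2 >= lo - 1e-12 and hi2 <= hi + 1e-12


def _brute_force_ks(a, b):
    """All-breakpoints ECDF supremum distance."""
    pts = np.concatenate([a, b])
    d = 0.0
    for t in pts:
        d = max(d, abs(np.mean(a <= t) - np.mean(b <= t)))
    return d


class TestKSTwoSample:
    def test_identical_samples(self):
        d, p = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0

    def test_fully_separated(self):
        d, _ = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert d == 1.0

    def test_interleaved_quarter(self):
        d, _ = ks_two_sample([1, 2, 3, 4], [1.5, 2.5, 3.5, 4.5])
        assert d == pytest.approx(0.25)

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a = rng.normal(0, 1, rng.integers(3, 15))
            b = rng.normal(rng.uniform(-1, 1), 1, rng.integers(3, 15))
            d, _ = ks_two_sample(a, b)
            assert d == pytest.approx(_brute_force_ks(a, b), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestForceKDE:
    def test_repeated_value_mode(self):
        kde = force_distribution_kde([104.0] * 25)
        assert kde.mode == pytest.approx(104.0, abs=1e-6)

    def test_integrates_to_one(self):
        rng = np.random.default_rng(2)
        kde = force_distribution_kde(rng.normal(100, 12, 500))
        assert np.trapezoid(kde.density, kde.grid) == pytest.approx(1.0, abs=1e-6)

    def test_mode_matches_bell_evans_analytic(self):
        params = BellEvansParams(1e-4, 0.4)
        load = LoadingContext(1000.0, 10.0)
        sample = sample_rupture_forces(params, load, 50_000, seed=6)
        kde = force_distribution_kde(sample)
        fstar = (4.114 / 0.4) * np.log(1e4 * 0.4 / (1e-4 * 4.114))
        assert abs(kde.mode - fstar) < 3.0

    def test_matches_scipy_gaussian_kde(self):
        from scipy.stats import gaussian_kde
        rng = np.random.default_rng(3)
        x = rng.normal(100, 10, 300)
        bw = 4.0
        ours = force_distribution_kde(x, bandwidth=bw, grid_points=200)
        ref = gaussian_kde(x, bw_method=bw / x.std(ddof=1))(ours.grid)
        np.testing.assert_allclose(ours.density, ref, rtol=1e-8)


class TestOverlapProbability:
    def test_complete_separation(self):
        assert overlap_probability([1, 2, 3], [10, 11]) == 1.0
        assert overlap_probability([10, 11], [1, 2, 3]) == 0.0

    def test_same_distribution_near_half(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 4000)
        b = rng.normal(0, 1, 4000)
        assert overlap_probability(a, b) == pytest.approx(0.5, abs=0.03)

    def test_small_example_pair_enumeration(self):
        # exhaustive pairs: (90,95)+ (90,105)+ (100,105)+ of 6 -> 0.5
        assert overlap_probability([90, 100, 110], [95, 105]) == pytest.approx(3 / 6)

    def test_ties_count_half(self):
        assert overlap_probability([5.0], [5.0]) == 0.5

    def test_complement_identity(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 200)
        b = rng.normal(0.3, 1.2, 150)
        assert overlap_probability(a, b) + overlap_probability(b, a) == \
            pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_kde_integral(self):
        """Independent estimate: integral of KDE_a times the survival of b."""
        rng = np.random.default_rng(9)
        a = rng.normal(100, 10, 800)
        b = rng.normal(110, 12, 800)
        pairwise = overlap_probability(a, b)
        ka = force_distribution_kde(a, grid_points=2000)
        surv_b = 1.0 - np.searchsorted(np.sort(b), ka.grid, side="right") / b.size
        kde_est = np.trapezoid(ka.density * surv_b, ka.grid)
        assert abs(pairwise - kde_est) < 0.02

    def test_weighted_recovers_truncated_marginal(self):
        """IPW with the pooled rupture survival undoes fingerprint censoring."""
        rng = np.random.default_rng(10)
        fp = rng.normal(100, 10, 30_000)
        rupture = rng.normal(105, 12, 30_000)
        seen = fp < rupture
        truth = overlap_probability(fp, rupture)
        naive = overlap_probability(fp[seen], rupture)
        w = censoring_weights(fp[seen], rupture)
        ipw = overlap_probability(fp[seen], rupture, w)
        assert abs(ipw - truth) < 0.01
        assert naive > truth + 0.03  # the bias the weighting removes

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            overlap_probability([], [1.0])


class TestCorrection:
    def test_equal_overlaps_cancel(self):
        counts = EventCounts.from_counts(40, 60)
        res = correct_binding_mode_ratio(counts, 0.7, 0.7, 200, seed=0)
        assert res.corrected_ratio == pytest.approx(res.observed_ratio)

    def test_stated_rule_arithmetic(self):
        counts = EventCounts.from_counts(430, 570)
        res = correct_binding_mode_ratio(counts, 0.5, 1.0, 200, seed=0)
        assert res.corrected_ratio == pytest.approx(570 / 860, abs=1e-12)

    def test_zero_singles_undefined(self):
        with pytest.raises(ValueError):
            correct_binding_mode_ratio(EventCounts.from_counts(0, 5), 0.5, 0.9)

    def test_bootstrap_interval_brackets_estimate(self):
        counts = EventCounts.from_counts(400, 420)
        res = correct_binding_mode_ratio(counts, 0.5, 0.9, 500, seed=1)
        lo, hi = res.bootstrap_interval
        assert lo < res.corrected_ratio < hi

    def test_recovery_coverage_over_replicates(self):
        """Barrier-level recovery: with apparent doubles/singles odds 1 and
        xylanase-grade censoring the bootstrap interval contains 1.0 in
        >= 17 of 20 replicates."""
        hits = 0
        for r in range(20):
            res = _event_level_correction(2000, seed=100 + r, replicates=400)
            lo, hi = res.bootstrap_interval
            hits += lo <= 1.0 <= hi
        assert hits >= 17


def _event_level_correction(n, seed, replicates=400):
    """Simulate barrier thresholds, censor, estimate overlaps, correct."""
    cfg = SimulationConfig(
        fingerprint=make_domain("xylanase", 89.0, 108.3),
        complex=make_complex(0.5, sub_fstar=90.0),  # sub far below final
    )
    tab = sample_event_table(cfg, n, seed=seed)
    double = tab["apparent_event"].eq("double").to_numpy()
    fp = tab["fingerprint_threshold"].to_numpy()
    final = tab["final_threshold"].to_numpy()
    sub = tab["sub_threshold"].to_numpy()
    countable = tab["countable_double"].to_numpy()
    kept_single = ~double & (fp < final)
    counts = EventCounts.from_counts(int(kept_single.sum()), int(countable.sum()))
    fp_seen = fp[fp < final]
    w = censoring_weights(fp_seen, final)
    o_s = overlap_probability(fp_seen, final[~double], w)
    o_d = overlap_probability(fp_seen, sub[double], w)
    return correct_binding_mode_ratio(
        counts, o_s, o_d, replicates, seed=seed,
        force_samples={"fingerprint": fp_seen, "fingerprint_weights": w,
                       "singles": final[~double], "doubles": sub[double]})


class TestBiasingReport:
    def test_identical_conditionals(self):
        x = np.linspace(90, 120, 50)
        rep = biasing_report(x, x)
        assert rep.ks_statistic == 0.0
        assert not rep.downward_shift

    def test_censoring_produces_downward_shift(self):
        cfg = SimulationConfig()
        tab = sample_event_table(cfg, 30_000, seed=3)
        double = tab["apparent_event"].eq("double")
        kept = tab["fingerprint_unfolded"]
        rep = biasing_report(tab.loc[kept & ~double, "fingerprint_threshold"],
                             tab.loc[kept & double, "fingerprint_threshold"])
        assert rep.downward_shift
        assert rep.ks_pvalue < 0.05

    def test_no_censoring_null(self):
        """Fingerprint far weaker than the complex: conditional modes agree
        and the KS test does not reject."""
        cfg = SimulationConfig(fingerprint=make_domain("xylanase", 89.0, 60.0))
        tab = sample_event_table(cfg, 6000, seed=21)
        double = tab["apparent_event"].eq("double")
        kept = tab["fingerprint_unfolded"]
        rep = biasing_report(tab.loc[kept & ~double, "fingerprint_threshold"],
                             tab.loc[kept & double, "fingerprint_threshold"])
        assert abs(rep.mode_single - rep.mode_double) < 3.0
        assert rep.ks_pvalue > 0.05
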