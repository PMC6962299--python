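"""Cox fit, Kaplan-Meier estimator, log-rank test and the threshold-sweep
stability screen, each checked against an independent oracle."""

import numpy as np
import pytest
from scipy import optimize, stats

from pdsgscreen import (fit_cox_univariate, km_estimate, logrank_test,
                        screen_survival, stability_sweep)
from pdsgscreen.simulate import (BlockSpec, PlantedGene, SimConfig,
                                 simulate_cohort)
from pdsgscreen.survival import is_stable

from conftest import build_cohort


def cox_loglik(beta, z, t, e):
    """Breslow partial log-likelihood (valid oracle for untied times)."""
    order = np.argsort(-np.asarray(t))
    z = np.asarray(z, float)[order]
    e = np.asarray(e, int)[order]
    risk = np.cumsum(np.exp(beta * z))
    return float(np.sum(e * (beta * z - np.log(risk))))


def simulate_exponential(rng, n, beta, censor_at=None):
    z = rng.normal(size=n)
    t = rng.exponential(1.0 / (0.1 * np.exp(beta * z)))
    if censor_at is None:
        return z, t, np.ones(n, int)
    e = (t <= censor_at).astype(int)
    return z, np.minimum(t, censor_at), e


class TestCoxUnivariate:
    def test_constant_covariate_not_evaluable(self):
        res = fit_cox_univariate([1.0] * 10, range(1, 11), [1] * 10)
        assert not res.evaluable

    def test_too_few_events_not_evaluable(self):
        res = fit_cox_univariate([1, 2, 3], [5, 6, 7], [1, 0, 0])
        assert not res.evaluable

    def test_sign_antisymmetry(self, rng):
        z, t, e = simulate_exponential(rng, 80, 0.7)
        a = fit_cox_univariate(z, t, e)
        b = fit_cox_univariate(-z, t, e)
        assert a.beta == pytest.approx(-b.beta, abs=1e-6)

    def test_recovers_known_beta_and_maximizes_partial_likelihood(self, rng):
        z, t, e = simulate_exponential(rng, 500, 1.0)
        res = fit_cox_univariate(z, t, e)
        assert res.beta == pytest.approx(1.0, abs=0.15)
        # independent numeric maximization of the partial likelihood
        opt = optimize.minimize_scalar(lambda b: -cox_loglik(b, z, t, e),
                                       bounds=(-3, 3), method="bounded")
        assert res.beta == pytest.approx(opt.x, abs=0.01)

    def test_estimator_calibration(self):
        """Mean |bias| < 0.1 across beta settings, and a roughly nominal
        Wald rejection rate at beta=0 (loose band at this replicate count)."""
        rng = np.random.default_rng(11)
        n_rep = 34  # ~100 fits across the three beta settings
        rejections = 0
        for beta_true in (0.0, 0.5, 1.0):
            betas = []
            for _ in range(n_rep):
                z, t, e = simulate_exponential(rng, 300, beta_true,
                                               censor_at=20.0)
                res = fit_cox_univariate(z, t, e)
                betas.append(res.beta)
                if beta_true == 0.0 and res.p < 0.05:
                    rejections += 1
            assert abs(np.mean(betas) - beta_true) < 0.1
        assert 0.0 <= rejections / n_rep <= 0.15  # small-sample size check


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate([5, 6, 7], [0, 0, 0])
        assert curve.times.size == 0  # no drops: survival is identically 1

    def test_hand_product_limit(self):
        curve = km_estimate([1, 2, 3], [1, 1, 1])
        assert curve.survival == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert curve.at_risk.tolist() == [3, 2, 1]

    def test_doubling_observations_leaves_curve_unchanged(self, rng):
        t = rng.exponential(10, size=30)
        e = rng.integers(0, 2, size=30)
        if e.sum() == 0:
            e[0] = 1
        a = km_estimate(t, e)
        b = km_estimate(np.tile(t, 2), np.tile(e, 2))
        assert a.survival == pytest.approx(b.survival)

    def test_monotone_non_increasing_within_unit(self, rng):
        t = rng.exponential(5, size=50)
        e = rng.integers(0, 2, size=50)
        e[0] = 1
        curve = km_estimate(t, e)
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert np.all((curve.survival >= 0) & (curve.survival <= 1))

    def test_negative_times_error(self):
        with pytest.raises(ValueError):
            km_estimate([-1, 2], [1, 1])


def logrank_oracle(ta, ea, tb, eb):
    """Hand risk-table computation of the two-group log-rank chi-square."""
    ta, tb = np.asarray(ta, float), np.asarray(tb, float)
    ea, eb = np.asarray(ea, int), np.asarray(eb, int)
    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        na = np.sum(ta >= t)
        nb = np.sum(tb >= t)
        da = np.sum((ta == t) & (ea == 1))
        db = np.sum((tb == t) & (eb == 1))
        n, d = na + nb, da + db
        e_a = d * na / n
        o_minus_e += da - e_a
        if n > 1:
            var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    chi2 = o_minus_e ** 2 / var
    return chi2, float(stats.chi2.sf(chi2, 1))


class TestLogrank:
    def test_identical_groups(self):
        t, e = [1, 2, 3, 4], [1, 1, 0, 1]
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_risk_table(self):
        ta, ea = [1, 3, 5], [1, 1, 1]
        tb, eb = [2, 4, 6], [1, 1, 1]
        stat, p = logrank_test(ta, ea, tb, eb)
        stat_o, p_o = logrank_oracle(ta, ea, tb, eb)
        assert stat == pytest.approx(stat_o, abs=1e-10)
        assert p == pytest.approx(p_o, abs=1e-10)

    def test_matches_oracle_on_random_data(self, rng):
        ta = rng.exponential(5, 25)
        tb = rng.exponential(9, 30)
        ea = rng.integers(0, 2, 25)
        eb = rng.integers(0, 2, 30)
        ea[0] = 1
        stat, p = logrank_test(ta, ea, tb, eb)
        stat_o, _ = logrank_oracle(ta, ea, tb, eb)
        assert stat == pytest.approx(stat_o, rel=1e-9)
        assert p == pytest.approx(stats.chi2.sf(stat, 1), abs=1e-10)

    def test_no_events_not_evaluable(self):
        stat, p = logrank_test([1, 2], [0, 0], [3, 4], [0, 0])
        assert np.isnan(stat) and np.isnan(p)


class TestStabilityRule:
    def test_cutoff_is_strict_majority_of_full_grid(self):
        assert is_stable(11, 21)
        assert not is_stable(10, 21)

    def test_sweep_counts_and_monotone_altered_sizes(self, rng):
        n = 200
        scna = np.concatenate([rng.uniform(0.3, 1.5, 60),
                               rng.normal(0, 0.1, 140)])
        expr = np.abs(rng.normal(8, 2, n))
        hr = np.exp(0.9 * np.clip(scna, 0, None))
        t = rng.exponential(100 / hr)
        cohort = build_cohort(scna[None, :], expr[None, :], t, [1] * n)
        prof = stability_sweep(cohort, "G0000")
        assert prof.n_significant <= prof.n_evaluable <= len(prof.grid)
        sizes = [np.sum(scna >= x) for x in prof.grid]
        assert all(b <= a for a, b in zip(sizes, sizes[1:]))

    def test_inevaluable_gene_is_unstable(self):
        cohort = build_cohort(np.zeros((1, 30)), np.ones((1, 30)),
                              range(1, 31), [1] * 30)
        prof = stability_sweep(cohort, "G0000")
        assert not prof.stable and prof.n_evaluable == 0

    def test_planted_prognostic_gene_is_stable_in_most_replicates(self):
        """Strong planted hazard (log HR 1 at SCNA=1, 40% altered, n=400)
        yields a stable profile in >90% of replicates."""
        n_stable = 0
        n_rep = 30
        for seed in range(n_rep):
            cfg = SimConfig(
                n_samples=400, n_genes=4, seed=seed,
                blocks=(BlockSpec(n_genes=1, amplified_fraction=0.4),),
                planted_pdsg=(PlantedGene("G0000", 2.0, 1.0),),
            )
            cohort = simulate_cohort(cfg)
            n_stable += stability_sweep(cohort, "G0000").stable
        assert n_stable / n_rep >= 0.9


class TestScreenSurvival:
    def test_empty_candidates(self, tiny_cohort):
        cox, profiles = screen_survival(tiny_cohort, [])
        assert cox == [] and profiles == []

    def test_cox_failures_never_reach_stability(self, rng):
        n = 120
        scna = rng.normal(0, 0.5, size=(3, n))
        expr = np.abs(rng.normal(10, 2, size=(3, n)))
        t = rng.exponential(50, n)
        cohort = build_cohort(scna, expr, t, [1] * n)
        candidates = [(f"G{i:04d}", "amplified") for i in range(3)]
        cox, profiles = screen_survival(cohort, candidates, cox_p=0.05)
        passing = {c.gene for c in cox
                   if c.evaluable and c.converged and c.p < 0.05}
        assert {p.gene for p in profiles} == passing
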