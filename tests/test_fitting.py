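import numpy as np
import pytest
from scipy.special import expit

from timeavg.fitting import (
    VARIANTS,
    DegenerateDataError,
    FitFailureError,
    compare_variants,
    fit_observers,
    fit_psychometric,
    jnd_of,
    pse_of,
)

LN3 = np.log(3.0)


def logistic_trials(alpha, beta, lam, n, rng, lo=400.0, hi=1000.0):
    x = rng.uniform(lo, hi, size=n)
    p = lam / 2 + (1 - lam) * expit((x - alpha) * beta)
    r = (rng.random(n) < p).astype(int)
    return list(zip(x, r))


class TestFitLogistic:
    def test_parameter_recovery_median(self):
        """Median recovery over 100 seeds: alpha +-25 ms, beta within x/1.5."""
        alpha_errs, beta_ratios = [], []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            trials = logistic_trials(700.0, 0.01, 0.0, 240, rng)
            fit = fit_psychometric(trials, "logistic", n_starts=3, seed=seed)
            alpha_errs.append(abs(fit.params["alpha"] - 700.0))
            beta_ratios.append(fit.params["beta"] / 0.01)
        assert np.median(alpha_errs) < 25.0
        med_ratio = np.median(beta_ratios)
        assert 1 / 1.5 < med_ratio < 1.5

    def test_loglik_beats_generative(self, rng):
        trials = logistic_trials(700.0, 0.01, 0.0, 240, rng)
        fit = fit_psychometric(trials, "logistic")
        x = np.array([t[0] for t in trials])
        r = np.array([t[1] for t in trials])
        p = np.clip(expit((x - 700.0) * 0.01), 1e-9, 1 - 1e-9)
        gen_ll = float(np.sum(np.where(r == 1, np.log(p), np.log1p(-p))))
        assert fit.loglik >= gen_ll - 1e-6

    def test_order_invariance(self, rng):
        trials = logistic_trials(700.0, 0.01, 0.0, 120, rng)
        f1 = fit_psychometric(trials, "logistic", seed=0)
        f2 = fit_psychometric(trials[::-1], "logistic", seed=0)
        # invariant up to floating-point summation order in the likelihood
        assert f1.params["alpha"] == pytest.approx(f2.params["alpha"], abs=0.01)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)

    def test_separation_flagged(self):
        # perfect step at 700 ms: slope runs to its bound
        x = np.concatenate([np.linspace(400, 699, 20), np.linspace(701, 1000, 20)])
        trials = [(xi, int(xi > 700)) for xi in x]
        try:
            fit = fit_psychometric(trials, "logistic")
        except FitFailureError:
            return
        assert "slope-at-bound" in fit.flags

    def test_aic_definition(self, rng):
        trials = logistic_trials(700.0, 0.01, 0.0, 100, rng)
        fit = fit_psychometric(trials, "logistic")
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.loglik)
        lapse_fit = fit_psychometric(trials, "logistic+lapse")
        assert lapse_fit.aic == pytest.approx(2 * 3 - 2 * lapse_fit.loglik)


class TestDegenerateData:
    def test_too_few_trials(self):
        with pytest.raises(DegenerateDataError):
            fit_psychometric([(500.0, 0), (900.0, 1)] * 3, "logistic")

    def test_single_category(self):
        with pytest.raises(DegenerateDataError):
            fit_psychometric([(500.0 + i, 1) for i in range(40)], "logistic")

    def test_empty(self):
        with pytest.raises(DegenerateDataError):
            fit_psychometric([], "logistic")

    def test_unknown_variant(self, rng):
        trials = logistic_trials(700.0, 0.01, 0.0, 40, rng)
        with pytest.raises(ValueError):
            fit_psychometric(trials, "weibull")


class TestPseJnd:
    def test_pse_is_alpha(self, rng):
        trials = logistic_trials(629.0, 0.012, 0.0, 200, rng, lo=350, hi=950)
        fit = fit_psychometric(trials, "logistic")
        assert pse_of(fit) == fit.params["alpha"]

    def test_pse_unchanged_by_lapse(self, rng):
        trials = logistic_trials(700.0, 0.01, 0.08, 240, rng)
        fit = fit_psychometric(trials, "logistic+lapse")
        assert pse_of(fit) == fit.params["alpha"]

    def test_jnd_closed_form(self, rng):
        trials = logistic_trials(700.0, 0.01, 0.0, 100, rng)
        fit = fit_psychometric(trials, "logistic")
        assert jnd_of(fit) == pytest.approx(LN3 / fit.params["beta"], rel=1e-12)

    def test_jnd_at_beta_001(self):
        assert LN3 / 0.01 == pytest.approx(109.86, abs=0.01)

    def test_jnd_halves_when_beta_doubles(self, rng):
        trials = logistic_trials(700.0, 0.01, 0.0, 100, rng)
        fit = fit_psychometric(trials, "logistic")
        fit2 = fit_psychometric(trials, "logistic")
        fit2.params["beta"] = fit.params["beta"] * 2
        assert jnd_of(fit2) == pytest.approx(jnd_of(fit) / 2)

    def test_gamma_pse_matches_logistic_on_symmetric_data(self):
        # symmetric (normal-CDF) generative curve: both temporal medians agree
        from scipy.stats import norm

        rng = np.random.default_rng(3)
        x = rng.uniform(400.0, 1000.0, 4000)
        p = norm.cdf(x, 700.0, 90.0)
        trials = list(zip(x, (rng.random(x.size) < p).astype(int)))
        f_log = fit_psychometric(trials, "logistic", seed=1)
        f_gam = fit_psychometric(trials, "gamma+nontemporal", seed=1)
        assert pse_of(f_gam) == pytest.approx(pse_of(f_log), abs=5.0)


class TestModelSelection:
    def test_lapse_detected_by_aic(self):
        """Generative lapse 0.1: lapse variant wins AIC in the majority of runs.

        Constant-stimuli design with asymptote coverage, where the lapse
        is statistically separable from a shallower slope."""
        levels = np.repeat(np.array([250.0, 400.0, 550.0, 700.0, 850.0, 1000.0, 1150.0]), 34)
        wins = 0
        n_runs = 60
        for seed in range(n_runs):
            rng = np.random.default_rng(1000 + seed)
            p = 0.05 + 0.9 * expit((levels - 700.0) * 0.02)
            trials = list(zip(levels, (rng.random(levels.size) < p).astype(int)))
            f0 = fit_psychometric(trials, "logistic", n_starts=3, seed=seed)
            f1 = fit_psychometric(trials, "logistic+lapse", n_starts=3, seed=seed)
            wins += f1.aic < f0.aic
        assert wins > n_runs / 2

    def test_parsimony_no_lapse(self):
        """Generative lapse 0: plain logistic wins or ties within dAIC 2 >= 70%."""
        ok = 0
        n_runs = 40
        for seed in range(n_runs):
            rng = np.random.default_rng(2000 + seed)
            trials = logistic_trials(700.0, 0.012, 0.0, 240, rng, lo=350, hi=1050)
            table = compare_variants(trials, variants=VARIANTS, n_starts=2, seed=seed)
            row = table[table["model_variant"] == "logistic"].iloc[0]
            ok += row["delta_aic"] <= 2.0 or row.name == 0
        assert ok >= 0.7 * n_runs

    def test_mixture_recovers_nontemporal_weight(self):
        """p_nt recovered within +-0.05 (median) from the mixture's own model.

        A symmetric coin-flip lapse cannot be represented by the 0-to-1
        non-temporal CDF, so recovery is checked self-consistently."""
        from timeavg.fitting import _nt_prob

        errs = []
        for seed in range(100):
            rng = np.random.default_rng(3000 + seed)
            x = rng.uniform(250.0, 1150.0, 240)
            f = expit((x - 700.0) * 0.02)
            p = 0.1 * _nt_prob(x, 1.5, 250.0, 1150.0) + 0.9 * f
            trials = list(zip(x, (rng.random(240) < p).astype(int)))
            fit = fit_psychometric(trials, "logistic+nontemporal", n_starts=3, seed=seed)
            errs.append(fit.params["p_nt"] - 0.1)
        assert abs(np.median(errs)) < 0.05

    def test_lapse_variant_recovers_coinflip_lapse(self):
        """The lapse parameter itself recovers a generative coin-flip lapse."""
        levels = np.repeat(np.array([250.0, 400.0, 550.0, 700.0, 850.0, 1000.0, 1150.0]), 34)
        errs = []
        for seed in range(40):
            rng = np.random.default_rng(7000 + seed)
            p = 0.05 + 0.9 * expit((levels - 700.0) * 0.02)
            trials = list(zip(levels, (rng.random(levels.size) < p).astype(int)))
            fit = fit_psychometric(trials, "logistic+lapse", n_starts=3, seed=seed)
            errs.append(fit.params["lam"] - 0.1)
        assert abs(np.median(errs)) < 0.05


class TestCompareVariants:
    def test_deterministic(self, rng):
        trials = logistic_trials(700.0, 0.01, 0.05, 240, rng)
        t1 = compare_variants(trials, seed=5)
        t2 = compare_variants(trials, seed=5)
        assert t1["aic"].tolist() == t2["aic"].tolist()
        assert t1["model_variant"].tolist() == t2["model_variant"].tolist()

    def test_ranked_by_aic(self, rng):
        trials = logistic_trials(700.0, 0.01, 0.0, 240, rng)
        table = compare_variants(trials)
        aics = table["aic"].dropna()
        assert aics.is_monotonic_increasing
        assert table["delta_aic"].iloc[0] == pytest.approx(0.0)

    def test_partial_failure_reported(self):
        # step data: some variants may fail; the table still carries 4 rows
        x = np.concatenate([np.linspace(400, 699, 30), np.linspace(701, 1000, 30)])
        trials = [(xi, int(xi > 700)) for xi in x]
        table = compare_variants(trials)
        assert len(table) == len(VARIANTS)
        assert set(table["model_variant"]) == set(VARIANTS)


class TestFitObservers:
    def test_tidy_output(self, rng):
        import pandas as pd

        rows = []
        for obs_id in ("a", "b"):
            for set_id in ("set1", "set2"):
                for x, r in logistic_trials(700.0, 0.01, 0.0, 60, rng):
                    rows.append(
                        {"observer_id": obs_id, "set_id": set_id,
                         "comparison_ms": x, "response": r}
                    )
        fits = fit_observers(pd.DataFrame(rows))
        assert len(fits) == 4
        assert fits["error"].isna().all()
        assert (fits["jnd"] > 0).all()
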