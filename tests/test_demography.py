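import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from sagecort.demography import (BernoulliRegression, KnownFateSurvival,
                                 ZIPRegression, fit_binary_component,
                                 fit_fledging, known_fate_loglik,
                                 validate_histories, zip_logpmf)
from sagecort.seasons import season_of_date
from sagecort.synthetic import (SyntheticConfig, SurvivalTruth, generate,
                                simulate_zip_outcomes, FledgingTruth)
from datetime import date, timedelta

FAST_MCMC = dict(n_chains=2, n_walkers=16, n_burn=200, n_steps=150)


def _history(bird_id, states, start=date(2015, 3, 1)):
    return pd.DataFrame({
        "bird_id": bird_id,
        "week": range(1, len(states) + 1),
        "date": [(start + timedelta(days=7 * t)).isoformat()
                 for t in range(len(states))],
        "state": states,
    })


def _birds(bird_ids, cort, age):
    return pd.DataFrame({"bird_id": bird_ids, "fcort_pg_mm": cort, "age": age})


class TestKnownFateLoglik:
    def test_two_weeks_then_censored(self):
        enc = _history("b1", ["alive", "alive", "censored"])
        birds = _birds(["b1"], [0.0], [0])
        ll = known_fate_loglik(enc, birds, np.zeros(6))
        assert ll == pytest.approx(2 * np.log(0.5))

    def test_death_in_week_one(self):
        enc = _history("b1", ["dead"])
        birds = _birds(["b1"], [0.0], [0])
        assert known_fate_loglik(enc, birds, np.zeros(6)) == \
            pytest.approx(np.log(0.5))

    def test_matches_bernoulli_product_oracle(self, rng):
        """Independent per-week Bernoulli product on 50 random tiny
        histories, random coefficients, agreement to 1e-10."""
        coefs = rng.normal(0, 0.5, 6)
        coefs[1] = rng.normal(0, 0.01)  # cort slope on raw scale
        frames, birds_rows, oracle = [], [], 0.0
        start = date(2015, 3, 1)
        for i in range(50):
            n_weeks = int(rng.integers(1, 9))
            final = rng.choice(["alive", "dead", "censored"])
            states = ["alive"] * (n_weeks - 1) + [final]
            bid = f"b{i}"
            frames.append(_history(bid, states, start))
            cort, age = float(rng.integers(0, 200)), int(rng.integers(0, 2))
            birds_rows.append((bid, cort, age))
            for t, state in enumerate(states, start=1):
                d = start + timedelta(days=7 * (t - 1))
                season = season_of_date(d)
                x = np.array([1.0, cort, age,
                              season == "spring", season == "summer",
                              season == "fall"], dtype=float)
                s = 1 / (1 + np.exp(-(x @ coefs)))
                if state == "alive":
                    oracle += np.log(s)
                elif state == "dead":
                    oracle += np.log(1 - s)
        enc = pd.concat(frames, ignore_index=True)
        birds = pd.DataFrame(birds_rows,
                             columns=["bird_id", "fcort_pg_mm", "age"])
        assert known_fate_loglik(enc, birds, coefs) == pytest.approx(
            oracle, abs=1e-10)

    def test_additive_over_birds(self, rng):
        enc1 = _history("b1", ["alive", "dead"])
        enc2 = _history("b2", ["alive", "alive", "censored"])
        birds = _birds(["b1", "b2"], [10.0, 50.0], [0, 1])
        coefs = rng.normal(0, 0.3, 6)
        both = known_fate_loglik(pd.concat([enc1, enc2]), birds, coefs)
        solo = known_fate_loglik(enc1, birds, coefs) + \
            known_fate_loglik(enc2, birds, coefs)
        assert both == pytest.approx(solo, abs=1e-12)

    def test_grammar_violation_names_bird(self):
        enc = _history("bad1", ["dead", "alive"])
        with pytest.raises(ValueError, match="bad1"):
            known_fate_loglik(enc, _birds(["bad1"], [0.0], [0]), np.zeros(6))

    def test_validate_rejects_unknown_state(self):
        enc = _history("b1", ["alive", "vanished"])
        with pytest.raises(ValueError, match="unknown"):
            validate_histories(enc)


class TestSurvivalFit:
    def test_cort_slope_recovery(self):
        d = generate(SyntheticConfig(n_birds=1500, seed=31))
        m = KnownFateSurvival(random_state=5).fit(d.encounters, d.birds)
        row = m.cort_row()
        truth = d.config.survival.cort
        assert abs(row.estimate - truth) < 2.5 * row.sd
        assert m.convergence_["ok"] or max(m.convergence_["rhat"].values()) < 1.05

    def test_null_season_offsets_covered(self):
        cfg = SyntheticConfig(
            n_birds=800, seed=32,
            survival=SurvivalTruth(intercept=3.5, cort=0.0, age=0.0,
                                   spring=0.0, summer=0.0, fall=0.0))
        d = generate(cfg)
        m = KnownFateSurvival(random_state=6).fit(d.encounters, d.birds)
        tab = m.summary_.set_index("term")
        for term in ("spring", "summer", "fall"):
            assert tab.loc[term, "lci"] <= 0 <= tab.loc[term, "uci"]

    def test_implied_annual_survival_matches_simulation(self):
        cfg = SyntheticConfig(n_birds=2500, seed=33)
        d = generate(cfg)
        m = KnownFateSurvival(random_state=7).fit(d.encounters, d.birds)
        # model-implied annual survival, averaged over birds
        implied = np.mean([
            m.annual_survival(c, a) for c, a in
            zip(d.birds.fcort_pg_mm[:400], d.birds.age[:400])])
        empirical = d.breeding.fate.eq("alive").mean()
        assert implied == pytest.approx(empirical, abs=0.04)

    def test_no_deaths_warns(self):
        enc = pd.concat([_history(f"b{i}", ["alive"] * 5 + ["censored"])
                         for i in range(8)], ignore_index=True)
        birds = _birds([f"b{i}" for i in range(8)], np.zeros(8), np.zeros(8))
        with pytest.warns(UserWarning, match="mortality"):
            KnownFateSurvival(random_state=1, **FAST_MCMC).fit(enc, birds)


class TestBinaryComponents:
    def test_intercept_only_logit_recovery(self, rng):
        y = (rng.uniform(size=3000) < 0.7).astype(float)
        m = BernoulliRegression(random_state=2, **FAST_MCMC) \
            .fit(np.zeros((3000, 0)), y)
        assert m.coef_[0] == pytest.approx(logit(y.mean()), abs=0.1)

    def test_permuted_cort_covers_zero(self):
        d = generate(SyntheticConfig(n_birds=1000, seed=41))
        rng = np.random.default_rng(0)
        shuffled = d.birds.copy()
        shuffled["fcort_pg_mm"] = rng.permutation(shuffled["fcort_pg_mm"].values)
        m = fit_binary_component(d.breeding, shuffled, "ns", seed=3)
        row = m.cort_row()
        assert row.lci <= 0 <= row.uci

    def test_nest_success_slope_recovery(self):
        d = generate(SyntheticConfig(n_birds=2000, seed=42))
        m = fit_binary_component(d.breeding, d.birds, "ns", seed=4)
        row = m.cort_row()
        truth = d.config.nest_success.cort
        assert abs(row.estimate - truth) < 2.5 * row.sd

    def test_risk_set_codings_differ(self):
        d = generate(SyntheticConfig(n_birds=600, seed=43))
        nesters = fit_binary_component(d.breeding, d.birds, "ns", seed=5,
                                       **FAST_MCMC)
        all_birds = fit_binary_component(d.breeding, d.birds, "ns", seed=5,
                                         nesters_only=False, **FAST_MCMC)
        n_nesters = int((d.breeding.ybp == 1).sum())
        n_all = int(d.breeding.ybp.notna().sum())
        assert n_nesters < n_all
        # the unconditional coding mixes propensity into the intercept
        assert all_birds.coef_[0] < nesters.coef_[0]

    def test_separation_warns(self):
        X = np.zeros((20, 0))
        with pytest.warns(UserWarning, match="separation"):
            BernoulliRegression(random_state=1, **FAST_MCMC).fit(X, np.ones(20))


class TestFledging:
    def test_zip_pmf_normalizes(self, rng):
        k = np.arange(0, 1001)
        for _ in range(100):
            p = rng.uniform(0.01, 0.99)
            mu = rng.uniform(0.05, 20)
            total = np.exp(zip_logpmf(k, p, mu)).sum()
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_pure_poisson_collapse(self, rng):
        lam = 2.0
        y = rng.poisson(lam, size=4000)
        m = ZIPRegression(random_state=3).fit(np.zeros((4000, 0)), y)
        draws = m.draws_
        p_bs = 1 / (1 + np.exp(-draws[:, 0]))
        mu = np.exp(draws[:, 1])
        implied_mean = (p_bs * mu).mean()
        assert implied_mean == pytest.approx(y.mean(), rel=0.05)
        implied_p0 = (1 - p_bs + p_bs * np.exp(-mu)).mean()
        assert implied_p0 == pytest.approx((y == 0).mean(), abs=0.03)

    def test_slope_recovery_from_exact_zip(self, rng):
        n = 2000
        cort = rng.negative_binomial(0.142, 0.142 / (0.142 + 43.8), size=n)
        age = (rng.uniform(size=n) < 0.7).astype(float)
        truth = FledgingTruth()
        out = simulate_zip_outcomes(cort, age, truth, rng)
        X = pd.DataFrame({"cort": cort, "age": age})
        m = ZIPRegression(random_state=4).fit(X, out.yf)
        tab = m.summary_.set_index("term")
        assert abs(tab.loc["bs_cort", "estimate"] - truth.bs_cort) \
            < 2.5 * tab.loc["bs_cort", "sd"]
        assert abs(tab.loc["mu_intercept", "estimate"] - truth.mu_intercept) \
            < 2.5 * tab.loc["mu_intercept", "sd"]

    def test_inconsistent_breeding_success_rejected(self):
        outcomes = pd.DataFrame({
            "bird_id": ["b0", "b1"], "ybp": [1.0, 1.0], "yns": [1.0, 1.0],
            "ybs": [0.0, 1.0], "yf": [2.0, 1.0]})
        birds = _birds(["b0", "b1"], [5.0, 9.0], [1, 0])
        with pytest.raises(ValueError, match="ybs"):
            fit_fledging(outcomes, birds)
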