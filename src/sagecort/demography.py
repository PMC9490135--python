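"""Effects of feather corticosterone on vital rates.

Four Bayesian models link fCort (raw pg/mm scale) and age to demographic
rates in the year after feather sampling:

* weekly known-fate survival with seasonal offsets (winter intercept),
  ``logit s_it = b0 + b_cort cort_i + b_age age_i + b_season[t]``;
* Bernoulli breeding propensity and nest success,
  ``logit p_i = b0 + b_cort cort_i + b_age age_i``;
* zero-inflated Poisson fledged-chick counts, where the zero-inflation
  probability (overall breeding success) and the Poisson mean are each
  logit-/log-linear in (cort, age).

Priors default to normal(0, 10) on intercepts and normal(0, 1) on slopes.
All posteriors are summarized through the shared coefficient-table code.
"""

from __future__ import annotations

import warnings
from datetime import date

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from ._mcmc import MCMCConfig, find_map, sample_posterior
from .posterior import summarize
from .seasons import N_WEEKS, season_of_date, week_seasons

__all__ = [
    "SURVIVAL_TERMS",
    "BINARY_TERMS",
    "ZIP_TERMS",
    "validate_histories",
    "known_fate_loglik",
    "zip_logpmf",
    "KnownFateSurvival",
    "BernoulliRegression",
    "ZIPRegression",
    "fit_survival",
    "fit_binary_component",
    "fit_fledging",
]

SURVIVAL_TERMS = ("intercept", "cort", "age", "spring", "summer", "fall")
BINARY_TERMS = ("intercept", "cort", "age")
ZIP_TERMS = ("bs_intercept", "bs_cort", "bs_age",
             "mu_intercept", "mu_cort", "mu_age")

INTERCEPT_PRIOR_VAR = 10.0
SLOPE_PRIOR_VAR = 1.0


# ---------------------------------------------------------------------------
# encounter histories


def validate_histories(encounters: pd.DataFrame) -> None:
    """Check the weekly state grammar: alive* (dead | censored)?.

    Weeks must be consecutive from 1 with no records after a terminal
    state.  Raises with the offending bird_id.
    """
    for col in ("bird_id", "week", "state"):
        if col not in encounters.columns:
            raise ValueError(f"encounters missing column {col!r}")
    bad_states = set(encounters["state"]) - {"alive", "dead", "censored"}
    if bad_states:
        raise ValueError(f"unknown states: {sorted(bad_states)}")
    for bird, grp in encounters.groupby("bird_id", sort=False):
        weeks = grp["week"].to_numpy()
        states = grp["state"].tolist()
        if not np.array_equal(weeks, np.arange(1, len(weeks) + 1)):
            raise ValueError(f"bird {bird}: weeks not consecutive from 1")
        if any(s != "alive" for s in states[:-1]):
            raise ValueError(f"bird {bird}: record after terminal state")


def _survival_rows(encounters: pd.DataFrame, birds: pd.DataFrame):
    """Per observed bird-week: (cort, age, season, survived)."""
    need = {"bird_id", "fcort_pg_mm", "age"}
    if not need <= set(birds.columns):
        raise ValueError(f"birds table must have columns {sorted(need)}")
    enc = encounters[encounters["week"] <= N_WEEKS]
    enc = enc[enc["state"] != "censored"]  # censored week contributes nothing
    merged = enc.merge(birds[["bird_id", "fcort_pg_mm", "age"]],
                       on="bird_id", how="left", validate="many_to_one")
    if merged["fcort_pg_mm"].isna().any():
        missing = merged.loc[merged["fcort_pg_mm"].isna(), "bird_id"].unique()
        raise ValueError(f"no covariates for bird(s): {list(missing)[:5]}")
    season = merged["date"].map(lambda d: season_of_date(date.fromisoformat(d)))
    return pd.DataFrame({
        "cort": merged["fcort_pg_mm"].astype(float),
        "age": merged["age"].astype(float),
        "season": season,
        "survived": (merged["state"] == "alive").astype(int),
    })


def _season_columns(season_labels) -> np.ndarray:
    return np.column_stack([
        (np.asarray(season_labels) == s).astype(float)
        for s in ("spring", "summer", "fall")
    ])


def known_fate_loglik(encounters: pd.DataFrame, birds: pd.DataFrame,
                      coefs) -> float:
    """Known-fate weekly binomial log likelihood.

    Every recorded alive week contributes ``log s``, a death week
    ``log(1 - s)``; a censored terminal week contributes nothing; weeks
    beyond the first year are excluded.  ``coefs`` is (intercept, cort,
    age, spring, summer, fall) on the logit scale.
    """
    validate_histories(encounters)
    coefs = np.asarray(coefs, dtype=float)
    if coefs.shape != (6,):
        raise ValueError("coefs must be the 6-vector "
                         "(intercept, cort, age, spring, summer, fall)")
    rows = _survival_rows(encounters, birds)
    X = np.column_stack([
        np.ones(len(rows)), rows["cort"], rows["age"],
        _season_columns(rows["season"]),
    ])
    eta = X @ coefs
    log_s = -np.logaddexp(0.0, -eta)
    log_1ms = -np.logaddexp(0.0, eta)
    surv = rows["survived"].to_numpy()
    return float(np.sum(surv * log_s + (1 - surv) * log_1ms))


# ---------------------------------------------------------------------------
# shared Bernoulli machinery


def _binomial_logpost_vec(G, n_succ, n_fail, prior_prec):
    """Vectorized log posterior for grouped Bernoulli data.

    G: (g, p) unique design rows; counts n_succ/n_fail per row.
    """
    def log_post(theta):
        theta = np.atleast_2d(theta)
        eta = G @ theta.T                           # (g, m)
        ll = (n_succ[:, None] * (-np.logaddexp(0.0, -eta))
              + n_fail[:, None] * (-np.logaddexp(0.0, eta))).sum(axis=0)
        lp = ll - 0.5 * (theta ** 2 * prior_prec[None, :]).sum(axis=1)
        return lp if lp.size > 1 else lp
    return log_post


def _group_binomial(X, y):
    """Collapse replicate design rows into (G, n_succ, n_fail)."""
    Xr = np.ascontiguousarray(X)
    key = Xr.view([("", Xr.dtype)] * Xr.shape[1]).ravel()
    uniq, inv = np.unique(key, return_inverse=True)
    g = len(uniq)
    n_succ = np.bincount(inv, weights=y, minlength=g)
    n_tot = np.bincount(inv, minlength=g).astype(float)
    G = np.empty((g, Xr.shape[1]))
    G[inv] = Xr
    return G, n_succ, n_tot - n_succ


class _BayesGLMBase(BaseEstimator):
    """Common fit plumbing: MAP init + ensemble sampling + summary table."""

    def __init__(self, intercept_prior_var=INTERCEPT_PRIOR_VAR,
                 slope_prior_var=SLOPE_PRIOR_VAR, n_chains=3, n_walkers=24,
                 n_burn=500, n_steps=500, thin=1, random_state=0):
        self.intercept_prior_var = intercept_prior_var
        self.slope_prior_var = slope_prior_var
        self.n_chains = n_chains
        self.n_walkers = n_walkers
        self.n_burn = n_burn
        self.n_steps = n_steps
        self.thin = thin
        self.random_state = random_state

    def _mcmc_config(self):
        return MCMCConfig(n_chains=self.n_chains, n_walkers=self.n_walkers,
                          n_burn=self.n_burn, n_steps=self.n_steps,
                          thin=self.thin)

    def _sample(self, log_post, ndim, x0, names):
        x_map = find_map(lambda t: float(np.atleast_1d(log_post(t[None, :]))[0]),
                         x0)
        sample = sample_posterior(log_post, ndim, x_map,
                                  config=self._mcmc_config(),
                                  seed=self.random_state, param_names=names)
        self.posterior_ = sample
        self.draws_ = sample.flat()
        self.coef_draws_ = self.draws_
        self.coef_ = self.draws_.mean(axis=0)
        self.term_names_ = list(names)
        self.summary_ = summarize(self.draws_, names)
        self.convergence_ = sample.convergence
        return self

    def cort_row(self) -> pd.Series:
        """The fCort coefficient row of the summary table."""
        tab = self.summary_
        mask = tab["term"].str.endswith("cort")
        return tab[mask].iloc[0]


class KnownFateSurvival(_BayesGLMBase):
    """Bayesian known-fate weekly survival model with seasonal offsets.

    ``fit(encounters, birds)`` takes the weekly encounter table
    (bird_id, week, date, state) and per-bird covariates
    (bird_id, fcort_pg_mm, age).  Winter is the intercept season.

    Attributes: ``coef_`` (posterior means in SURVIVAL_TERMS order),
    ``summary_``, ``convergence_``, ``draws_``.
    """

    def fit(self, encounters: pd.DataFrame, birds: pd.DataFrame):
        validate_histories(encounters)
        rows = _survival_rows(encounters, birds)
        if (rows["survived"] == 1).all():
            warnings.warn("no mortality events: survival likelihood is flat "
                          "in some directions", stacklevel=2)
        X = np.column_stack([
            np.ones(len(rows)), rows["cort"], rows["age"],
            _season_columns(rows["season"]),
        ])
        G, n_succ, n_fail = _group_binomial(X, rows["survived"].to_numpy(float))
        prior_prec = np.array([1 / self.intercept_prior_var]
                              + [1 / self.slope_prior_var] * 5)
        log_post = _binomial_logpost_vec(G, n_succ, n_fail, prior_prec)
        x0 = np.array([3.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        return self._sample(log_post, 6, x0, SURVIVAL_TERMS)

    def weekly_survival(self, cort, age, start=date(2015, 3, 1)) -> np.ndarray:
        """Posterior-mean weekly survival over the 52-week calendar."""
        b = self.coef_
        seas = _season_columns(week_seasons(start, N_WEEKS))
        eta = b[0] + b[1] * cort + b[2] * age + seas @ b[3:6]
        return 1.0 / (1.0 + np.exp(-eta))

    def annual_survival(self, cort, age, start=date(2015, 3, 1)) -> float:
        """Implied first-year survival at given covariates."""
        return float(np.prod(self.weekly_survival(cort, age, start)))


class BernoulliRegression(_BayesGLMBase):
    """Bayesian logistic regression for a binary recruitment component."""

    def fit(self, X, y):
        Xm = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) \
            else np.asarray(X, dtype=float)
        yv = np.asarray(y, dtype=float)
        if set(np.unique(yv)) - {0.0, 1.0}:
            raise ValueError("y must be binary 0/1")
        self.separation_warning_ = False
        if yv.min() == yv.max():
            self.separation_warning_ = True
            warnings.warn("all outcomes identical: complete separation, "
                          "posterior driven by the prior", stacklevel=2)
        Xd = np.column_stack([np.ones(len(Xm)), Xm])
        G, n_succ, n_fail = _group_binomial(Xd, yv)
        p = Xd.shape[1]
        prior_prec = np.array([1 / self.intercept_prior_var]
                              + [1 / self.slope_prior_var] * (p - 1))
        log_post = _binomial_logpost_vec(G, n_succ, n_fail, prior_prec)
        names = BINARY_TERMS if p == 3 else \
            ("intercept",) + tuple(f"x{i}" for i in range(1, p))
        return self._sample(log_post, p, np.zeros(p), names)

    def predict_proba(self, X):
        Xm = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) \
            else np.asarray(X, dtype=float)
        eta = self.coef_[0] + Xm @ self.coef_[1:]
        return 1.0 / (1.0 + np.exp(-eta))


def zip_logpmf(k, p_bs, mu):
    """Zero-inflated Poisson log pmf.

    ``P(0) = (1 - p_bs) + p_bs e^{-mu}``;
    ``P(k>0) = p_bs mu^k e^{-mu} / k!``.  Inputs broadcast.
    """
    k = np.asarray(k, dtype=float)
    p = np.asarray(p_bs, dtype=float)
    mu_a = np.asarray(mu, dtype=float)
    if np.any(k < 0) or not np.allclose(k, np.round(k)):
        raise ValueError("k must be non-negative integers")
    if np.any((p < 0) | (p > 1)) or np.any(mu_a <= 0):
        raise ValueError("need 0 <= p_bs <= 1 and mu > 0")
    with np.errstate(divide="ignore"):
        log_zero = np.logaddexp(np.log1p(-p), np.log(p) - mu_a)
        log_pos = np.log(p) + k * np.log(mu_a) - mu_a - gammaln(k + 1.0)
    return np.where(k == 0, log_zero, log_pos)


class ZIPRegression(_BayesGLMBase):
    """Zero-inflated Poisson model of fledged-chick counts.

    The zero-inflation probability (breeding success) is logit-linear and
    the Poisson mean log-linear, each in (cort, age).  ``fit(X, y)`` takes
    the 2-column (cort, age) matrix and the fledged counts.
    """

    def fit(self, X, y):
        Xm = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) \
            else np.asarray(X, dtype=float)
        yv = np.asarray(y, dtype=float)
        if np.any(yv < 0) or not np.allclose(yv, np.round(yv)):
            raise ValueError("fledged counts must be non-negative integers")
        Xd = np.column_stack([np.ones(len(Xm)), Xm])
        p = Xd.shape[1]
        zero = yv == 0
        k_pos = yv[~zero]
        X_pos, X_zero = Xd[~zero], Xd[zero]
        lgam = gammaln(k_pos + 1.0)
        prior_prec = np.concatenate([
            [1 / self.intercept_prior_var], np.full(p - 1, 1 / self.slope_prior_var),
            [1 / self.intercept_prior_var], np.full(p - 1, 1 / self.slope_prior_var),
        ])

        def log_post(theta):
            theta = np.atleast_2d(theta)
            tb, tm = theta[:, :p], theta[:, p:]
            eta_b_pos, eta_b_zero = X_pos @ tb.T, X_zero @ tb.T
            eta_m_pos = np.clip(X_pos @ tm.T, -40, 40)
            eta_m_zero = np.clip(X_zero @ tm.T, -40, 40)
            mu_pos, mu_zero = np.exp(eta_m_pos), np.exp(eta_m_zero)
            log_p_pos = -np.logaddexp(0.0, -eta_b_pos)
            ll_pos = (log_p_pos + k_pos[:, None] * eta_m_pos - mu_pos
                      - lgam[:, None]).sum(axis=0)
            log_p0 = -np.logaddexp(0.0, -eta_b_zero)
            log_1mp0 = -np.logaddexp(0.0, eta_b_zero)
            ll_zero = np.logaddexp(log_1mp0, log_p0 - mu_zero).sum(axis=0)
            return (ll_pos + ll_zero
                    - 0.5 * (theta ** 2 * prior_prec[None, :]).sum(axis=1))

        names = ZIP_TERMS if p == 3 else tuple(
            f"{part}{i}" for part in ("bs", "mu") for i in range(p))
        x0 = np.zeros(2 * p)
        x0[p] = np.log(max(yv[yv > 0].mean(), 0.5)) if (yv > 0).any() else 0.0
        return self._sample(log_post, 2 * p, x0, names)


# ---------------------------------------------------------------------------
# operation wrappers


def _merge_outcomes(outcomes: pd.DataFrame, birds: pd.DataFrame) -> pd.DataFrame:
    cols = ["bird_id", "fcort_pg_mm", "age"]
    return outcomes.merge(birds[cols], on="bird_id", validate="one_to_one")


def fit_survival(encounters, birds, seed: int = 0, **kwargs) -> KnownFateSurvival:
    """Fit the known-fate weekly survival model."""
    return KnownFateSurvival(random_state=seed, **kwargs).fit(encounters, birds)


def fit_binary_component(outcomes, birds, component: str, seed: int = 0,
                         nesters_only: bool = True, **kwargs) -> BernoulliRegression:
    """Fit breeding propensity (``"bp"``) or nest success (``"ns"``).

    Nest success defaults to the nesters-only risk set (birds with
    ybp == 1); pass ``nesters_only=False`` for the all-birds coding where
    non-nesters count as failures.
    """
    if component not in {"bp", "ns"}:
        raise ValueError("component must be 'bp' or 'ns'")
    df = _merge_outcomes(outcomes, birds)
    if component == "bp":
        df = df[df["ybp"].notna()]
        y = df["ybp"]
    else:
        if nesters_only:
            df = df[(df["ybp"] == 1) & df["yns"].notna()]
        else:
            df = df[df["ybp"].notna()]
            df = df.assign(yns=df["yns"].fillna(0.0))
        y = df["yns"]
    if len(df) == 0:
        raise ValueError(f"empty risk set for component {component!r}")
    X = df[["fcort_pg_mm", "age"]]
    return BernoulliRegression(random_state=seed, **kwargs).fit(X, y)


def fit_fledging(outcomes, birds, seed: int = 0, **kwargs) -> ZIPRegression:
    """Fit the zero-inflated Poisson fledged-count model.

    Validates that no bird has a positive count with recorded breeding
    success 0.
    """
    df = _merge_outcomes(outcomes, birds)
    df = df[df["yf"].notna()]
    if "ybs" in df.columns:
        bad = df[(df["yf"] > 0) & (df["ybs"] == 0)]
        if len(bad):
            raise ValueError(
                f"yf > 0 with ybs == 0 for bird(s) {bad['bird_id'].tolist()[:5]}")
    X = df[["fcort_pg_mm", "age"]]
    return ZIPRegression(random_state=seed, **kwargs).fit(X, df["yf"])
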