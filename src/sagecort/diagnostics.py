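"""Cross-cutting diagnostics: MAPE, fold assignment, Moran's I, convergence.

These are the model-agnostic pieces of the analysis: the cross-validation
loss and partitioner used to tune prior variances, the spatial
autocorrelation check on model residuals, and MCMC convergence summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
from sklearn.model_selection import KFold

__all__ = ["FoldAssignment", "MoranResult", "mape", "kfold", "morans_i",
           "convergence_report"]

RHAT_THRESHOLD = 1.01
ESS_THRESHOLD = 400


def mape(observed, predicted) -> float:
    """Mean absolute prediction error, ``mean(|obs - pred|)``.

    On count data this is in the response units (pg/mm for fCort).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size == 0:
        raise ValueError("empty inputs")
    return float(np.mean(np.abs(obs - pred)))


@dataclass(frozen=True)
class FoldAssignment:
    """Deterministic seeded partition into k near-equal folds (labels 1..k)."""

    n: int
    k: int
    labels: np.ndarray
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.labels == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.labels != fold)


def kfold(n: int, k: int, seed: int = 0) -> FoldAssignment:
    """Seeded uniform-random partition of ``range(n)`` into ``k`` folds.

    Fold sizes differ by at most one; the same (n, k, seed) always yields
    the same labels.
    """
    if k < 2:
        raise ValueError(f"need k >= 2 folds, got {k}")
    if n < k:
        raise ValueError(f"cannot split n={n} records into k={k} folds")
    labels = np.empty(n, dtype=int)
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(splitter.split(np.empty((n, 1))), start=1):
        labels[test_idx] = fold
    return FoldAssignment(n=n, k=k, labels=labels, seed=seed)


@dataclass(frozen=True)
class MoranResult:
    """Moran's I with its permutation null distribution summaries."""

    I: float
    expected: float  # -1/(n-1)
    sd: float        # SD of the permutation distribution
    p: float         # two-sided permutation p (observed in reference set)
    n_perm: int


def _moran_weights(coords: np.ndarray) -> np.ndarray:
    """Row-standardized inverse-Euclidean-distance weights, zero diagonal."""
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    np.fill_diagonal(dist, np.inf)
    off_diag = dist[np.isfinite(dist)]
    zero_pairs = off_diag == 0
    if zero_pairs.any():
        floor = off_diag[off_diag > 0].min() if (off_diag > 0).any() else 1.0
        warnings.warn(
            "duplicate coordinates: applying pairwise distance floor "
            f"{floor:g}", stacklevel=3)
        dist[dist == 0] = floor
    w = 1.0 / dist
    np.fill_diagonal(w, 0.0)
    w /= w.sum(axis=1, keepdims=True)
    return w


def _moran_stat(x: np.ndarray, w: np.ndarray) -> float:
    n = x.size
    z = x - x.mean()
    denom = float(z @ z)
    W = w.sum()
    return float(n / W * (z @ w @ z) / denom)


def morans_i(values, coords, n_perm: int = 9999, seed: int = 0) -> MoranResult:
    """Moran's I of ``values`` at ``coords`` with a permutation test.

    Weights are inverse Euclidean distance, row-standardized.  The null is
    built by shuffling values over the fixed coordinates; the two-sided p
    counts permutations at least as far from the -1/(n-1) expectation as
    the observed statistic, with the observed value in the reference set.
    """
    x = np.asarray(values, dtype=float)
    c = np.asarray(coords, dtype=float)
    if c.ndim != 2 or c.shape[0] != x.size:
        raise ValueError("coords must be (n, d) aligned with values")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 observations, got {n}")
    if np.all(x == x[0]):
        raise ValueError("constant residuals: Moran's I undefined")
    w = _moran_weights(c)
    i_obs = _moran_stat(x, w)
    expected = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    xs = x.copy()
    for j in range(n_perm):
        rng.shuffle(xs)
        perm[j] = _moran_stat(xs, w)
    sd = float(perm.std(ddof=1))
    extreme = np.abs(perm - expected) >= np.abs(i_obs - expected)
    p = float((extreme.sum() + 1) / (n_perm + 1))
    return MoranResult(I=i_obs, expected=expected, sd=sd, p=p, n_perm=n_perm)


def convergence_report(chains: np.ndarray, param_names=None) -> dict:
    """Split-R-hat and bulk ESS per parameter, with pass/warn flags.

    Parameters
    ----------
    chains : array (n_chains, n_draws, ndim).  With a single chain R-hat is
        undefined (reported as NaN) but ESS is still computed.

    Returns
    -------
    dict with per-parameter ``rhat`` and ``ess`` plus an overall ``ok``
    flag (all R-hat <= 1.01 and ESS >= 400) and a list of ``warnings``.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 3:
        raise ValueError("chains must be (n_chains, n_draws, ndim)")
    n_chains, _, ndim = chains.shape
    names = list(param_names) if param_names is not None \
        else [f"p{i}" for i in range(ndim)]
    rhat = {}
    ess = {}
    warns = []
    for i, name in enumerate(names):
        arr = chains[:, :, i]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess_val = float(az.ess(az.convert_to_dataset(arr))["x"].values)
            if n_chains >= 2:
                rhat_val = float(az.rhat(az.convert_to_dataset(arr))["x"].values)
            else:
                rhat_val = float("nan")
        rhat[name] = rhat_val
        ess[name] = ess_val
        if np.isfinite(rhat_val) and rhat_val > RHAT_THRESHOLD:
            warns.append(f"{name}: R-hat {rhat_val:.3f} > {RHAT_THRESHOLD}")
        if ess_val < ESS_THRESHOLD:
            warns.append(f"{name}: ESS {ess_val:.0f} < {ESS_THRESHOLD}")
    return {"rhat": rhat, "ess": ess, "ok": not warns, "warnings": warns}
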