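"""Posterior summary tables in the coefficient-table format used throughout.

Every model in the package reports its coefficients the same way: posterior
mean, posterior SD, 2.5/97.5 percentile credible bounds, and the posterior
mass below and above zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["summarize"]

SUMMARY_COLUMNS = ("term", "estimate", "sd", "lci", "uci", "pr_lt_0", "pr_gt_0")


def summarize(draws, term_names, min_draws: int = 1000) -> pd.DataFrame:
    """Summarize posterior draws into a coefficient table.

    Parameters
    ----------
    draws : array (n_draws, n_terms) of pooled posterior draws.
    term_names : column labels, one per term, in output row order.
    min_draws : minimum number of retained draws required for stable
        percentile intervals.

    Returns
    -------
    DataFrame with one row per term: posterior mean (``estimate``), SD,
    95% credible bounds (``lci``, ``uci``), and tail masses ``pr_lt_0`` /
    ``pr_gt_0``.  Draws exactly at zero are counted on the positive side
    so the two tail masses always sum to one.
    """
    d = np.asarray(draws, dtype=float)
    if d.ndim == 1:
        d = d[:, None]
    if d.shape[0] == 0:
        raise ValueError("empty posterior: no draws to summarize")
    if d.shape[0] < min_draws:
        raise ValueError(
            f"only {d.shape[0]} draws; need >= {min_draws} for stable intervals")
    names = list(term_names)
    if len(names) != d.shape[1]:
        raise ValueError(f"{len(names)} names for {d.shape[1]} columns")
    pr_lt = (d < 0).mean(axis=0)
    rows = {
        "term": names,
        "estimate": d.mean(axis=0),
        "sd": d.std(axis=0, ddof=1),
        "lci": np.percentile(d, 2.5, axis=0),
        "uci": np.percentile(d, 97.5, axis=0),
        "pr_lt_0": pr_lt,
        "pr_gt_0": 1.0 - pr_lt,
    }
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))
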