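"""Per-bird covariate construction for the feather-corticosterone analysis.

Raw field and management inputs (grazer head counts, per-location habitat
values, morphometrics) are turned into the analysis-ready design matrix:
use-days per square kilometre for horses and cows, per-bird averages over
relocation sets, a mass-residual body-condition index, z-standardized main
effects, and the three grazer x climate interaction columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "TERMS",
    "MAIN_EFFECTS",
    "CONTINUOUS_EFFECTS",
    "INTERACTIONS",
    "HORSE_DAYS_PER_YEAR",
    "compute_use_days",
    "average_covariates",
    "body_condition",
    "z_standardize",
    "DesignMatrixBuilder",
    "build_design",
]

#: Fixed model term order; defines the row order of every coefficient table.
TERMS = (
    "intercept",
    "cows",
    "horses",
    "body_condition",
    "age",
    "annual_grass",
    "precipitation",
    "horses_x_precipitation",
    "horses_x_annual_grass",
    "cows_x_precipitation",
)

MAIN_EFFECTS = ("cows", "horses", "body_condition", "age", "annual_grass", "precipitation")
#: Main effects that are z-standardized (age is a 0/1 indicator and is not).
CONTINUOUS_EFFECTS = ("cows", "horses", "body_condition", "annual_grass", "precipitation")
#: Interaction columns as products of standardized main effects.
INTERACTIONS = (
    ("horses_x_precipitation", "horses", "precipitation"),
    ("horses_x_annual_grass", "horses", "annual_grass"),
    ("cows_x_precipitation", "cows", "precipitation"),
)

#: Feral horses are on the landscape year-round, so their use-days always
#: accumulate over a full year; cow days-present are reported per allotment.
HORSE_DAYS_PER_YEAR = 365


def compute_use_days(head_count, days_present, area_km2):
    """Grazing intensity in head-days per square kilometre.

    ``head_count * days_present / area_km2``.  For horses pass
    ``days_present=HORSE_DAYS_PER_YEAR``.

    Raises
    ------
    ValueError
        If ``area_km2 <= 0`` or any count/day value is negative.
    """
    head_count = np.asarray(head_count, dtype=float)
    days_present = np.asarray(days_present, dtype=float)
    area_km2 = np.asarray(area_km2, dtype=float)
    if np.any(area_km2 <= 0):
        raise ValueError("area_km2 must be positive")
    if np.any(head_count < 0) or np.any(days_present < 0):
        raise ValueError("head_count and days_present must be non-negative")
    out = head_count * days_present / area_km2
    return float(out) if out.ndim == 0 else out


def average_covariates(locations: pd.DataFrame, value_columns=None) -> pd.DataFrame:
    """Average per-location covariate values to one row per bird.

    Because feathers are grown months before capture, a bird's exposure is
    indexed by the mean covariate value over all its relocations from the
    feather-growth year.

    Parameters
    ----------
    locations : DataFrame with a ``bird_id`` column and one row per location.
    value_columns : columns to average; default: all numeric columns except
        coordinates (``x``, ``y``) and ``year``.

    Raises
    ------
    ValueError
        If any requested bird has no locations (empty frame overall, or a
        bird_id present with only-NaN rows is not checked here).
    """
    if "bird_id" not in locations.columns:
        raise ValueError("locations must have a bird_id column")
    if len(locations) == 0:
        raise ValueError("empty location set: no locations for any bird")
    if value_columns is None:
        skip = {"bird_id", "x", "y", "year"}
        value_columns = [
            c for c in locations.columns
            if c not in skip and pd.api.types.is_numeric_dtype(locations[c])
        ]
    counts = locations.groupby("bird_id").size()
    empty = counts[counts == 0]
    if len(empty):
        raise ValueError(f"no locations for bird(s): {list(empty.index)}")
    out = locations.groupby("bird_id", sort=True)[list(value_columns)].mean().reset_index()
    return out


def body_condition(morph: pd.DataFrame) -> np.ndarray:
    """Mass-residual body condition index, in grams.

    Structural size is PC1 of (wing, tarsus), each standardized before the
    decomposition, computed on complete cases; body mass is regressed on PC1
    by OLS and the residual is the condition value.  Birds missing any of
    mass, wing, or tarsus receive the mean condition of complete cases
    (which is ~0 by the OLS zero-mean residual property).

    Parameters
    ----------
    morph : DataFrame with columns ``mass_g``, ``wing_mm``, ``tarsus_mm``
        (NaN marks missing).

    Returns
    -------
    ndarray of condition values aligned with ``morph`` rows.
    """
    required = ("mass_g", "wing_mm", "tarsus_mm")
    for c in required:
        if c not in morph.columns:
            raise ValueError(f"morphometrics missing column {c!r}")
    vals = morph[list(required)].to_numpy(dtype=float)
    complete = ~np.isnan(vals).any(axis=1)
    n_complete = int(complete.sum())
    if n_complete < 3:
        raise ValueError(f"need >=3 complete cases to fit condition model, got {n_complete}")
    mass = vals[complete, 0]
    wing = vals[complete, 1]
    tarsus = vals[complete, 2]
    for name, v in (("wing_mm", wing), ("tarsus_mm", tarsus)):
        if np.std(v, ddof=1) == 0:
            raise ValueError(f"zero variance in {name}: structural PCA undefined")
    z = np.column_stack([
        (wing - wing.mean()) / wing.std(ddof=1),
        (tarsus - tarsus.mean()) / tarsus.std(ddof=1),
    ])
    # PC1 via SVD of the standardized matrix (correlation-matrix PCA).
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    pc1_loading = vt[0]
    if pc1_loading[0] < 0:  # sign fixed: positive loading on wing
        pc1_loading = -pc1_loading
    pc1 = z @ pc1_loading
    # OLS mass ~ 1 + PC1
    design = np.column_stack([np.ones_like(pc1), pc1])
    coef, *_ = np.linalg.lstsq(design, mass, rcond=None)
    resid = mass - design @ coef
    out = np.full(len(morph), resid.mean())  # imputed value for incomplete cases
    out[complete] = resid
    return out


def z_standardize(values, name: str | None = None):
    """Center and scale to unit sample variance (n-1 denominator).

    Returns ``(z, mean, sd)`` so callers can back-transform exactly.

    Raises
    ------
    ValueError
        For length < 2 or zero variance; the offending covariate ``name``
        is included in the message when given.
    """
    v = np.asarray(values, dtype=float)
    label = f" for covariate {name!r}" if name else ""
    if v.ndim != 1 or v.size < 2:
        raise ValueError(f"need a 1-d vector of length >= 2{label}")
    if np.isnan(v).any():
        raise ValueError(f"NaN values{label}; impute before standardizing")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0:
        raise ValueError(f"zero variance{label}: cannot z-standardize a constant")
    return (v - mean) / sd, mean, sd


class DesignMatrixBuilder(BaseEstimator, TransformerMixin):
    """Build the 9-column (non-intercept) fCort design matrix.

    ``fit`` learns per-covariate standardization constants on the provided
    sample; ``transform`` z-scores the continuous main effects, passes age
    through, and forms the three interactions as products of the
    standardized mains.  Interactions are intentionally NOT re-standardized
    (set ``standardize_interactions=True`` to change that).

    Attributes
    ----------
    scale_ : dict mapping covariate name -> (mean, sd)
    feature_names_out_ : tuple of output column names (TERMS minus intercept)
    """

    def __init__(self, standardize_interactions: bool = False):
        self.standardize_interactions = standardize_interactions

    def fit(self, X: pd.DataFrame, y=None):
        for c in MAIN_EFFECTS:
            if c not in X.columns:
                raise ValueError(f"design input missing column {c!r}")
        self.scale_ = {}
        for c in CONTINUOUS_EFFECTS:
            _, mean, sd = z_standardize(X[c].to_numpy(), name=c)
            self.scale_[c] = (mean, sd)
        self.feature_names_out_ = tuple(t for t in TERMS if t != "intercept")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "scale_"):
            raise ValueError("DesignMatrixBuilder is not fitted")
        cols = {}
        for c in CONTINUOUS_EFFECTS:
            mean, sd = self.scale_[c]
            cols[c] = (X[c].to_numpy(dtype=float) - mean) / sd
        cols["age"] = X["age"].to_numpy(dtype=float)
        for out_name, a, b in INTERACTIONS:
            prod = cols[a] * cols[b]
            if self.standardize_interactions:
                prod, _, _ = z_standardize(prod, name=out_name)
            cols[out_name] = prod
        out = pd.DataFrame({name: cols[name] for name in self.feature_names_out_},
                           index=X.index)
        if not np.isfinite(out.to_numpy()).all():
            bad = out.columns[~np.isfinite(out.to_numpy()).all(axis=0)].tolist()
            raise ValueError(f"non-finite values in design columns {bad}")
        return out

    def inverse_transform(self, Z: pd.DataFrame) -> pd.DataFrame:
        """Back-transform standardized main effects to raw scale."""
        out = Z.copy()
        for c, (mean, sd) in self.scale_.items():
            if c in out.columns:
                out[c] = out[c] * sd + mean
        return out


def build_design(birds: pd.DataFrame, standardize_interactions: bool = False):
    """One-shot fit+transform; returns ``(design_df, builder)``."""
    builder = DesignMatrixBuilder(standardize_interactions=standardize_interactions)
    design = builder.fit(birds).transform(birds)
    return design, builder
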