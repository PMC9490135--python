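import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sagecort.covariates import (DesignMatrixBuilder, HORSE_DAYS_PER_YEAR,
                                 INTERACTIONS, TERMS, average_covariates,
                                 body_condition, build_design,
                                 compute_use_days, z_standardize)


class TestUseDays:
    @pytest.mark.parametrize("head,days,area,expected", [
        (0, 120, 400, 0.0),
        (100, 120, 400, 30.0),
        (50, HORSE_DAYS_PER_YEAR, 365, 50.0),
    ])
    def test_examples(self, head, days, area, expected):
        assert compute_use_days(head, days, area) == pytest.approx(expected)

    @pytest.mark.parametrize("head,days,area", [
        (10, 100, 0), (10, 100, -5), (-1, 100, 10), (10, -1, 10),
    ])
    def test_domain_errors(self, head, days, area):
        with pytest.raises(ValueError):
            compute_use_days(head, days, area)

    @given(head=st.floats(0, 1e4), days=st.floats(0, 366),
           area=st.floats(0.1, 1e4), c=st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None)
    def test_homogeneity(self, head, days, area, c):
        base = compute_use_days(head, days, area)
        assert compute_use_days(c * head, days, area) == pytest.approx(c * base, rel=1e-9)
        assert compute_use_days(head, c * days, area) == pytest.approx(c * base, rel=1e-9)
        assert compute_use_days(head, days, c * area) == pytest.approx(base / c, rel=1e-9)


class TestAverageCovariates:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["bird_id", "x", "y", "year",
                                           "horse_use", "cow_use",
                                           "precip_mm", "grass_pct"])

    def test_single_location_identity(self):
        df = self._frame([("b1", 0, 0, 2015, 12.0, 3.0, 250.0, 5.0)])
        out = average_covariates(df)
        assert out.loc[0, "horse_use"] == 12.0
        assert out.loc[0, "precip_mm"] == 250.0

    def test_two_location_midpoint(self):
        df = self._frame([("b1", 0, 0, 2015, 10.0, 0, 200, 0),
                          ("b1", 1, 1, 2015, 30.0, 0, 300, 0)])
        out = average_covariates(df)
        assert out.loc[0, "horse_use"] == pytest.approx(20.0)
        assert out.loc[0, "precip_mm"] == pytest.approx(250.0)

    def test_permutation_invariance(self, rng):
        rows = [("b1", i, i, 2015, float(v), 1.0, 200.0, 2.0)
                for i, v in enumerate(rng.uniform(0, 50, 7))]
        df = self._frame(rows)
        shuffled = df.sample(frac=1, random_state=3).reset_index(drop=True)
        pd.testing.assert_frame_equal(average_covariates(df),
                                      average_covariates(shuffled))

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="location"):
            average_covariates(self._frame([]))


class TestBodyCondition:
    def _morph(self, n, rng, missing=()):
        zw = rng.standard_normal(n)
        zt = 0.7 * zw + 0.7 * rng.standard_normal(n)
        df = pd.DataFrame({
            "wing_mm": 190 + 5 * zw,
            "tarsus_mm": 55 + 2 * zt,
        })
        df["mass_g"] = 1500 + 30 * (zw + zt) + rng.normal(0, 25, n)
        for (row, col) in missing:
            df.loc[row, col] = np.nan
        return df

    def test_residuals_sum_to_zero(self, rng):
        cond = body_condition(self._morph(40, rng))
        assert abs(cond.sum()) < 1e-8

    def test_missing_gets_mean_condition(self, rng):
        df = self._morph(30, rng, missing=[(4, "wing_mm")])
        cond = body_condition(df)
        complete = np.ones(30, bool)
        complete[4] = False
        assert cond[4] == pytest.approx(cond[complete].mean(), abs=1e-10)
        assert cond[4] == pytest.approx(0.0, abs=1e-8)

    def test_linearity_in_mass(self, rng):
        df = self._morph(25, rng)
        doubled = df.assign(mass_g=2 * df["mass_g"])
        np.testing.assert_allclose(body_condition(doubled),
                                   2 * body_condition(df), atol=1e-8)

    def test_pc1_sign_irrelevant_for_residuals(self, rng):
        """An independent OLS oracle gives identical residuals for either
        sign convention of the structural-size axis."""
        df = self._morph(35, rng)
        wing = df["wing_mm"].to_numpy()
        tarsus = df["tarsus_mm"].to_numpy()
        mass = df["mass_g"].to_numpy()
        z = np.column_stack([
            (wing - wing.mean()) / wing.std(ddof=1),
            (tarsus - tarsus.mean()) / tarsus.std(ddof=1)])
        cov = np.cov(z, rowvar=False)
        _, vecs = np.linalg.eigh(cov)
        for sign in (1.0, -1.0):
            pc1 = z @ (sign * vecs[:, -1])
            design = np.column_stack([np.ones_like(pc1), pc1])
            coef, *_ = np.linalg.lstsq(design, mass, rcond=None)
            oracle = mass - design @ coef
            np.testing.assert_allclose(body_condition(df), oracle, atol=1e-8)

    def test_too_few_complete_cases(self, rng):
        df = self._morph(5, rng, missing=[(0, "wing_mm"), (1, "tarsus_mm"),
                                          (2, "mass_g")])
        with pytest.raises(ValueError, match="complete"):
            body_condition(df)

    def test_zero_variance_errors(self):
        df = pd.DataFrame({"mass_g": [1500.0, 1520, 1540, 1510],
                           "wing_mm": [190.0, 190, 190, 190],
                           "tarsus_mm": [54.0, 55, 56, 57]})
        with pytest.raises(ValueError, match="wing"):
            body_condition(df)


class TestZStandardize:
    def test_symmetric_triple(self):
        z, mean, sd = z_standardize([1.0, 2.0, 3.0])
        np.testing.assert_allclose(z, [-1, 0, 1])
        assert mean == 2.0 and sd == 1.0

    def test_idempotence(self, rng):
        z, _, _ = z_standardize(rng.normal(10, 3, 50))
        z2, m2, s2 = z_standardize(z)
        np.testing.assert_allclose(z2, z, atol=1e-12)
        assert m2 == pytest.approx(0, abs=1e-12)
        assert s2 == pytest.approx(1, abs=1e-12)

    def test_constant_errors_with_name(self):
        with pytest.raises(ValueError, match="precip"):
            z_standardize(np.full(10, 3.0), name="precip")

    @given(st.lists(st.floats(-1e5, 1e5), min_size=2, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_back_transform_round_trip(self, values):
        v = np.asarray(values)
        if v.std(ddof=1) < 1e-9:
            return
        z, mean, sd = z_standardize(v)
        back = z * sd + mean
        np.testing.assert_allclose(back, v, rtol=1e-10, atol=1e-10)


class TestDesignMatrixBuilder:
    def _birds(self, rng, n=80):
        return pd.DataFrame({
            "cows": rng.uniform(0, 100, n),
            "horses": rng.uniform(0, 60, n),
            "body_condition": rng.normal(0, 30, n),
            "age": rng.integers(0, 2, n),
            "annual_grass": rng.uniform(0, 25, n),
            "precipitation": rng.uniform(150, 410, n),
        })

    def test_columns_follow_term_order(self, rng):
        design, _ = build_design(self._birds(rng))
        assert tuple(design.columns) == tuple(t for t in TERMS if t != "intercept")

    def test_mains_standardized_interactions_not(self, rng):
        birds = self._birds(rng)
        design, _ = build_design(birds)
        for c in ("cows", "horses", "precipitation"):
            assert design[c].mean() == pytest.approx(0, abs=1e-10)
            assert design[c].std(ddof=1) == pytest.approx(1, rel=1e-10)
        # interaction column equals the product of standardized mains,
        # so its mean is the sample covariance of the two z-scores
        for name, a, b in INTERACTIONS:
            np.testing.assert_allclose(design[name], design[a] * design[b],
                                       atol=1e-12)
            n = len(birds)
            cov = np.cov(design[a], design[b], ddof=0)[0, 1]
            assert design[name].mean() == pytest.approx(cov, abs=1e-10)

    def test_scale_constants_back_transform(self, rng):
        birds = self._birds(rng)
        design, builder = build_design(birds)
        back = builder.inverse_transform(design)
        for c in ("cows", "horses", "precipitation", "annual_grass"):
            np.testing.assert_allclose(back[c], birds[c], rtol=1e-10)

    def test_unfitted_transform_errors(self, rng):
        with pytest.raises(ValueError, match="not fitted"):
            DesignMatrixBuilder().transform(self._birds(rng))
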