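"""Box-Cox, nested mixed models, Poisson spline rate curves, KS test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from slicephys.population_stats import (
    boxcox_transform,
    fit_nested_model,
    fit_rate_curves,
    ks_two_sample,
    rate_difference_intervals,
)


class TestBoxCox:
    def test_lambda_one_is_shifted_identity(self):
        y = np.array([1.0, 2.0, 5.0])
        res = boxcox_transform(y, lam=1.0)
        assert np.allclose(res.values, y - 1.0)

    def test_lambda_zero_is_log(self):
        res = boxcox_transform(np.array([np.e]), lam=0.0)
        assert res.values[0] == pytest.approx(1.0)

    def test_continuity_near_zero(self):
        y = np.exp(np.random.default_rng(1).normal(size=200))
        a = boxcox_transform(y, lam=1e-8).values
        b = boxcox_transform(y, lam=0.0).values
        assert np.max(np.abs(a - b) / np.abs(b)) < 1e-6

    def test_profile_likelihood_matches_scipy_mle(self):
        """Grid argmax agrees with scipy's continuous MLE within one step."""
        from scipy import stats as _st

        y = np.exp(np.random.default_rng(7).normal(size=500)) + 2.0
        res = boxcox_transform(y)
        _, lam_scipy = _st.boxcox(y)
        assert res.lam == pytest.approx(lam_scipy, abs=0.011)

    def test_nonpositive_values_are_shifted(self):
        res = boxcox_transform(np.array([-1.0, 0.0, 2.0]), lam=1.0)
        assert res.shift == pytest.approx(1.0 + 1e-6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            boxcox_transform([])


def _nested_frame(rng, n_animals=4, n_slices=2, n_channels=6, delta=0.0,
                  sa=0.2, ss=0.2, sr=0.5):
    rows = []
    for gen in ("wt", "mut"):
        for a in range(n_animals):
            aid = f"{gen}a{a}"
            ae = rng.normal(0, sa)
            for s in range(n_slices):
                sid = f"{aid}s{s}"
                se = rng.normal(0, ss)
                vals = 1.0 + delta * (gen == "mut") + ae + se + rng.normal(
                    0, sr, n_channels
                )
                rows += [
                    {"value": v, "genotype": gen, "animal_id": aid,
                     "slice_id": sid}
                    for v in vals
                ]
    return pd.DataFrame(rows)


class TestNestedModel:
    def test_balanced_design_matches_ols(self, rng):
        """On a balanced design the mixed-model fixed effects equal OLS."""
        import statsmodels.formula.api as smf

        df = _nested_frame(rng, sa=0.0, ss=0.0)
        res = fit_nested_model(df, "value ~ genotype")
        ols = smf.ols("value ~ genotype", df).fit()
        assert np.allclose(
            res.table["estimate"].to_numpy(), ols.params.to_numpy(), atol=1e-6
        )

    def test_ci_brackets_estimate(self, rng):
        res = fit_nested_model(_nested_frame(rng, delta=1.0),
                               "value ~ genotype")
        t = res.table
        assert (t["ci_lo"] <= t["estimate"]).all()
        assert (t["estimate"] <= t["ci_hi"]).all()

    def test_genotype_tested_at_animal_level(self, rng):
        """Containment df for the genotype contrast equals animals minus
        between-animal parameters, not the channel count."""
        df = _nested_frame(rng, n_animals=4)
        res = fit_nested_model(df, "value ~ genotype")
        row = res.table[res.table["effect"].str.contains("genotype")].iloc[0]
        assert row["df"] == 8 - 2

    def test_effect_recovery(self, rng):
        df = _nested_frame(rng, n_animals=6, delta=1.0, sa=0.1, ss=0.1, sr=0.3)
        res = fit_nested_model(
            df, "value ~ C(genotype, Treatment('wt'))"
        )
        e = res.effect("mut")
        assert e["ci_lo"] <= 1.0 <= e["ci_hi"]

    def test_zero_variance_components_recovered_small(self):
        rng = np.random.default_rng(3)
        df = _nested_frame(rng, n_animals=10, n_slices=4, n_channels=40,
                           sa=0.0, ss=0.0)
        res = fit_nested_model(df, "value ~ genotype")
        assert res.sigma_animal <= 0.05
        assert res.sigma_slice <= 0.05

    def test_single_slice_genotype_is_singular(self, rng):
        df = _nested_frame(rng)
        df = df[(df["genotype"] == "wt") | (df["slice_id"] == "muta0s0")]
        df = df[(df["genotype"] == "mut") | True]
        sub = pd.concat(
            [
                df[df["genotype"] == "wt"],
                df[(df["genotype"] == "mut") & (df["slice_id"] == "muta0s0")],
            ]
        )
        with pytest.raises(ValueError, match="singular"):
            fit_nested_model(sub)

    def test_slice_ids_must_nest_in_animals(self, rng):
        df = _nested_frame(rng)
        df.loc[df.index[-1], "slice_id"] = "wta0s0"  # reused across animals
        with pytest.raises(ValueError, match="slice_id"):
            fit_nested_model(df)


class TestRateCurves:
    def test_constant_rate_recovered(self):
        rng = np.random.default_rng(1)
        counts = {"g": rng.poisson(5.0, (64, 600))}
        c = fit_rate_curves(counts)["g"]
        m = (c.times >= 50) & (c.times <= 550)
        assert np.max(np.abs(c.log_rate[m] - np.log(5.0))) < 0.05

    def test_rate_integral_conserves_total_spikes(self):
        rng = np.random.default_rng(2)
        counts = {"g": rng.poisson(3.0, (32, 600))}
        c = fit_rate_curves(counts)["g"]
        integral = np.exp(c.log_rate).sum()  # 1-s bins
        assert integral == pytest.approx(counts["g"].sum() / 32, rel=0.05)

    def test_step_recovered_with_breakpoint(self):
        rng = np.random.default_rng(3)
        t = np.arange(600) + 0.5
        rate = np.where(t >= 20, 5.0, 1.0)
        counts = {"g": rng.poisson(rate, (64, 600))}
        c = fit_rate_curves(counts, breakpoints=[20.0])["g"]
        assert np.max(np.abs(np.exp(c.log_rate[t < 10]) - 1.0)) < 0.10
        assert np.max(np.abs(np.exp(c.log_rate[t > 30]) / 5.0 - 1.0)) < 0.10

    def test_zero_counts_flagged_floor(self):
        res = fit_rate_curves({"g": np.zeros((8, 100))})["g"]
        assert res.flat_floor
        assert np.all(np.isinf(res.se))

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            fit_rate_curves({"g": np.full((2, 50), 0.5)})

    def test_band_brackets_estimate(self):
        rng = np.random.default_rng(4)
        c = fit_rate_curves({"g": rng.poisson(2.0, (16, 200))})["g"]
        assert np.all(c.lo <= c.log_rate)
        assert np.all(c.log_rate <= c.hi)


class TestRateDifference:
    def _curves(self, seed=0, shift=0.0):
        rng = np.random.default_rng(seed)
        a = fit_rate_curves({"a": rng.poisson(2.0, (32, 300))})["a"]
        b = fit_rate_curves({"b": rng.poisson(2.0 * np.exp(shift), (32, 300))})["b"]
        return a, b

    def test_identical_curves_have_no_intervals(self):
        a = self._curves(seed=5)[0]
        rd = rate_difference_intervals(a, a)
        assert rd.intervals == []
        assert np.allclose(rd.diff, 0.0)

    def test_swapped_arguments_negate_difference(self):
        a, b = self._curves(seed=6, shift=1.0)
        r1 = rate_difference_intervals(a, b)
        r2 = rate_difference_intervals(b, a)
        assert np.allclose(r1.diff, -r2.diff)
        assert r1.intervals == r2.intervals

    def test_grid_mismatch_rejected(self):
        rng = np.random.default_rng(7)
        a = fit_rate_curves({"a": rng.poisson(2.0, (8, 100))})["a"]
        b = fit_rate_curves({"b": rng.poisson(2.0, (8, 120))})["b"]
        with pytest.raises(ValueError, match="grid"):
            rate_difference_intervals(a, b)

    def test_large_shift_detected_everywhere(self):
        a, b = self._curves(seed=8, shift=1.0)
        rd = rate_difference_intervals(b, a)
        covered = sum(e - s for s, e in rd.intervals)
        assert covered >= 0.95 * 300


def _brute_force_D(a, b):
    """Exhaustive supremum of |F_a - F_b| over all pooled sample points."""
    best = 0.0
    for x in np.concatenate([a, b]):
        fa = np.sum(a <= x) / len(a)
        fb = np.sum(b <= x) / len(b)
        best = max(best, abs(fa - fb))
    return best


class TestKS:
    def test_identical_samples(self):
        r = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0
        assert r.pvalue == 1.0

    def test_disjoint_supports(self):
        r = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert r.statistic == 1.0

    def test_matches_brute_force_supremum_exactly(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n, m = rng.integers(1, 9, size=2)
            a = rng.uniform(size=n)
            b = rng.uniform(size=m)
            r = ks_two_sample(a, b)
            assert r.statistic == pytest.approx(_brute_force_D(a, b), abs=1e-12)

    def test_agrees_with_scipy_asymptotic(self):
        from scipy import stats as _st

        rng = np.random.default_rng(12)
        a = rng.normal(size=300)
        b = rng.normal(0.3, 1.0, size=250)
        r = ks_two_sample(a, b)
        ref = _st.ks_2samp(a, b, mode="asymp")
        assert r.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert r.pvalue == pytest.approx(ref.pvalue, rel=0.2)

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(seed=st.integers(min_value=0, max_value=5000))
    def test_invariance_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=20)
        b = rng.normal(0.5, 1.2, size=25)
        d0 = ks_two_sample(a, b).statistic
        for f in (np.exp, np.arctan, lambda x: x**3):
            assert ks_two_sample(f(a), f(b)).statistic == pytest.approx(
                d0, abs=1e-12
            )

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])
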