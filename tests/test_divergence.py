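"""LOESS, bootstrap difference curves, BCa intervals, divergence windows."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from petrodim import (AngleParams, BootEnsemble, CohortTable, DiffCurve,
                      GrowthParams, LoessError, SimConfig, bca_interval,
                      bootstrap_difference, detect_divergence_windows,
                      loess_fit, pubertal_ramp, sex_difference_curve,
                      simulate_cohort)


def loess_oracle(x, y, x0, span, degree=1):
    """Brute-force single-point tricube-weighted polynomial fit."""
    n = len(x)
    d = np.abs(np.asarray(x) - x0)
    q = int(np.ceil(span * n))
    h = np.sort(d)[q - 1]
    u = d / h
    w = np.where(u < 1, (1 - u**3) ** 3, 0.0)
    V = np.vander(np.asarray(x) - x0, degree + 1, increasing=True)
    W = np.diag(w)
    beta = np.linalg.solve(V.T @ W @ V, V.T @ W @ np.asarray(y))
    return beta[0]


class TestLoess:
    def test_reproduces_global_line(self):
        x = np.linspace(0, 10, 25)
        y = 3.0 - 0.5 * x
        for span in (0.3, 0.6, 1.0):
            sm = loess_fit(x, y, span=span, degree=1)
            assert np.allclose(sm.predict(x), y, atol=1e-10)

    def test_span_one_degree_one_equals_global_ols(self):
        rng = np.random.default_rng(2)
        x = np.sort(rng.uniform(0, 1, 30))
        y = rng.normal(size=30)
        sm = loess_fit(x, y, span=1.0, degree=1)
        grid = np.array([x.min(), 0.37, x.max()])
        # span=1 still weights by tricube distance, so compare against the
        # same weighted fit done by the brute-force oracle
        expect = [loess_oracle(x, y, g, span=1.0) for g in grid]
        assert np.allclose(sm.predict(grid), expect, atol=1e-10)

    def test_five_point_hand_oracle(self):
        x = [0.0, 1.0, 2.0, 3.0, 4.0]
        y = [1.0, 2.0, 1.5, 3.0, 2.5]
        sm = loess_fit(np.array(x), np.array(y), span=0.8, degree=1)
        assert sm.predict(1.7)[0] == pytest.approx(
            loess_oracle(x, y, 1.7, span=0.8), abs=1e-10)

    @pytest.mark.parametrize("degree", [0, 1, 2])
    def test_matches_per_point_weighted_ls(self, degree):
        rng = np.random.default_rng(degree + 100)
        for _ in range(8):
            n = int(rng.integers(8, 50))
            x = np.sort(rng.uniform(0, 5, n))
            y = np.sin(x) + rng.normal(scale=0.2, size=n)
            span = float(rng.uniform(0.4, 1.0))
            sm = loess_fit(x, y, span=span, degree=degree)
            grid = rng.uniform(x.min(), x.max(), 5)
            expect = [loess_oracle(x, y, g, span, degree) for g in grid]
            assert np.allclose(sm.predict(grid), expect, atol=1e-8)

    def test_degree_one_agrees_with_statsmodels_lowess(self):
        # independent reference implementation, identical definition
        from statsmodels.nonparametric.smoothers_lowess import lowess
        rng = np.random.default_rng(8)
        x = np.sort(rng.uniform(0, 10, 60))
        y = np.cos(x) + rng.normal(scale=0.1, size=60)
        grid = np.linspace(x.min(), x.max(), 11)
        ours = loess_fit(x, y, span=0.5, degree=1).predict(grid)
        ref = lowess(y, x, frac=0.5, it=0, xvals=grid)
        assert np.allclose(ours, ref, atol=1e-8)

    def test_no_extrapolation(self):
        sm = loess_fit(np.arange(5.0), np.arange(5.0))
        with pytest.raises(ValueError, match="outside the training range"):
            sm.predict(7.0)

    def test_degenerate_neighbourhood_names_point(self):
        x = np.array([1.0, 1.0, 1.0, 1.0, 5.0])
        y = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        sm = loess_fit(x, y, span=0.8, degree=1)
        with pytest.raises(LoessError, match="1\\."):
            sm.predict(1.0)

    def test_validation(self):
        x, y = np.arange(10.0), np.arange(10.0)
        with pytest.raises(ValueError):
            loess_fit(x, y, span=0.0)
        with pytest.raises(ValueError):
            loess_fit(x, y, degree=3)
        with pytest.raises(ValueError):
            loess_fit(x[:3], y[:3], span=0.5)  # fewer than degree+2 local
        with pytest.raises(ValueError):
            loess_fit(np.array([0.0, np.nan, 2.0]), y[:3])


def two_sex_table(age_f, val_f, age_m, val_m):
    rows = []
    for sex, ages, vals in (("F", age_f, val_f), ("M", age_m, val_m)):
        for i, (a, v) in enumerate(zip(ages, vals)):
            rows.append({"specimen_id": f"{sex}{i}", "collection": "other",
                         "sex": sex, "age_years": a, "aub_mm": v})
    return CohortTable(pd.DataFrame(rows))


class TestDifferenceCurve:
    def test_identical_sexes_give_zero(self):
        rng = np.random.default_rng(1)
        ages = np.sort(rng.uniform(0, 20, 40))
        vals = 70 + 2 * ages + rng.normal(size=40)
        table = two_sex_table(ages, vals, ages, vals)
        dc = sex_difference_curve(table)
        assert np.allclose(dc.diff, 0.0, atol=1e-10)

    def test_label_swap_negates(self):
        rng = np.random.default_rng(9)
        af, am = np.sort(rng.uniform(0, 20, 30)), np.sort(rng.uniform(0, 20, 35))
        vf, vm = 70 + af + rng.normal(size=30), 68 + am + rng.normal(size=35)
        d1 = sex_difference_curve(two_sex_table(af, vf, am, vm))
        d2 = sex_difference_curve(two_sex_table(am, vm, af, vf))
        assert np.allclose(d1.diff, -d2.diff, atol=1e-10)
        assert np.array_equal(d1.grid, d2.grid)

    def test_noise_free_recovers_minus_delta_ramp(self):
        # shared age design: LOESS is linear in y, so the log-growth term
        # cancels exactly and the difference is the smoothed ramp alone
        from petrodim import mean_aub
        g = GrowthParams(delta=6.0, sigma_aub=0.0)
        rng = np.random.default_rng(6)
        ages = np.sort(rng.uniform(0, 30, 400))
        vf = mean_aub(ages, np.repeat("F", 400), g)
        vm = mean_aub(ages, np.repeat("M", 400), g)
        dc = sex_difference_curve(two_sex_table(ages, vf, ages, vm),
                                  span=0.25)
        expect = -g.delta * pubertal_ramp(dc.grid, g.tau, g.ramp_width)
        # residual is smoothing bias at the ramp's curvature only
        assert np.allclose(dc.diff, expect, atol=0.5)
        assert np.all(np.abs(dc.diff[dc.grid < 6]) < 0.1)
        assert np.all(np.abs(dc.diff[dc.grid > 20] + g.delta) < 0.1)

    def test_grid_within_shared_support(self):
        table = two_sex_table([0, 5, 10, 15, 20.0], 70 + np.arange(5.0),
                              [3, 6, 12, 18, 25.0], 71 + np.arange(5.0))
        dc = sex_difference_curve(table, grid_step=0.5, span=0.75)
        assert dc.grid.min() >= 3.0 and dc.grid.max() <= 20.0
        assert np.all(np.diff(dc.grid) > 0)
        assert dc.support_n.shape == (dc.grid.size, 2)
        assert np.all(dc.support_n >= 1)

    def test_insufficient_per_sex_data(self):
        table = two_sex_table([1.0, 2.0], [70.0, 71.0],
                              [1, 2, 3, 4, 5.0], 70 + np.arange(5.0))
        with pytest.raises(ValueError, match="insufficient F data"):
            sex_difference_curve(table)


class TestBcaInterval:
    def test_reduces_to_percentile_when_symmetric(self):
        # replicates symmetric about observed, flat jackknife: z0=0, a=0
        reps = np.concatenate([np.linspace(-1, 1, 500),
                               -np.linspace(-1, 1, 500)])
        lo, hi = bca_interval(reps, observed=0.0,
                              jackknife=np.zeros(50), alpha=0.05)
        assert lo == pytest.approx(np.quantile(reps, 0.025), abs=1e-12)
        assert hi == pytest.approx(np.quantile(reps, 0.975), abs=1e-12)

    def test_direct_formula_oracle(self):
        # textbook formula computed independently, replicates {1..1000}
        reps = np.arange(1.0, 1001.0)
        observed, alpha = 500.5, 0.05
        z0 = norm.ppf(0.5)        # exactly half the replicates below
        zl, zh = norm.ppf(0.025), norm.ppf(0.975)
        a1 = norm.cdf(z0 + (z0 + zl) / 1.0)
        a2 = norm.cdf(z0 + (z0 + zh) / 1.0)
        expect = np.quantile(reps, [a1, a2])
        lo, hi = bca_interval(reps, observed, jackknife=np.zeros(20),
                              alpha=alpha)
        assert (lo, hi) == pytest.approx(tuple(expect))
        assert lo == pytest.approx(25.975)   # ~the 2.5% empirical quantile
        assert hi == pytest.approx(975.025)

    def test_skewed_jackknife_shifts_interval(self):
        rng = np.random.default_rng(14)
        reps = rng.normal(size=1000)
        jack = rng.gamma(1.0, size=60)  # skewed: a != 0
        lo0, hi0 = bca_interval(reps, 0.0, jackknife=None)
        lo1, hi1 = bca_interval(reps, 0.0, jackknife=jack)
        assert (lo0, hi0) != (lo1, hi1)

    def test_alpha_half_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            bca_interval(np.arange(200.0), 100.0, alpha=0.5)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            bca_interval(np.arange(50.0), 25.0)

    def test_degenerate_replicates_warn_point_interval(self):
        with pytest.warns(UserWarning, match="identical"):
            lo, hi = bca_interval(np.full(200, 3.0), 3.0)
        assert lo == hi == 3.0

    def test_observed_outside_range_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            lo, hi = bca_interval(np.arange(1.0, 201.0), observed=500.0)
        assert lo <= hi


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(SimConfig.balanced(120, seed=33))


class TestBootstrap:

    def test_seed_reproducible(self, cohort):
        e1 = bootstrap_difference(cohort, B=200, seed=5)
        e2 = bootstrap_difference(cohort, B=200, seed=5)
        assert np.array_equal(e1.bca_lo, e2.bca_lo, equal_nan=True)
        assert np.array_equal(e1.bca_hi, e2.bca_hi, equal_nan=True)
        e3 = bootstrap_difference(cohort, B=200, seed=6)
        assert not np.array_equal(e1.bca_lo, e3.bca_lo, equal_nan=True)

    def test_changing_b_keeps_observed_diff(self, cohort):
        e1 = bootstrap_difference(cohort, B=150, seed=5)
        e2 = bootstrap_difference(cohort, B=300, seed=5)
        assert np.array_equal(e1.observed.diff, e2.observed.diff)

    def test_interval_brackets_and_orders(self, cohort):
        ens = bootstrap_difference(cohort, B=300, seed=7)
        ok = np.isfinite(ens.bca_lo)
        assert ok.any()
        assert np.all(ens.bca_lo[ok] <= ens.bca_hi[ok])
        assert ens.replicates.shape[1] == ens.grid.size
        assert ens.n_failed <= 0.1 * 300

    def test_noise_free_linear_data_gives_degenerate_bands(self):
        # every resample of collinear points reproduces the same line, so
        # all replicate curves coincide and the bands collapse to points
        rng = np.random.default_rng(40)
        ages = np.sort(rng.uniform(0, 25, 150))
        table = two_sex_table(ages, 70 + 2 * ages, ages, 76 + 2 * ages)
        ens = bootstrap_difference(table, B=200, seed=1)
        ok = np.isfinite(ens.bca_lo)
        width = ens.bca_hi[ok] - ens.bca_lo[ok]
        assert np.nanmax(width) < 1e-8
        assert np.allclose(ens.observed.diff, -6.0, atol=1e-8)

    def test_noise_free_curved_data_width_below_signal_scale(self):
        # with a curved mean the only replicate variation is design-driven
        # smoothing bias; widths stay well under the dimorphism signal
        from petrodim import mean_aub
        g = GrowthParams(delta=6.0, sigma_aub=0.0)
        rng = np.random.default_rng(41)
        ages = np.sort(rng.uniform(0, 30, 150))
        table = two_sex_table(ages, mean_aub(ages, np.repeat("F", 150), g),
                              ages, mean_aub(ages, np.repeat("M", 150), g))
        ens = bootstrap_difference(table, B=200, seed=1)
        ok = np.isfinite(ens.bca_lo)
        width = ens.bca_hi[ok] - ens.bca_lo[ok]
        assert np.all(width < g.delta)
        assert np.median(width) < 1.0
        assert np.nanmax(np.abs(ens.observed.diff)) > g.delta * 0.9

    def test_pooled_resampling_option(self, cohort):
        ens = bootstrap_difference(cohort, B=150, seed=3, stratified=False)
        assert not ens.stratified
        assert np.isfinite(ens.bca_lo).any()


def fabricate_ensemble(grid, lo, hi):
    diff = (np.asarray(lo) + np.asarray(hi)) / 2
    observed = DiffCurve(grid=np.asarray(grid, float), diff=diff,
                         curve_f=diff, curve_m=np.zeros_like(diff),
                         support_n=np.ones((len(grid), 2), int))
    return BootEnsemble(observed=observed, replicates=np.empty((0, len(grid))),
                        bca_lo=np.asarray(lo, float),
                        bca_hi=np.asarray(hi, float), alpha=0.05, seed=0,
                        b_requested=0, n_failed=0)


class TestWindows:
    def test_all_intervals_contain_zero(self):
        grid = np.arange(0.0, 5.0, 0.5)
        ens = fabricate_ensemble(grid, -np.ones(10), np.ones(10))
        assert len(detect_divergence_windows(ens)) == 0

    def test_single_constructed_window(self):
        grid = np.arange(10.0, 20.5, 0.5)
        lo = np.where((grid >= 12) & (grid <= 18), 0.5, -1.0)
        ens = fabricate_ensemble(grid, lo, lo + 2.0)
        win = detect_divergence_windows(ens)
        assert len(win) == 1
        w = win.windows[0]
        assert (w.start_age, w.end_age, w.sign) == (12.0, 18.0, 1)
        assert win.earliest_onset == 12.0

    def test_min_run_suppresses_flicker(self):
        grid = np.arange(0.0, 5.0, 0.5)
        lo = -np.ones(10)
        hi = np.ones(10)
        hi[4] = -0.1  # single flagged point (males larger)
        ens = fabricate_ensemble(grid, lo, hi)
        assert len(detect_divergence_windows(ens, min_run=2)) == 0
        assert len(detect_divergence_windows(ens, min_run=1)) == 1
        assert detect_divergence_windows(ens, min_run=1).windows[0].sign == -1

    def test_sign_change_splits_window(self):
        grid = np.arange(0.0, 3.0, 0.5)
        lo = np.array([0.1, 0.1, 0.1, -2.0, -2.0, -2.0])
        hi = np.array([1.0, 1.0, 1.0, -0.1, -0.1, -0.1])
        win = detect_divergence_windows(fabricate_ensemble(grid, lo, hi))
        assert len(win) == 2
        assert win.windows[0].sign == 1 and win.windows[1].sign == -1

    def test_persistent_window_reaches_grid_end(self):
        grid = np.arange(0.0, 20.5, 0.5)
        # transient early excursion plus a terminal separation
        hi = np.ones(grid.size)
        hi[(grid >= 2) & (grid <= 3.5)] = -0.1
        hi[grid >= 14] = -0.5
        ens = fabricate_ensemble(grid, -2 * np.ones(grid.size), hi)
        win = detect_divergence_windows(ens)
        assert len(win) == 2
        assert win.earliest_onset == 2.0
        # the headline onset ignores the transient excursion
        assert win.persistent_onset == 14.0
        assert win.persistent_window(sign=1) is None

    def test_no_persistent_window_when_only_transient(self):
        grid = np.arange(0.0, 20.5, 0.5)
        hi = np.ones(grid.size)
        hi[(grid >= 2) & (grid <= 3.5)] = -0.1
        ens = fabricate_ensemble(grid, -2 * np.ones(grid.size), hi)
        assert detect_divergence_windows(ens).persistent_onset is None

    def test_nan_intervals_never_flagged(self):
        grid = np.arange(0.0, 3.0, 0.5)
        lo = np.full(6, np.nan)
        hi = np.full(6, np.nan)
        assert len(detect_divergence_windows(
            fabricate_ensemble(grid, lo, hi))) == 0
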