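"""Segmented regression, modified t-test, ANOVA-LSD and letter display."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from canopylux.stats import (
    anova_lsd,
    compact_letter_display,
    pearson_modified,
    segmented_fit,
)
from canopylux.synthetic import ResponseSimConfig, gen_response


def grid_oracle_psi(x, y, grid):
    """Brute-force RSS minimiser over a fixed breakpoint grid."""
    best_psi, best_rss = None, np.inf
    for psi in grid:
        X = np.column_stack([np.ones_like(x), x, np.maximum(x - psi, 0.0)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ coef) ** 2))
        if rss < best_rss:
            best_psi, best_rss = psi, rss
    return best_psi


class TestSegmented:
    def test_noiseless_breakpoint_recovered_exactly(self):
        x = np.arange(0.0, 10.01, 0.5)
        y = np.where(x <= 5, x, 5 + 3 * (x - 5))
        fit = segmented_fit(x, y)
        assert abs(fit.psi - 5.0) < 1e-4
        assert fit.slope_left == pytest.approx(1.0, abs=1e-8)
        assert fit.slope_right == pytest.approx(3.0, abs=1e-8)
        assert fit.converged

    def test_pure_line_flagged_degenerate(self):
        x = np.linspace(0, 10, 30)
        fit = segmented_fit(x, 2 * x + 1)
        assert not fit.converged or abs(fit.slope_change) < 1e-8

    def test_matches_grid_oracle_and_unbiased_over_replicates(self):
        cfg0 = ResponseSimConfig(psi_true=550.0, slope_below=0.01,
                                 slope_above=0.05, noise_sd=0.5, n=48,
                                 dose_range=(300.0, 700.0))
        # single replicate vs brute-force grid oracle, same grid spacing
        df = gen_response(cfg0)
        x, y = df["dose"].to_numpy(), df["response"].to_numpy()
        grid = np.linspace(x.min() + 1, x.max() - 1, 400)
        cell = grid[1] - grid[0]
        oracle = grid_oracle_psi(x, y, grid)
        fit = segmented_fit(x, y)
        assert abs(fit.psi - oracle) <= cell

        psis = []
        for seed in range(200):
            d = gen_response(ResponseSimConfig(
                psi_true=550.0, slope_below=0.01, slope_above=0.05,
                noise_sd=0.5, n=48, dose_range=(300.0, 700.0), seed=seed))
            psis.append(segmented_fit(d["dose"].to_numpy(),
                                      d["response"].to_numpy()).psi)
        psis = np.asarray(psis)
        se = psis.std(ddof=1) / np.sqrt(len(psis))
        assert abs(psis.mean() - 550.0) <= 2 * se

    def test_shift_and_scale_equivariance(self):
        d = gen_response(ResponseSimConfig(psi_true=550.0, seed=11))
        x, y = d["dose"].to_numpy(), d["response"].to_numpy()
        f0 = segmented_fit(x, y)
        f_shift = segmented_fit(x + 100.0, y)
        assert f_shift.psi == pytest.approx(f0.psi + 100.0, abs=1e-6)
        f_scale = segmented_fit(x, 3.0 * y)
        assert f_scale.psi == pytest.approx(f0.psi, abs=1e-6)
        assert f_scale.slope_left == pytest.approx(3 * f0.slope_left)
        assert f_scale.slope_right == pytest.approx(3 * f0.slope_right)

    def test_rss_never_worse_than_single_line(self):
        for seed in range(5):
            d = gen_response(ResponseSimConfig(psi_true=500.0, seed=seed,
                                               noise_sd=2.0))
            x, y = d["dose"].to_numpy(), d["response"].to_numpy()
            fit = segmented_fit(x, y)
            coef, *_ = np.linalg.lstsq(np.column_stack([np.ones_like(x), x]),
                                       y, rcond=None)
            rss_line = np.sum((y - coef[0] - coef[1] * x) ** 2)
            assert fit.rss <= rss_line + 1e-9

    def test_input_validation(self):
        with pytest.raises(ValueError, match="6 points"):
            segmented_fit([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError, match="constant"):
            segmented_fit(np.ones(10), np.arange(10.0))


class TestPearsonModified:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = pearson_modified(x, x)
        assert res.r == pytest.approx(1.0)

    def test_reduces_to_classical_without_coords(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        res = pearson_modified(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert res.p_value == pytest.approx(p_ref, abs=1e-12)
        assert res.effective_n == 50 and not res.corrected

    def test_duplicated_sites_halve_effective_n(self, rng):
        n2 = 50
        x0, y0 = rng.normal(size=n2), rng.normal(size=n2)
        coords0 = rng.uniform(0, 10, size=(n2, 2))
        x = np.concatenate([x0, x0])
        y = np.concatenate([y0, y0])
        coords = np.vstack([coords0, coords0])
        res = pearson_modified(x, y, coords)
        assert abs(res.effective_n - n2) / n2 < 0.15

    def test_null_calibration_and_effective_n(self, rng):
        n, reps = 100, 500
        rejections = 0
        eff = []
        for _ in range(reps):
            x, y = rng.normal(size=n), rng.normal(size=n)
            res = pearson_modified(x, y, rng.uniform(size=(n, 2)))
            eff.append(res.effective_n)
            rejections += res.p_value < 0.05
        assert abs(np.mean(eff) - n) / n < 0.10
        assert 0.03 <= rejections / reps <= 0.07

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_modified(np.ones(10), np.arange(10.0))

    def test_undefined_when_effective_n_too_small(self):
        # two distinct sites duplicated many times: massive deflation
        x0 = np.array([0.0, 1.0])
        x = np.tile(x0, 10)
        y = np.tile(np.array([1.0, 0.0]), 10)
        coords = np.tile(np.array([[0.0, 0.0], [1.0, 1.0]]), (10, 1))
        res = pearson_modified(x + np.arange(20) * 1e-9, y, coords)
        assert res.effective_n < 5
        assert np.isfinite(res.r)


class TestAnovaLsd:
    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
        res = anova_lsd(np.r_[a, b], ["a"] * 12 + ["b"] * 15)
        t, _ = sps.ttest_ind(a, b)
        assert res.F == pytest.approx(t**2, abs=1e-10)

    def test_separated_group_gets_own_letter(self, rng):
        vals = np.r_[rng.normal(0, 1, 10), rng.normal(0, 1, 10),
                     rng.normal(10, 1, 10)]
        groups = ["g1"] * 10 + ["g2"] * 10 + ["g3"] * 10
        res = anova_lsd(vals, groups)
        assert res.letters["g1"] == res.letters["g2"]
        assert set(res.letters["g3"]).isdisjoint(set(res.letters["g1"]))

    def test_identical_constant_groups_flagged(self):
        res = anova_lsd([1.0] * 6, ["a", "a", "b", "b", "c", "c"])
        assert res.zero_mse
        assert len({res.letters[g] for g in res.groups}) == 1

    def test_group_size_validation(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            anova_lsd([1.0, 2.0, 3.0], ["a", "a", "b"])

    def test_letters_consistent_with_pairwise_lsd(self, rng):
        """Randomised means vs a brute-force all-pairs check."""
        for trial in range(20):
            t_rng = np.random.default_rng(trial)
            k = int(t_rng.integers(3, 6))
            means = t_rng.uniform(0, 3, size=k)
            vals = np.concatenate(
                [t_rng.normal(m, 1.0, size=8) for m in means]
            )
            groups = np.repeat([f"g{i}" for i in range(k)], 8)
            res = anova_lsd(vals, groups)
            for a, b in itertools.combinations(res.groups, 2):
                shared = set(res.letters[a]) & set(res.letters[b])
                if res.differ(a, b):
                    assert not shared, (trial, a, b, res.letters)
                else:
                    assert shared, (trial, a, b, res.letters)


def test_compact_letter_display_orders_letters_by_mean():
    means = {"hi": 3.0, "mid": 2.0, "lo": 1.0}

    def differ(a, b):
        return abs(means[a] - means[b]) > 1.5

    letters = compact_letter_display(list(means), means, differ)
    assert letters["hi"].startswith("a")
    assert "a" not in letters["lo"]
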