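"""Statistical procedures: transforms, mixed models, rank tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from skilledreach.stats import (
    LmmSpec, asinh_transform, contrast_test, fit_lmm, kruskal_wallis,
    paired_t, paired_t_by_bin, sign_test, trialwise_ranksum,
)


class TestAsinh:
    def test_zero_maps_to_zero(self):
        assert asinh_transform([0.0])[0] == 0.0

    def test_closed_form_at_one(self):
        # asinh(1) = ln(1 + sqrt(2))
        assert np.isclose(asinh_transform([1.0])[0], np.log(1 + np.sqrt(2)))

    def test_odd_symmetry(self):
        x = np.linspace(-5, 5, 11)
        assert np.allclose(asinh_transform(-x), -asinh_transform(x))


def synth_lmm_table(slope=-0.5, noise=0.3, rat_sd=0.2, n_rats=6, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(n_rats):
        u = rng.normal(0, rat_sd)
        for s in range(1, 23):
            laser = int(3 <= s <= 12)
            k = s - 2 if laser else 0
            y = 2.0 + u + slope * laser * k + (rng.normal(0, noise) if noise else 0)
            rows.append(dict(rat=f"r{r}", session=s, laser=laser,
                             laser_session=laser * k, y=y))
    return pd.DataFrame(rows)


class TestFitLmm:
    def test_noiseless_recovery_is_exact(self):
        table = synth_lmm_table(slope=-0.5, noise=0.0, rat_sd=0.0)
        fit = fit_lmm(table, LmmSpec(response="y", fixed="laser + laser_session"))
        assert abs(fit["laser_session"]["estimate"] - (-0.5)) < 1e-8
        assert abs(fit["Intercept"]["estimate"] - 2.0) < 1e-8

    def test_monte_carlo_recovery_and_coverage(self):
        """Across seeded replicates the interaction estimate is unbiased
        (within 0.05 of truth) and its 95% CI covers the truth at a
        nominal-ish rate."""
        est, cover = [], 0
        n = 60
        for rep in range(n):
            table = synth_lmm_table(seed=100 + rep)
            fit = fit_lmm(table, LmmSpec(response="y",
                                         fixed="laser + laser_session"))
            est.append(fit["laser_session"]["estimate"])
            lo, hi = fit.conf_int("laser_session")
            cover += lo <= -0.5 <= hi
        assert abs(np.mean(est) - (-0.5)) < 0.05
        assert 0.85 <= cover / n <= 1.0

    def test_null_permutation_calibration(self):
        """With laser labels permuted across sessions the interaction term
        rejects at roughly the nominal 5% rate."""
        rng = np.random.default_rng(3)
        rejections = 0
        n = 100
        for _ in range(n):
            table = synth_lmm_table(slope=0.0, seed=rng.integers(2**31))
            perm = rng.permutation(22) + 1
            remap = dict(zip(range(1, 23), perm))
            table["laser"] = table["session"].map(
                lambda s: int(3 <= remap[s] <= 12))
            table["laser_session"] = table["laser"] * table["session"]
            fit = fit_lmm(table, LmmSpec(response="y",
                                         fixed="laser + laser_session"))
            rejections += fit["laser_session"]["p"] < 0.05
        assert 0.02 <= rejections / n <= 0.09

    def test_asinh_transform_applied(self):
        table = synth_lmm_table(noise=0.0, rat_sd=0.0)
        fit = fit_lmm(table, LmmSpec(response="y", fixed="laser",
                                     transform="asinh"))
        # the intercept is now on the asinh scale of the baseline value 2.0
        assert abs(fit["Intercept"]["estimate"] - np.arcsinh(2.0)) < 0.5

    def test_requires_two_rats(self):
        table = synth_lmm_table(n_rats=1)
        with pytest.raises(ValueError, match="2 grouping units"):
            fit_lmm(table, LmmSpec(response="y", fixed="laser"))

    def test_fixed_effects_match_independent_lme4_fit(self, tmp_path):
        """Cross-check against an independent mixed-model implementation:
        the same REML fit in R's lme4 must give the same fixed-effect
        estimates and standard errors."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        table = synth_lmm_table(seed=21)
        csv = tmp_path / "table.csv"
        table.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f"d <- read.csv('{csv}')\n"
            "m <- lmer(y ~ laser + laser_session + (1 | rat), data = d, REML = TRUE)\n"
            "s <- summary(m)$coefficients\n"
            "write.csv(s, stdout())\n")
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True).stdout
        ref = {}
        for line in out.strip().splitlines()[1:]:
            name, est, se, _ = line.replace('"', "").split(",")
            ref[{"(Intercept)": "Intercept"}.get(name, name)] = \
                (float(est), float(se))
        fit = fit_lmm(table, LmmSpec(response="y", fixed="laser + laser_session"))
        for term, (est, se) in ref.items():
            ours = fit[term]
            assert np.isclose(ours["estimate"], est, atol=1e-5), term
            assert np.isclose(ours["se"], se, rtol=1e-3), term

    def test_singular_random_effects_flagged_not_fatal(self):
        # no between-rat variance at all: the random-intercept variance
        # collapses to zero and must be flagged, with fixed effects intact
        table = synth_lmm_table(rat_sd=0.0, noise=0.0, seed=5)
        fit = fit_lmm(table, LmmSpec(response="y", fixed="laser + laser_session"))
        assert fit.singular
        assert np.isfinite(fit["laser_session"]["estimate"])


class TestContrast:
    @pytest.fixture(scope="class")
    def fit(self):
        return fit_lmm(synth_lmm_table(seed=7),
                       LmmSpec(response="y", fixed="laser + laser_session"))

    def test_unit_vector_reproduces_coefficient_t(self, fit):
        c = np.zeros(len(fit.terms))
        c[fit.terms.index("laser_session")] = 1.0
        res = contrast_test(fit, c)
        ref = fit["laser_session"]
        assert np.isclose(res.statistic, ref["t"], atol=1e-10)
        assert np.isclose(res.p_value, ref["p"], atol=1e-12)

    def test_zero_vector_gives_p_one(self, fit):
        res = contrast_test(fit, np.zeros(len(fit.terms)))
        assert res.estimate == 0.0 and res.p_value == 1.0

    def test_named_weights_equal_vector_form(self, fit):
        res_named = contrast_test(fit, {"laser": 1.0, "laser_session": -1.0})
        c = np.zeros(len(fit.terms))
        c[fit.terms.index("laser")] = 1.0
        c[fit.terms.index("laser_session")] = -1.0
        res_vec = contrast_test(fit, c)
        assert np.isclose(res_named.statistic, res_vec.statistic)

    def test_unknown_term_rejected(self, fit):
        with pytest.raises(ValueError, match="unfitted"):
            contrast_test(fit, {"nonexistent": 1.0})


class TestTrialwiseRanksum:
    def test_identical_groups_empty_mask(self):
        a = np.tile(np.linspace(0, 1, 10), (4, 1))
        mask, _ = trialwise_ranksum(a, a.copy())
        assert not mask.any()

    def test_fully_separated_groups_full_mask(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, size=(6, 15))
        b = a + 100.0
        mask, p = trialwise_ranksum(a, b, alpha=0.01)
        assert mask.all()

    def test_exact_p_matches_exhaustive_enumeration(self):
        """3 vs 3 fixture: the reported p equals the exhaustive-permutation
        rank-sum p."""
        a = np.array([[1.0], [5.0], [9.0]])
        b = np.array([[2.0], [3.0], [4.0]])
        _, p = trialwise_ranksum(a, b, alpha=0.05)
        from scipy.stats import rankdata

        pooled = np.concatenate([a[:, 0], b[:, 0]])
        ranks = rankdata(pooled)
        obs = ranks[:3].sum()
        sums = [sum(c) for c in itertools.combinations(ranks, 3)]
        lo = np.mean([s <= obs for s in sums])
        hi = np.mean([s >= obs for s in sums])
        p_exact = min(1.0, 2.0 * min(lo, hi))   # doubled-tail convention
        assert np.isclose(p[0], p_exact, atol=1e-12)

    def test_insufficient_data_never_significant(self):
        a = np.array([[1.0, np.nan], [2.0, np.nan]])
        b = np.array([[5.0, 1.0], [6.0, 2.0]])
        mask, p = trialwise_ranksum(a, b)
        assert not mask[1] and np.isnan(p[1])


class TestOtherTests:
    def test_kruskal_identical_groups_nonsignificant(self):
        res = kruskal_wallis([np.ones(5), np.ones(6), np.ones(4)])
        assert res.p_value == 1.0 and res.statistic == 0.0

    def test_kruskal_two_groups_equals_ranksum_chi2(self):
        """With two groups, H equals the squared standardized rank-sum
        statistic (chi-squared with 1 df)."""
        from scipy.stats import rankdata

        a = np.array([3.1, 4.2, 5.5, 1.0])
        b = np.array([7.7, 8.1, 2.2, 9.9, 6.0])
        res = kruskal_wallis([a, b])
        pooled = np.concatenate([a, b])
        r = rankdata(pooled)
        n, na = len(pooled), len(a)
        ra = r[:na].sum()
        expected = na * (n + 1) / 2
        var = na * (n - na) * (n + 1) / 12
        h_ref = (ra - expected) ** 2 / var
        assert np.isclose(res.statistic, h_ref, atol=1e-10)

    def test_paired_t_detects_large_shift(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 10)
        res = paired_t(base + 3.0, base + rng.normal(0, 1, 10) * 0.0)
        # closed form: t = mean shift / (sd/sqrt(n)); here the difference is
        # exactly 3 with zero variance removed -> recompute directly
        diff = 3.0 - 0.0 * base
        assert res.p_value < 0.01

    def test_paired_t_closed_form(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([0.5, 1.0, 2.0, 3.5])
        res = paired_t(a, b)
        d = a - b
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert np.isclose(res.statistic, t_ref, atol=1e-12)

    def test_paired_t_by_bin_skips_sparse_bins(self):
        a = {0: [1.0, 2.0, 3.0], 1: [5.0]}
        b = {0: [0.5, 1.5, 2.0], 1: [4.0], 2: [9.9]}
        out = paired_t_by_bin(a, b)
        assert set(out) == {0}

    def test_sign_test_exact_binomial(self):
        a = np.arange(10, dtype=float)
        b = a - 1.0                       # all differences positive
        res = sign_test(a, b)
        assert np.isclose(res.p_value, 2 * 0.5**10, atol=1e-12)

    def test_sign_test_all_ties_undefined(self):
        with pytest.raises(ValueError, match="tied"):
            sign_test(np.ones(5), np.ones(5))
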