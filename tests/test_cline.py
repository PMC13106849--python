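"""Logistic cline regression: IRLS correctness, inference, battery logic."""

import numpy as np
import pandas as pd
import pytest

from honeygeo import synthdata
from honeygeo.cline import (
    DegenerateFitError,
    code_outcome,
    fit_logistic,
    run_cline_battery,
)

from conftest import make_table


def expit(z):
    return 1.0 / (1.0 + np.exp(-z))


class TestCodeOutcome:
    def test_include_mode_contains(self):
        df = make_table({"ACM": 1, "C": 1, "AM": 1})
        y, kept = code_outcome(df, "contains-A", "include")
        assert len(kept) == 3
        assert y.tolist() == [1.0, 0.0, 1.0]

    def test_exclude_mode_drops_multi_lineage(self):
        df = make_table({"ACM": 2, "AC": 1, "A": 3, "C": 4, "M": 1})
        y, kept = code_outcome(df, "contains-A", "exclude")
        assert len(kept) == 8  # multi-lineage patterns dropped
        assert y.sum() == 3  # the pure-A samples

    def test_only_coding_retains_all_samples(self):
        df = make_table({"ACM": 2, "C": 5, "CM": 1})
        y, kept = code_outcome(df, "only-C", "exclude")
        assert len(kept) == 8
        assert y.sum() == 5

    def test_counts_match_brute_force(self, small_survey):
        for coding, pred in [("contains-A", lambda p: "A" in p),
                             ("contains-M", lambda p: "M" in p),
                             ("only-C", lambda p: p == "C")]:
            y, kept = code_outcome(small_survey, coding)
            brute = sum(pred(p) for p in small_survey["pattern"])
            assert int(y.sum()) == brute

    def test_unknown_coding_rejected(self, small_survey):
        with pytest.raises(ValueError, match="coding"):
            code_outcome(small_survey, "contains-Z")


class TestFitLogistic:
    def test_binary_predictor_equals_log_odds_ratio(self):
        # 2x2 cell counts (a, b; c, d), all > 0: slope = ln(ad/bc)
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b, c, d = rng.integers(3, 200, size=4)
            x = np.r_[np.zeros(a + b), np.ones(c + d)]
            y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
            fit = fit_logistic(y, x)
            assert fit.converged
            assert fit.slope == pytest.approx(np.log(c * b / (a * d)), abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(DegenerateFitError):
            fit_logistic(np.ones(10), x)
        with pytest.raises(DegenerateFitError):
            fit_logistic(np.zeros(10), x)
        with pytest.raises(DegenerateFitError):
            fit_logistic(np.r_[np.ones(5), np.zeros(5)], np.full(10, 2.0))

    def test_complete_separation_flagged(self):
        x = np.arange(20.0)
        y = (x >= 10).astype(float)
        fit = fit_logistic(y, x)
        assert fit.separation
        assert not fit.converged

    def test_parameter_recovery_known_slope(self):
        # y generated with slope -0.3/degree over a 10-degree span
        rng = np.random.default_rng(12)
        n, b0, b1 = 2000, 12.0, -0.3
        x = rng.uniform(38, 48, n)
        y = (rng.random(n) < expit(b0 + b1 * x)).astype(float)
        fit = fit_logistic(y, x)
        assert fit.converged
        assert abs(fit.slope - b1) < 3 * fit.se_slope

    def test_gradient_vanishes_at_convergence(self):
        rng = np.random.default_rng(3)
        n = 500
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(0.2 + 0.8 * x)).astype(float)
        fit = fit_logistic(y, x)
        assert fit.converged
        mu = expit(fit.intercept + fit.slope * x)
        grad = np.array([(y - mu).sum(), ((y - mu) * x).sum()])
        assert np.abs(grad).max() < 1e-6 * n

    def test_lr_chi2_nonnegative_and_wald_close(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=800)
        y = (rng.random(800) < expit(0.5 * x)).astype(float)
        fit = fit_logistic(y, x)
        assert fit.lr_chi2 >= 0
        # Wald and LR agree to first order for a well-behaved fit
        assert fit.lr_chi2 == pytest.approx(fit.wald_z**2, rel=0.2)

    def test_matches_reference_glm_on_random_data(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(99)
        for _ in range(50):
            n = int(rng.integers(80, 400))
            b0 = rng.normal(0, 0.5)
            b1 = rng.normal(0, 0.8)
            x = rng.normal(size=n)
            y = (rng.random(n) < expit(b0 + b1 * x)).astype(float)
            if y.sum() in (0, n):
                continue
            fit = fit_logistic(y, x)
            ref = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
            assert fit.slope == pytest.approx(ref.params[1], rel=1e-6, abs=1e-9)
            assert fit.se_slope == pytest.approx(ref.bse[1], rel=1e-5)


class TestBattery:
    def test_sign_of_synthetic_latitudinal_cline(self, drift_survey):
        fits = run_cline_battery(drift_survey)
        pooled = fits[(fits.year == "all") & (fits.predictor == "latitude")]
        a = pooled[(pooled.coding == "contains-A") & (pooled.subset == "Peninsula")]
        c = pooled[(pooled.coding == "only-C") & (pooled.subset == "Peninsula")]
        # A rises southward -> negative latitude slope; only-C the reverse
        assert float(a["slope"].iloc[0]) < 0
        assert float(c["slope"].iloc[0]) > 0
        assert float(a["lr_p"].iloc[0]) < 0.001

    def test_high_A_island_raises_model_chi2(self, drift_survey):
        fits = run_cline_battery(drift_survey)
        pooled = fits[
            (fits.year == "all") & (fits.predictor == "latitude")
            & (fits.coding == "contains-A")
        ].set_index("subset")
        assert pooled.loc["Peninsula+Sicily", "lr_chi2"] > pooled.loc["Peninsula", "lr_chi2"]

    def test_degenerate_subsets_recorded_as_skipped(self):
        df = make_table({"C": 30}, macro="North")
        df["latitude"] = np.linspace(44, 46, 30)
        df["year"] = 2020
        fits = run_cline_battery(df, codings=("contains-A",), per_year=False)
        assert len(fits) > 0
        assert fits["skipped"].all()

    def test_year_fits_respect_cell_threshold(self, drift_survey):
        fits = run_cline_battery(drift_survey, year_cell_min=100)
        year_fits = fits[fits.predictor == "year"]
        cell = drift_survey.groupby(["macro_region", "year"]).size()
        for _, row in year_fits.iterrows():
            macros = {"North": ["North"], "Central+South": ["Central", "South"]}[row["subset"]]
            sizes = cell.loc[macros].groupby("year").sum()
            assert row["n"] == int(sizes[sizes > 100].sum())

    def test_battery_shape(self, small_survey):
        codings = ("contains-A", "only-C")
        fits = run_cline_battery(small_survey, codings=codings, per_year=False)
        # per coding: 3 latitude subsets + 1 longitude fit, plus <=2 year fits
        per_coding = fits.groupby("coding").size()
        assert set(per_coding.index) == set(codings)
        assert (per_coding >= 4).all() and (per_coding <= 6).all()


def test_null_type_one_error_rate():
    """LR test rejects at roughly the nominal rate when y is independent of x."""
    rng = np.random.default_rng(2024)
    n, reps = 10_000, 500
    rej = 0
    for _ in range(reps):
        x = rng.normal(size=n)
        y = (rng.random(n) < 0.3).astype(float)
        fit = fit_logistic(y, x)
        rej += fit.lr_p < 0.05
    rate = rej / reps
    se = np.sqrt(0.05 * 0.95 / reps)
    assert abs(rate - 0.05) < 3 * se
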