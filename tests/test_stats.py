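"""Robust MM regression, bootstrap/permutation inference, moderation."""

import os
import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest

import capdyn as cd
from capdyn.errors import InputError
from capdyn.stats import bisquare_weights

LIGHT = dict(n_subsets=10, s_refine=1)


def _design(n, seed, p_extra=2):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n)] + [rng.normal(size=n) for _ in range(p_extra)])
    return rng, X


def _pheno(n, rng, outcome):
    return pd.DataFrame({"y": outcome, "rnt": rng.normal(size=n),
                         "neu": rng.normal(size=n),
                         "age": rng.normal(23, 4, n),
                         "sex": rng.choice(["F", "M"], size=n)})


def test_exact_linear_data_is_a_zero_residual_fixed_point():
    x = np.linspace(-3, 3, 40)
    fit = cd.mm_fit(2 * x, np.column_stack([np.ones(40), x]))
    assert fit.coef == pytest.approx([0.0, 2.0], abs=1e-12)
    assert np.all(fit.weights == 1.0)
    assert fit.scale == 0.0
    assert fit.r2_weighted == 1.0


def test_mm_matches_ols_on_clean_gaussian_data():
    """Without contamination the MM estimate must track OLS closely —
    within 3 Monte-Carlo standard errors of the slope at n = 200."""
    diffs = []
    for seed in range(20):
        rng, X = _design(200, seed)
        y = 1.0 + 0.5 * X[:, 1] - 0.2 * X[:, 2] + rng.normal(size=200)
        mm = cd.mm_fit(y, X).coef
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        diffs.append(np.abs(mm - ols).max())
    mc_se = 1 / np.sqrt(200)
    assert np.max(diffs) < 3 * mc_se


def test_mm_resists_gross_outliers_better_than_ols():
    """10% gross outliers placed at high-leverage points, so they bias the
    OLS slope; the bisquare MM fit must be closer to the truth every time."""
    wins = 0
    reps = 30
    for seed in range(reps):
        rng, X = _design(150, 100 + seed)
        y = 2.0 * X[:, 1] + rng.normal(size=150)
        bad = np.argsort(X[:, 1])[-15:]
        y[bad] += 20
        mm = cd.mm_fit(y, X, **LIGHT).coef[1]
        ols = np.linalg.lstsq(X, y, rcond=None)[0][1]
        wins += abs(mm - 2.0) < abs(ols - 2.0)
    assert wins == reps


def test_mm_agrees_with_mass_rlm_oracle():
    """Independent oracle: MASS::rlm(method='MM') with bisquare psi."""
    rng, X = _design(110, 7)
    y = 1.0 + 2.0 * X[:, 1] - 0.5 * X[:, 2] + rng.normal(size=110)
    y[rng.choice(110, 11, replace=False)] += 15
    fit = cd.mm_fit(y, X)
    with tempfile.TemporaryDirectory() as d:
        path = os.path.join(d, "d.csv")
        pd.DataFrame({"y": y, "x1": X[:, 1], "x2": X[:, 2]}).to_csv(path, index=False)
        out = subprocess.run(
            ["Rscript", "-e",
             f'd<-read.csv("{path}");'
             'm<-MASS::rlm(y~x1+x2,data=d,method="MM",psi=MASS::psi.bisquare,maxit=200);'
             'cat(coef(m))'],
            capture_output=True, text=True, check=True)
    oracle = np.array([float(v) for v in out.stdout.split()])
    assert fit.coef == pytest.approx(oracle, abs=0.02)


def test_weights_lie_in_unit_interval_and_shrink_with_residuals():
    u = np.linspace(0, 10, 200)
    w = bisquare_weights(u, 4.6851)
    assert np.all((w >= 0) & (w <= 1))
    assert np.all(np.diff(w) <= 1e-12)
    assert w[0] == 1.0 and w[-1] == 0.0


def test_rank_deficient_design_rejected():
    rng, X = _design(30, 0)
    X = np.column_stack([X, X[:, 1]])
    with pytest.raises(InputError):
        cd.mm_fit(rng.normal(size=30), X)


def test_degenerate_bootstrap_has_zero_width_ci():
    x = np.linspace(0, 1, 25)
    X = np.column_stack([np.ones(25), x])
    draws = cd.bootstrap_coefs(3 * x, X, n_boot=50, seed=0, **LIGHT)
    ci = cd.percentile_ci(draws)
    assert np.allclose(ci[:, 0], ci[:, 1])
    assert np.allclose(draws[:, 1], 3.0)


def test_bootstrap_is_seed_reproducible():
    rng, X = _design(40, 3)
    y = X[:, 1] + rng.normal(size=40)
    a = cd.bootstrap_coefs(y, X, n_boot=30, seed=11, **LIGHT)
    b = cd.bootstrap_coefs(y, X, n_boot=30, seed=11, **LIGHT)
    assert np.array_equal(a, b)


def test_moderation_recovers_planted_interaction_sign():
    rng = np.random.default_rng(21)
    n = 200
    df = _pheno(n, rng, np.zeros(n))
    sex = (df["sex"] == "F").astype(float)
    df["y"] = (0.4 * df["rnt"] - 0.35 * df["rnt"] * df["neu"]
               + 0.02 * df["age"] + 0.1 * sex + rng.normal(scale=0.5, size=n))
    rep = cd.moderation(df, "y", n_boot=400, seed=1, **LIGHT)
    t = rep.terms
    assert t.loc["rnt_x_neu", "B"] < 0
    assert t.loc["rnt_x_neu", "ci_high"] < 0
    assert t.loc["rnt", "ci_low"] > 0
    assert t.loc["rnt_x_neu", "p"] < 0.05


def test_moderation_null_interaction_ci_covers_zero():
    rng = np.random.default_rng(33)
    n = 150
    df = _pheno(n, rng, np.zeros(n))
    df["y"] = 0.3 * df["rnt"] + rng.normal(size=n)
    rep = cd.moderation(df, "y", n_boot=400, seed=2, **LIGHT)
    lo, hi = rep.terms.loc["rnt_x_neu", ["ci_low", "ci_high"]]
    assert lo <= 0 <= hi


def test_moderation_slopes_invariant_to_age_shift():
    rng = np.random.default_rng(5)
    n = 120
    df = _pheno(n, rng, rng.normal(size=n))
    a = cd.moderation(df, "y", n_boot=0, **LIGHT).terms["B"]
    df2 = df.assign(age=df["age"] + 100.0)
    b = cd.moderation(df2, "y", n_boot=0, **LIGHT).terms["B"]
    keep = [t for t in a.index if t != "intercept"]
    assert np.allclose(a[keep], b[keep], atol=1e-6)


def test_standardized_beta_invariant_to_predictor_rescaling():
    rng = np.random.default_rng(6)
    n = 120
    df = _pheno(n, rng, rng.normal(size=n))
    a = cd.moderation(df, "y", n_boot=0, **LIGHT).terms["beta"]
    b = cd.moderation(df.assign(age=df["age"] * 10), "y", n_boot=0, **LIGHT).terms["beta"]
    assert a["age"] == pytest.approx(b["age"], abs=1e-6)


def test_simple_slopes_arithmetic_and_errors():
    rng = np.random.default_rng(9)
    n = 150
    df = _pheno(n, rng, np.zeros(n))
    df["y"] = df["rnt"] - 0.5 * df["rnt"] * df["neu"] + rng.normal(scale=0.3, size=n)
    rep = cd.moderation(df, "y", n_boot=200, seed=3, **LIGHT)
    slopes = cd.simple_slopes(rep)
    b_rnt = rep.terms.loc["rnt", "B"]
    b_int = rep.terms.loc["rnt_x_neu", "B"]
    sd = rep.moderator_sd
    expected = {-1.0: b_rnt - sd * b_int, 1.0: b_rnt + sd * b_int}
    for row in slopes.itertuples():
        assert row.slope == pytest.approx(expected[row.moderator_level_sd])
    assert slopes.set_index("moderator_level_sd").loc[1.0, "slope"] < \
           slopes.set_index("moderator_level_sd").loc[-1.0, "slope"]
    no_int = cd.moderation(df, "y", n_boot=0, include_interaction=False, **LIGHT)
    with pytest.raises(InputError):
        cd.simple_slopes(no_int)


def test_zero_interaction_gives_equal_simple_slopes():
    """With a zero interaction coefficient the conditional slope no longer
    depends on the moderator level."""
    rng = np.random.default_rng(12)
    n = 100
    df = _pheno(n, rng, np.zeros(n))
    df["y"] = 0.8 * df["rnt"] + rng.normal(scale=0.1, size=n)
    rep = cd.moderation(df, "y", n_boot=100, seed=4, **LIGHT)
    j = rep.term_names.index("rnt_x_neu")
    rep.fit.coef[j] = 0.0
    rep.boot_coefs[:, j] = 0.0
    slopes = cd.simple_slopes(rep)["slope"]
    assert slopes.iloc[0] == pytest.approx(slopes.iloc[1], abs=1e-12)


def test_polynomial_comparison_no_signal_limit():
    """On exactly linear noiseless data both models fit perfectly, so the
    R-squared gain from the quadratic term is numerically zero."""
    rng = np.random.default_rng(14)
    n = 60
    df = _pheno(n, rng, np.zeros(n))
    sex = (df["sex"] == "F").astype(float)
    df["y"] = 2 * df["rnt"] + 0.5 * df["neu"] + 0.1 * df["age"] + sex
    mc = cd.compare_polynomial(df, "y", n_boot=20, n_perm=20, seed=0, **LIGHT)
    assert abs(mc.delta_r2) < 1e-6


def test_polynomial_comparison_detects_strong_quadratic():
    rng = np.random.default_rng(15)
    n = 120
    df = _pheno(n, rng, np.zeros(n))
    df["y"] = 0.2 * df["rnt"] + 1.5 * (df["rnt"] - df["rnt"].mean()) ** 2 \
        + rng.normal(scale=0.5, size=n)
    mc = cd.compare_polynomial(df, "y", n_boot=50, n_perm=199, seed=1, **LIGHT)
    assert mc.p_perm < 0.05
    assert mc.delta_bic < 0
    assert mc.delta_r2 > 0


def test_cap_to_cap_identity_regression():
    rng = np.random.default_rng(16)
    n = 80
    df = pd.DataFrame({"a": rng.normal(size=n), "age": rng.normal(23, 4, n),
                       "sex": rng.choice(["F", "M"], n)})
    df["b"] = df["a"]
    rep = cd.cap_to_cap(df, outcome="b", predictor="a", n_boot=50, seed=0, **LIGHT)
    assert rep.terms.loc["a", "B"] == pytest.approx(1.0, abs=1e-10)
    assert rep.fit.r2_weighted == pytest.approx(1.0)


def test_cap_to_cap_recovers_negative_coupling():
    rng = np.random.default_rng(17)
    n = 150
    a = rng.normal(size=n)
    df = pd.DataFrame({"a": a, "b": -0.8 * a + rng.normal(scale=0.4, size=n),
                       "age": rng.normal(23, 4, n), "sex": rng.choice(["F", "M"], n)})
    rep = cd.cap_to_cap(df, outcome="b", predictor="a", n_boot=300, seed=1, **LIGHT)
    assert rep.terms.loc["a", "ci_high"] < 0


@pytest.mark.parametrize("p,expected", [
    ([0.5], [0.5]),
    ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
    ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
])
def test_fdr_adjust_examples(p, expected):
    assert cd.fdr_adjust(p) == pytest.approx(expected)


def test_fdr_rejects_invalid_p():
    with pytest.raises(InputError):
        cd.fdr_adjust([0.5, 1.5])
    with pytest.raises(InputError):
        cd.fdr_adjust([])
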