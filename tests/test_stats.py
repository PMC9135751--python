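"""Statistical engine: screens, GEE, LS-means, FDR, ICC, growth fits, batteries."""

import numpy as np
import pandas as pd
import pytest

from fetalfold import (
    CohortSpec,
    GEESpec,
    ValidationError,
    bh_fdr,
    battery_sizes,
    chi_square,
    enumerate_models,
    fit_gee,
    growth_fit,
    icc_agreement,
    ls_means,
    mann_whitney,
    normality_screen,
    run_battery,
    simulate_cohort,
)


# -- normality screen ----------------------------------------------------------


def test_shapiro_type_one_error_calibrated():
    rng = np.random.default_rng(0)
    rejections = sum(
        normality_screen(rng.normal(size=100)) < 0.05 for _ in range(1000)
    )
    assert 0.03 <= rejections / 1000 <= 0.07


def test_shapiro_power_against_lognormal():
    rng = np.random.default_rng(1)
    rejections = sum(
        normality_screen(rng.lognormal(0, 1, size=100)) < 0.05 for _ in range(500)
    )
    assert rejections / 500 > 0.9


def test_shapiro_rejects_constant_sample():
    with pytest.raises(ValidationError):
        normality_screen(np.ones(10))


# -- rank / categorical tests --------------------------------------------------


def test_mann_whitney_u_identity_with_ties():
    rng = np.random.default_rng(2)
    x = rng.integers(0, 5, 12).astype(float)
    y = rng.integers(0, 5, 9).astype(float)
    u_xy, _ = mann_whitney(x, y)
    u_yx, _ = mann_whitney(y, x)
    assert u_xy + u_yx == pytest.approx(len(x) * len(y))


def test_mann_whitney_exact_small_sample():
    _, p = mann_whitney([1, 2, 3], [4, 5, 6])
    assert p == pytest.approx(0.1)


def test_mann_whitney_identical_samples_null():
    x = np.arange(20, dtype=float)
    _, p = mann_whitney(x, x + 0.0)
    assert p >= 0.99


def test_chi_square_proportional_rows_null():
    stat, p = chi_square([[10, 20, 30], [20, 40, 60]])
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_chi_square_hand_computed_2x2():
    stat, _ = chi_square([[10, 20], [20, 10]])
    assert stat == pytest.approx(20 / 3)


def test_chi_square_permutation_invariant():
    t = np.array([[5, 9, 2], [7, 3, 11]])
    s1, _ = chi_square(t)
    s2, _ = chi_square(t[::-1])
    s3, _ = chi_square(t[:, [2, 0, 1]])
    assert s1 == pytest.approx(s2) == pytest.approx(s3)


# -- BH-FDR --------------------------------------------------------------------


def _bh_oracle(p):
    """Brute-force step-up q-values: q_(i) = min_{j >= i} m * p_(j) / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        tail = [m * p[order[j - 1]] / j for j in range(rank_pos, m + 1)]
        q[idx] = min(min(tail), 1.0)
    return q


def test_single_p_is_its_own_q():
    assert bh_fdr([0.037]).qvalues[0] == pytest.approx(0.037)


def test_equal_ps_share_q():
    res = bh_fdr([0.02, 0.02, 0.02])
    assert np.allclose(res.qvalues, 0.02)


def test_example_family_matches_oracle():
    p = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06]
    assert np.allclose(bh_fdr(p).qvalues, _bh_oracle(p))


def test_random_families_match_oracle_with_invariants():
    rng = np.random.default_rng(3)
    for _ in range(50):
        p = rng.random(rng.integers(1, 12))
        q = bh_fdr(p).qvalues
        assert np.allclose(q, _bh_oracle(p))
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)


def test_grid_of_six_long_p_vectors_matches_oracle():
    grid = (0.004, 0.04, 0.4)
    for bits in range(2**6):
        p = [grid[(bits >> k) % 3] for k in range(6)]
        assert np.allclose(bh_fdr(p).qvalues, _bh_oracle(p))


def test_invalid_p_rejected():
    with pytest.raises(ValidationError):
        bh_fdr([0.5, 1.2])


# -- ICC -----------------------------------------------------------------------


def test_identical_raters_give_icc_one():
    rng = np.random.default_rng(4)
    a = rng.normal(size=20)
    assert icc_agreement(np.column_stack([a, a])) == pytest.approx(1.0)


def test_independent_noise_has_icc_near_zero():
    rng = np.random.default_rng(5)
    r = rng.normal(size=(1000, 2))
    assert abs(icc_agreement(r)) < 0.1


def test_toy_matrix_matches_hand_anova_and_pingouin():
    ratings = np.array(
        [[9, 2], [1, 10], [8, 8], [2, 6], [10, 6], [6, 2]], dtype=float
    )
    ours = icc_agreement(ratings)

    # hand mean-squares decomposition
    n, k = ratings.shape
    grand = ratings.mean()
    msr = k * ((ratings.mean(1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((ratings.mean(0) - grand) ** 2).sum() / (k - 1)
    sse = (
        (ratings - ratings.mean(1, keepdims=True)
         - ratings.mean(0, keepdims=True) + grand) ** 2
    ).sum()
    mse = sse / ((n - 1) * (k - 1))
    expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    assert ours == pytest.approx(expected, abs=1e-12)

    pingouin = pytest.importorskip("pingouin")
    long = pd.DataFrame(
        {
            "item": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": ratings.ravel(),
        }
    )
    table = pingouin.intraclass_corr(
        data=long, targets="item", raters="rater", ratings="score"
    )
    # two-way random, absolute agreement, single measure
    icc2 = table.loc[table["Type"].isin(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0]
    assert ours == pytest.approx(icc2, abs=1e-9)


def test_icc_requires_enough_items():
    with pytest.raises(ValidationError):
        icc_agreement(np.ones((2, 2)))


# -- growth fits ---------------------------------------------------------------


def test_exponential_fit_recovers_parameters():
    ga = np.linspace(18, 38, 40)
    y = 2.0 * np.exp(0.1 * ga)
    fit = growth_fit(ga, y, "exponential")
    assert fit.intercept == pytest.approx(np.log(2.0), abs=1e-8)
    assert fit.slope == pytest.approx(0.1, abs=1e-10)


def test_linear_fit_exact_on_line():
    ga = np.linspace(18, 38, 10)
    fit = growth_fit(ga, 3.0 + 0.5 * ga, "linear")
    assert fit.intercept == pytest.approx(3.0)
    assert fit.slope == pytest.approx(0.5)


def test_exponential_fit_rejects_nonpositive():
    with pytest.raises(ValidationError):
        growth_fit([20, 30], [1.0, -0.5], "exponential")


# -- GEE -----------------------------------------------------------------------


def _singleton_frame(n=60, seed=6):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "cohort": rng.integers(0, 2, n),
            "ga_mri_weeks": rng.uniform(17, 39, n),
            "sex": rng.integers(0, 2, n),
        }
    )
    df["wm"] = (
        50 + 2.0 * df.ga_mri_weeks - 4.0 * df.cohort + 1.5 * df.sex
        + rng.normal(0, 3, n)
    )
    return df


def test_singleton_clusters_equal_ols():
    df = _singleton_frame()
    spec = GEESpec(outcome="wm", covariates=("cohort", "ga_mri_weeks", "sex"))
    fit = fit_gee(df, spec)
    X = np.column_stack(
        [np.ones(len(df)), df.cohort, df.ga_mri_weeks, df.sex]
    )
    beta = np.linalg.solve(X.T @ X, X.T @ df.wm.to_numpy())
    assert np.allclose(fit.params.to_numpy(), beta, atol=1e-8)


def test_constant_outcome_gives_zero_slopes():
    df = _singleton_frame()
    df["wm"] = 7.5
    fit = fit_gee(df, GEESpec(outcome="wm", covariates=("cohort", "ga_mri_weeks", "sex")))
    assert fit.params["intercept"] == pytest.approx(7.5, abs=1e-8)
    assert np.allclose(fit.params[["cohort", "ga_mri_weeks", "sex"]], 0, atol=1e-8)


def test_rank_deficient_design_rejected():
    df = _singleton_frame()
    df["sex"] = df["cohort"]
    with pytest.raises(ValidationError):
        fit_gee(df, GEESpec(outcome="wm", covariates=("cohort", "ga_mri_weeks", "sex")))


def test_too_few_clusters_rejected():
    df = _singleton_frame().iloc[:1]
    with pytest.raises(ValidationError):
        fit_gee(df, GEESpec(outcome="wm", covariates=("cohort", "ga_mri_weeks", "sex")))


def test_lsmean_difference_equals_cohort_beta():
    sim = simulate_cohort(CohortSpec(n_subjects={"pre": 60, "pandemic": 40}, seed=8))
    fit = fit_gee(
        sim.records, GEESpec(outcome="wm", covariates=("cohort", "ga_mri_weeks", "sex"))
    )
    lsm = ls_means(fit)
    diff = lsm.loc[1, "lsmean"] - lsm.loc[0, "lsmean"]
    assert diff == pytest.approx(fit.params["cohort"], abs=1e-10)


def test_balanced_orthogonal_design_lsmeans_equal_group_means():
    # cohort balanced and orthogonal to the (centred) covariate
    n = 40
    cov = np.tile([-1.0, 1.0], n // 2)
    cohort = np.repeat([0.0, 1.0], n // 2)
    cov = np.concatenate([cov[: n // 2], cov[: n // 2]])
    y = 10 + 3 * cohort + 0.5 * cov
    df = pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "cohort": cohort,
            "x": cov,
            "y": y,
            "sex": 0.0,
        }
    )
    fit = fit_gee(df, GEESpec(outcome="y", covariates=("cohort", "x")))
    lsm = ls_means(fit)
    assert lsm.loc[0, "lsmean"] == pytest.approx(10.0, abs=1e-8)
    assert lsm.loc[1, "lsmean"] == pytest.approx(13.0, abs=1e-8)


def test_five_row_toy_matches_manual_normal_equations():
    df = pd.DataFrame(
        {
            "subject_id": list("abcde"),
            "cohort": [0, 0, 1, 1, 1],
            "x": [1.0, 2.0, 3.0, 4.0, 5.0],
            "y": [2.0, 2.9, 5.1, 6.2, 6.8],
        }
    )
    fit = fit_gee(df, GEESpec(outcome="y", covariates=("cohort", "x")))
    X = np.column_stack([np.ones(5), df.cohort, df.x])
    beta = np.linalg.solve(X.T @ X, X.T @ df.y.to_numpy())
    assert np.allclose(fit.params.to_numpy(), beta, atol=1e-10)
    lsm = ls_means(fit)
    xref = X.mean(axis=0)
    for level, row in zip((0.0, 1.0), lsm.itertuples()):
        xr = xref.copy()
        xr[1] = level
        assert row.lsmean == pytest.approx(float(xr @ beta), abs=1e-10)


def test_exchangeable_correlation_within_valid_range():
    sim = simulate_cohort(CohortSpec(n_subjects={"pre": 80, "pandemic": 50}, seed=9))
    fit = fit_gee(
        sim.records, GEESpec(outcome="wm", covariates=("cohort", "ga_mri_weeks", "sex"))
    )
    assert -1.0 < fit.working_correlation < 1.0
    assert fit.correlation_structure.startswith("exchangeable")


# -- battery enumeration -------------------------------------------------------


def test_battery_sizes_match_analysis_plan():
    assert battery_sizes() == {
        "step1": 12,
        "step2": 90,
        "step3": 36,
        "distress_association": 72,
        "interaction": 12,
        "sensitivity": 180,
        "laterality": 36,
        "parental": 72,
    }


def test_step2_composition():
    specs = enumerate_models("step2")
    unadjusted = [s for s in specs if len(s.covariates) == 3]
    adjusted = [s for s in specs if len(s.covariates) == 4]
    assert len(unadjusted) == 18
    assert len(adjusted) == 72


def test_step3_composition_uses_explicit_measures():
    specs = enumerate_models("step3")
    assert len(specs) == 36
    assert {s.subset.split()[0] for s in specs} == {"pss", "epds"}
    volumes = [s for s in specs if "global" not in s.outcome]
    assert len(volumes) == 24


def test_enumeration_is_deterministic_and_order_stable():
    a = enumerate_models("sensitivity")
    b = enumerate_models("sensitivity")
    assert [(s.outcome, s.subset, s.covariates) for s in a] == [
        (s.outcome, s.subset, s.covariates) for s in b
    ]


def test_unknown_battery_rejected():
    with pytest.raises(ValidationError):
        enumerate_models("step4")


def test_fdr_families_have_expected_sizes():
    from collections import Counter

    specs = enumerate_models("step2")
    sizes = Counter(s.fdr_family for s in specs)
    assert sorted(sizes.values()) == sorted([6] * 5 + [4] * 15)


def test_run_battery_grid_shape_and_flags():
    sim = simulate_cohort(
        CohortSpec(n_subjects={"pre": 60, "pandemic": 40},
                   feature_missing_fraction=0.1, seed=10)
    )
    out = run_battery(sim.records, enumerate_models("step1"), with_lsmeans=True)
    assert len(out) == 12
    assert {"beta", "se", "p", "q", "bold_p", "fdr_pass"} <= set(out.columns)
    assert (out["q"] >= out["p"] - 1e-12).all()
    assert ((out["q"] <= 1) & (out["q"] >= 0)).all()
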