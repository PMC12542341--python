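"""Differential-methylation engine: linear-model fits against a
normal-equations oracle, variance shrinkage behaviour and parameter
recovery, BH against the brute-force step-up definition, and planted-DMP
recovery on simulated cohorts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from methmir import (
    BetaMatrix,
    SampleSheet,
    SimulationConfig,
    ValidationError,
    bh_adjust,
    delta_beta,
    ebayes_moderate,
    exclude_sex_dependent_probes,
    fit_linear_models,
    moderated_t,
    run_dmp_analysis,
    simulate_study,
)
from methmir.dmp import ModelFit, VarianceShrinkage, call_dmps, trigamma_inverse
from methmir.io import ProbeAnnotation


def _beta(values, sample_ids):
    df = pd.DataFrame(
        values,
        index=pd.Index([f"cg{i}" for i in range(len(values))], name="probe_id"),
        columns=sample_ids,
    )
    return BetaMatrix(df)


def bh_bruteforce(p):
    """min over j >= i of p_(j) * n / j, mapped back to input order."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    out = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        running = min(running, p[order[rank]] * n / (rank + 1))
        out[order[rank]] = running
    return out


# ---------------------------------------------------------------------------
# linear model fits
# ---------------------------------------------------------------------------


def test_constant_betas_give_zero_effect_and_variance(toy_sheet):
    beta = _beta(np.full((4, 6), 0.5), toy_sheet.sample_ids)
    fit = fit_linear_models(beta, toy_sheet)
    assert np.allclose(fit.coef["group"], 0.0)
    assert np.allclose(fit.sigma2, 0.0)


def test_fit_matches_normal_equations_oracle(toy_sheet):
    rng = np.random.default_rng(3)
    values = rng.uniform(0.1, 0.9, (5, 6))
    beta = _beta(values, toy_sheet.sample_ids)
    fit = fit_linear_models(beta, toy_sheet)
    g = (toy_sheet.group == "iDCM").to_numpy(float)
    s = (toy_sheet.sex == "M").to_numpy(float)
    X = np.column_stack([np.ones(6), g, s])
    for i in range(5):
        coef = np.linalg.solve(X.T @ X, X.T @ values[i])
        assert np.allclose(fit.coef.iloc[i].to_numpy(), coef, atol=1e-10)
        resid = values[i] - X @ coef
        assert np.isclose(fit.sigma2[i], resid @ resid / (6 - 3), atol=1e-12)


def test_single_sex_drops_covariate_with_warning():
    sheet = SampleSheet(
        pd.DataFrame(
            {"group": ["CNT"] * 3 + ["iDCM"] * 3, "sex": ["M"] * 6},
            index=pd.Index([f"S{i}" for i in range(6)], name="sample_id"),
        )
    )
    beta = _beta(np.random.default_rng(0).uniform(0.2, 0.8, (3, 6)), sheet.sample_ids)
    with pytest.warns(UserWarning, match="single level"):
        fit = fit_linear_models(beta, sheet)
    assert fit.design_columns == ["intercept", "group"]
    assert fit.df_residual == 4


def test_sex_confounded_with_group_raises():
    sheet = SampleSheet(
        pd.DataFrame(
            {"group": ["CNT"] * 3 + ["iDCM"] * 3, "sex": ["M"] * 3 + ["F"] * 3},
            index=pd.Index([f"S{i}" for i in range(6)], name="sample_id"),
        )
    )
    beta = _beta(np.random.default_rng(0).uniform(0.2, 0.8, (3, 6)), sheet.sample_ids)
    with pytest.raises(ValidationError, match="confounded"):
        fit_linear_models(beta, sheet)


def test_too_few_samples_per_group_raises(toy_sheet):
    sheet = SampleSheet(toy_sheet.df.iloc[[0, 3, 4, 5]])
    beta = _beta(np.full((2, 4), 0.4), sheet.sample_ids)
    with pytest.raises(ValidationError, match="at least 2"):
        fit_linear_models(beta, sheet)


# ---------------------------------------------------------------------------
# sex-dependent probe exclusion
# ---------------------------------------------------------------------------


def test_zero_sex_effect_probe_retained_and_unchanged(toy_sheet):
    rng = np.random.default_rng(5)
    g = (toy_sheet.group == "iDCM").to_numpy(float)
    # betas depend on group only; the sex coefficient is ~0
    values = np.clip(0.4 + 0.1 * g + rng.normal(0, 0.01, (20, 6)), 0, 1)
    beta = _beta(values, toy_sheet.sample_ids)
    fit = fit_linear_models(beta, toy_sheet)
    adj, excluded = exclude_sex_dependent_probes(fit, beta, toy_sheet)
    assert len(excluded) == 0
    assert np.allclose(adj.values.to_numpy(), values, atol=0.05)
    assert (adj.values.to_numpy() >= 0).all() and (adj.values.to_numpy() <= 1).all()


def test_planted_sex_shift_is_excluded_reliably():
    """A 0.3 sex shift at n=15 should be caught in >= 95% of replicates."""
    n = 15
    rng = np.random.default_rng(11)
    sexes = np.array(["M"] * 8 + ["F"] * 7)
    groups = np.array(["CNT"] * 7 + ["iDCM"] * 8)
    sheet = SampleSheet(
        pd.DataFrame(
            {"group": groups, "sex": sexes},
            index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"),
        )
    )
    male = (sexes == "M").astype(float)
    hits = 0
    n_rep = 200
    for _ in range(n_rep):
        values = rng.uniform(0.3, 0.7, (50, 1)) + rng.normal(0, 0.03, (50, n))
        values[0] += 0.3 * male  # planted sex-dependent probe
        beta = _beta(np.clip(values, 0, 1), sheet.sample_ids)
        fit = fit_linear_models(beta, sheet)
        _, excluded = exclude_sex_dependent_probes(fit, beta, sheet)
        hits += "cg0" in excluded
    assert hits / n_rep >= 0.95


# ---------------------------------------------------------------------------
# empirical Bayes moderation
# ---------------------------------------------------------------------------


def _fits_from_s2(s2, d=10):
    n = len(s2)
    ids = pd.Index([f"f{i}" for i in range(n)])
    coef = pd.DataFrame({"intercept": np.zeros(n), "group": np.zeros(n)}, index=ids)
    return ModelFit(ids, coef, np.asarray(s2, float), d,
                    pd.Series([1.0, 1.0], index=["intercept", "group"]),
                    ["intercept", "group"])


def test_equal_variances_give_infinite_prior_df():
    fit = _fits_from_s2(np.full(100, 0.02))
    shrink = ebayes_moderate(fit)
    assert np.isinf(shrink.d0)
    assert np.allclose(shrink.s2_post, 0.02, rtol=1e-10)


def test_all_zero_variances_raise():
    with pytest.raises(ValidationError, match="zero"):
        ebayes_moderate(_fits_from_s2(np.zeros(10)))


def test_ebayes_recovers_planted_prior():
    """s2 ~ s0^2 * chisq_d / d scaled by gene variances from the d0=4 prior."""
    rng = np.random.default_rng(42)
    d0, s0_sq, d, n = 4.0, 0.01, 10, 5000
    true_var = s0_sq * d0 / rng.chisquare(d0, n)
    s2 = true_var * rng.chisquare(d, n) / d
    shrink = ebayes_moderate(_fits_from_s2(s2, d=d))
    assert abs(shrink.d0 - d0) <= 1.0
    assert abs(shrink.s0_sq - s0_sq) / s0_sq <= 0.20


def test_posterior_variance_is_convex_combination():
    rng = np.random.default_rng(1)
    s2 = rng.chisquare(5, 500) * 0.004
    shrink = ebayes_moderate(_fits_from_s2(s2, d=8))
    lo = np.minimum(s2, shrink.s0_sq)
    hi = np.maximum(s2, shrink.s0_sq)
    assert ((shrink.s2_post >= lo - 1e-12) & (shrink.s2_post <= hi + 1e-12)).all()


def test_trigamma_inverse_roundtrip():
    from scipy.special import polygamma

    for x in (0.1, 0.7, 2.0, 13.0, 250.0):
        y = float(polygamma(1, x))
        assert np.isclose(trigamma_inverse(y), x, rtol=1e-6)


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------


def test_zero_coefficient_gives_t0_p1():
    fit = _fits_from_s2(np.full(10, 0.01))
    fit.coef["group"] = 0.0
    shrink = ebayes_moderate(fit)
    t, p, _ = moderated_t(fit, shrink)
    assert np.allclose(t, 0.0) and np.allclose(p, 1.0)


def test_d0_zero_limit_reproduces_classical_t(toy_sheet):
    rng = np.random.default_rng(9)
    values = rng.uniform(0.2, 0.8, (10, 6))
    beta = _beta(values, toy_sheet.sample_ids)
    fit = fit_linear_models(beta, toy_sheet)
    shrink = VarianceShrinkage(d0=0.0, s0_sq=1.0, s2_post=fit.sigma2)
    t, p, df = moderated_t(fit, shrink)
    classical = fit.coef["group"].to_numpy() / (
        fit.se_unit["group"] * np.sqrt(fit.sigma2)
    )
    assert np.allclose(t, classical, atol=1e-10)
    assert df == fit.df_residual
    assert np.allclose(p, 2 * sps.t.sf(np.abs(classical), fit.df_residual), atol=1e-12)


def test_moderated_t_sign_matches_coefficient(toy_sheet):
    rng = np.random.default_rng(21)
    values = rng.uniform(0.1, 0.9, (50, 6))
    beta = _beta(values, toy_sheet.sample_ids)
    fit = fit_linear_models(beta, toy_sheet)
    t, _, _ = moderated_t(fit, ebayes_moderate(fit))
    assert (np.sign(t) == np.sign(fit.coef["group"].to_numpy())).all()


def test_infinite_d0_uses_normal_tail():
    fit = _fits_from_s2(np.full(50, 0.01))
    fit.coef["group"] = np.linspace(-0.3, 0.3, 50)
    shrink = ebayes_moderate(fit)
    t, p, df = moderated_t(fit, shrink)
    assert np.isinf(df)
    assert np.allclose(p, 2 * sps.norm.sf(np.abs(t)), atol=1e-12)


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------


def test_bh_worked_examples():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    assert np.allclose(bh_adjust([0.2]), [0.2])
    with pytest.raises(ValidationError):
        bh_adjust([0.5, 1.2])


def test_bh_matches_bruteforce_on_random_vectors():
    rng = np.random.default_rng(17)
    for _ in range(200):
        p = rng.uniform(size=rng.integers(1, 60))
        assert np.allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)


def test_bh_is_permutation_equivariant():
    rng = np.random.default_rng(4)
    p = rng.uniform(size=100)
    perm = rng.permutation(100)
    assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


# ---------------------------------------------------------------------------
# delta beta and DMP calling
# ---------------------------------------------------------------------------


def test_delta_beta_median_arithmetic(toy_sheet):
    values = np.array([[0.5, 0.6, 0.7, 0.2, 0.3, 0.4]])
    beta = _beta(values, toy_sheet.sample_ids)
    db = delta_beta(beta, toy_sheet)
    assert np.isclose(db.iloc[0], -0.3)
    same = _beta(np.tile([0.4, 0.5, 0.6], (1, 2)), toy_sheet.sample_ids)
    assert np.isclose(delta_beta(same, toy_sheet).iloc[0], 0.0)


def test_delta_beta_matches_naive_oracle(toy_sheet):
    rng = np.random.default_rng(31)
    values = rng.uniform(0, 1, (500, 6))
    beta = _beta(values, toy_sheet.sample_ids)
    db = delta_beta(beta, toy_sheet)
    idcm = (toy_sheet.group == "iDCM").to_numpy()
    for i in range(500):
        expect = np.median(values[i, idcm]) - np.median(values[i, ~idcm])
        assert db.iloc[i] == expect


def test_dmp_selection_boundary_semantics():
    annot = ProbeAnnotation(
        pd.DataFrame({"chrom": ["chr1"] * 2, "pos": [1, 2]},
                     index=pd.Index(["cg0", "cg1"], name="probe_id"))
    )
    table = call_dmps(
        pd.Index(["cg0", "cg1"]), annot,
        db=pd.Series([0.10, 0.50], index=["cg0", "cg1"]),
        t=np.array([2.0, 3.0]), p=np.array([0.01, 0.02]),
        q=np.array([0.04, 0.05]),
    )
    row0, row1 = table.iloc[0], table.iloc[1]
    assert row0["significant"] and row0["direction"] == "hyper"   # fdr 0.04, |db| 0.10
    assert not row1["significant"]                                 # fdr exactly 0.05


def test_planted_dmp_recovery_across_seeds():
    """200 planted |delta beta|=0.15 probes among 5,000 at n=10 vs 10:
    empirical FDR <= 0.10 and sensitivity >= 0.5 averaged over seeds."""
    fdrs, senss = [], []
    for seed in range(10):
        cfg = SimulationConfig(n_cnt=10, n_idcm=10, seed=seed)
        study = simulate_study(cfg)
        table, summary = run_dmp_analysis(study.beta, study.annotation, study.sheet)
        called = set(table.loc[table["significant"], "probe_id"])
        truth = set(study.truth.true_dmp_probes)
        tp = len(called & truth)
        senss.append(tp / len(truth))
        fdrs.append((len(called) - tp) / len(called) if called else 0.0)
        assert summary["n_hyper"] + summary["n_hypo"] == summary["n_significant"]
    assert np.mean(fdrs) <= 0.10
    assert np.mean(senss) >= 0.5
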