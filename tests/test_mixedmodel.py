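"""Mixed models: GLS oracles, REML recovery, model equivalences, summaries."""

import numpy as np
import pandas as pd
import pytest

from selboa.containers import BREEDS, CROSSBRED
from selboa.mixedmodel import (
    GeneticComponent,
    MixedModel,
    ModelSpec,
    build_mme,
    build_model_spec,
    crossbred_h2,
    crossbred_variance,
    derive_summaries,
    predict_gebv,
    reml_fit,
)

from conftest import small_config
from selboa.simdata import simulate


def _toy_model(n=30, seed=0, two_pop=False):
    rng = np.random.default_rng(seed)
    m = rng.binomial(2, 0.4, size=(n, 60)).astype(float)
    p = m.mean(0) / 2
    K = (m - 2 * p) @ (m - 2 * p).T / (2 * p * (1 - p)).sum() + 1e-6 * np.eye(n)
    ids = [f"a{i}" for i in range(n)]
    pops = ["P1"] * n
    trait_of = {"P1": 0}
    names = ["T1"]
    if two_pop:
        pops = ["P1"] * (n // 2) + ["P2"] * (n - n // 2)
        trait_of = {"P1": 0, "P2": 1}
        names = ["T1", "T2"]
    ph = pd.DataFrame({
        "animal_id": ids, "population": pops,
        "trait_value": rng.normal(100, 10, n),
        "fixed_level": rng.choice(["x", "y"], n),
        "covariate": rng.normal(size=n),
        "litter_id": rng.choice([f"L{i}" for i in range(6)], n),
    })
    comp = GeneticComponent(label="g", K=K, k_ids=ids, trait_of=trait_of,
                            trait_names=names)
    return ph, ModelSpec("G", [comp])


def test_near_zero_variance_reduces_to_ols():
    """With vanishing genetic and litter variance, GLS fixed effects = OLS."""
    ph, spec = _toy_model()
    mm = MixedModel(ph, spec)
    theta = np.array([1e-8, 1e-8, 25.0])  # gvar, litter, resid
    st = mm._projection(theta)
    beta_ols, *_ = np.linalg.lstsq(mm.X, mm.y, rcond=None)
    np.testing.assert_allclose(st["beta"], beta_ols, rtol=1e-4)


def test_gls_oracle_30_animals():
    """Fixed-effect solutions equal direct dense-GLS inversion."""
    ph, spec = _toy_model(seed=1)
    mm = MixedModel(ph, spec)
    theta = np.array([40.0, 10.0, 25.0])
    v = mm.build_v(theta)
    vi = np.linalg.inv(v)
    beta_gls = np.linalg.solve(mm.X.T @ vi @ mm.X, mm.X.T @ vi @ mm.y)
    st = mm._projection(theta)
    np.testing.assert_allclose(st["beta"], beta_gls, rtol=1e-8)


def test_mme_solution_satisfies_normal_equations():
    """Henderson-system solutions match the V-form BLUP/BLUE to 1e-8."""
    ph, spec = _toy_model(seed=2)
    mm = MixedModel(ph, spec)
    theta = np.array([40.0, 10.0, 25.0])
    coeff, rhs, spans = build_mme(mm, theta)
    sol = np.linalg.solve(coeff, rhs)
    resid = coeff @ sol - rhs
    assert np.linalg.norm(resid) / np.linalg.norm(rhs) < 1e-8
    st = mm._projection(theta)
    lo, hi = spans["fixed"]
    np.testing.assert_allclose(sol[lo:hi], st["beta"], rtol=1e-6)
    lo, hi = spans["g"]
    u_mme = sol[lo:hi]
    u_v = mm.effects(theta, st)["g"].to_numpy().T.ravel()
    np.testing.assert_allclose(u_mme, u_v, atol=1e-6)


def test_singular_fixed_design_names_confounded_column():
    ph, spec = _toy_model(seed=3)
    # covariate duplicates the level-y dummy -> perfectly confounded
    ph["covariate"] = (ph["fixed_level"] == "y").astype(float)
    with pytest.raises(ValueError, match="confounded"):
        MixedModel(ph, spec)


def test_em_steps_monotone_loglik():
    """Restricted loglik never decreases along the accepted iteration path."""
    ph, spec = _toy_model(n=60, seed=4)
    mm = MixedModel(ph, spec)
    mm.reml(max_iter=25, n_em_start=25)  # EM-only path
    diffs = np.diff(mm.trace_)
    assert (diffs >= -1e-8).all()


def test_single_component_parameter_recovery():
    """sigma_a = 2,000, sigma_e = 5,000, n = 800: recovery within 2 SE.

    The oracle is data simulated directly from the model; the mean REML
    estimate over 10 seeds must sit within two empirical standard errors
    of the simulated truth.
    """
    rng = np.random.default_rng(11)
    n = 800
    m = rng.binomial(2, 0.5, size=(n, 400)).astype(float)
    p = m.mean(0) / 2
    K = (m - 2 * p) @ (m - 2 * p).T / (2 * p * (1 - p)).sum() + 1e-6 * np.eye(n)
    L = np.linalg.cholesky(K)
    ids = [f"a{i}" for i in range(n)]
    comp = GeneticComponent(label="g", K=K, k_ids=ids, trait_of={"P1": 0},
                            trait_names=["T"])
    ests = []
    for seed in range(10):
        r = np.random.default_rng(100 + seed)
        y = 300 + L @ r.normal(size=n) * np.sqrt(2000) + r.normal(size=n) * np.sqrt(5000)
        ph = pd.DataFrame({"animal_id": ids, "population": "P1", "trait_value": y,
                           "fixed_level": "l", "covariate": 0.0,
                           "litter_id": [f"L{i}" for i in range(n)]})
        fit = reml_fit(ModelSpec("G", [comp], litter=False), ph)
        ests.append([fit.varcomps["g"].iloc[0, 0], fit.residual_var["P1"]])
    arr = np.array(ests)
    for col, truth in ((0, 2000.0), (1, 5000.0)):
        se = arr[:, col].std(ddof=1) / np.sqrt(len(arr))
        assert abs(arr[:, col].mean() - truth) <= 2 * se, (col, arr[:, col].mean(), se)


@pytest.fixture(scope="module")
def tiny_sim():
    return simulate(small_config(seed=31, n_snp=400, n_chrom=4,
                                 founders_per_breed=60, n_crossbred=120,
                                 n_sires_S=10, n_f1_dams=24))


def test_selboa_equivalences_structural(tiny_sim):
    """SEL-BOA with no selected SNP is the G model; with all SNP, the BOA model."""
    d = tiny_sim
    pooled = d.pooled_genotypes()
    args = (pooled, d.purebreds, d.crossbreds, d.truth.true_origin)
    spec_empty = build_model_spec("SELBOA", *args, selected_index=np.array([], int))
    spec_g = build_model_spec("G", *args)
    assert [c.label for c in spec_empty.components] == [c.label for c in spec_g.components]
    np.testing.assert_allclose(spec_empty.components[0].K, spec_g.components[0].K)
    spec_all = build_model_spec("SELBOA", *args,
                                selected_index=np.arange(pooled.n_snp))
    spec_boa = build_model_spec("BOA", *args)
    assert [c.label for c in spec_all.components] == [c.label for c in spec_boa.components]
    for ca, cb in zip(spec_all.components, spec_boa.components):
        np.testing.assert_allclose(ca.K, cb.K)


def test_reml_fit_recovers_identical_fits_for_equivalent_specs(tiny_sim):
    d = tiny_sim
    pooled = d.pooled_genotypes()
    args = (pooled, d.purebreds, d.crossbreds, d.truth.true_origin)
    f_g = reml_fit(build_model_spec("G", *args), d.phenotypes, max_iter=40)
    f_e = reml_fit(build_model_spec("SELBOA", *args,
                                    selected_index=np.array([], int)),
                   d.phenotypes, max_iter=40)
    assert abs(f_g.loglik - f_e.loglik) <= 1e-4 * (1 + abs(f_g.loglik))
    np.testing.assert_allclose(
        f_g.varcomps["across-all"].to_numpy(),
        f_e.varcomps["across-all"].to_numpy(), rtol=1e-4, atol=1e-6)


def test_crossbred_variance_weighted_sum():
    """Equal per-breed variances v with weights summing to 1 combine to v."""
    v = 1234.5
    assert np.isclose(crossbred_variance({"S": v, "LR": v, "LW": v}), v)


def test_derive_summaries_clamps_rpc():
    c = pd.DataFrame([[100.0, 150.0], [150.0, 100.0]],
                     index=["PB_S", "CB"], columns=["PB_S", "CB"])
    comp = GeneticComponent(label="S-all", K=np.eye(2), k_ids=["a", "b"],
                            trait_of={"S": 0, CROSSBRED: 1},
                            trait_names=["PB_S", "CB"], breed="S")
    from selboa.mixedmodel import FitResult
    fit = FitResult(model_kind="BOA", varcomps={"S-all": c},
                    litter_var={"S": 10.0, CROSSBRED: 10.0},
                    residual_var={"S": 50.0, CROSSBRED: 50.0},
                    loglik=0.0, converged=True, iterations=1)
    fit = derive_summaries(fit, ModelSpec("BOA", [comp]))
    assert fit.rpc_raw[("S-all", "S")] == pytest.approx(1.5)
    assert fit.rpc[("S-all", "S")] == 0.99
    assert any("0.99" in line for line in fit.clamp_log)
    # negative covariance clamps to zero
    c2 = c.copy()
    c2.iloc[0, 1] = c2.iloc[1, 0] = -20.0
    fit2 = FitResult(model_kind="BOA", varcomps={"S-all": c2},
                     litter_var=fit.litter_var, residual_var=fit.residual_var,
                     loglik=0.0, converged=True, iterations=1)
    fit2 = derive_summaries(fit2, ModelSpec("BOA", [comp]))
    assert fit2.rpc[("S-all", "S")] == 0.0


def test_perfect_correlation_gives_identical_trait_effects():
    """With r_pc = 1 and equal variances, PB and CB effect predictions agree."""
    ph, spec = _toy_model(n=40, seed=6, two_pop=True)
    mm = MixedModel(ph, spec)
    v = 30.0
    theta = np.zeros(len(mm.params))
    for k, prm in enumerate(mm.params):
        if prm.kind == "gcov":
            theta[k] = v  # C = [[v, v], [v, v]] up to bending
        elif prm.kind == "litter":
            theta[k] = 5.0
        else:
            theta[k] = 20.0
    u = mm.effects(theta)["g"]
    np.testing.assert_allclose(u["T1"], u["T2"], rtol=1e-10)


def test_gebv_prediction_tracks_true_bv(tiny_sim):
    """BOA-model purebred GEBV for crossbred performance correlate with truth."""
    d = tiny_sim
    pooled = d.pooled_genotypes()
    spec = build_model_spec("BOA", pooled, d.purebreds, d.crossbreds,
                            d.truth.true_origin)
    fit = reml_fit(spec, d.phenotypes, max_iter=40)
    gebv = predict_gebv(fit, spec)["gebv_cb"]
    truth = pd.concat([d.truth.true_bv_cb_purebred[b] for b in BREEDS])
    common = gebv.index.intersection(truth.index)
    r = np.corrcoef(gebv.loc[common], truth.loc[common])[0, 1]
    assert r > 0.2, r
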