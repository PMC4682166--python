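import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from methmediate import (
    MediatorModel,
    MethylationMatrix,
    OutcomeModel,
    SimulationConfig,
    bootstrap_mediation,
    closed_form_nde_nie,
    draw_nested_case_control,
    fit_mediator_models,
    fit_outcome_model,
    gcompute_mediation,
    mediator_probe_ids,
    published_arithmetic,
    report_mediation_block,
    simulate_population,
    true_effects_oracle,
)
from methmediate.containers import LogisticFit
from methmediate.mediation import MEDIATOR_DESIGN


@pytest.fixture(scope="module")
def cc_data():
    cfg = SimulationConfig(
        n_population=6_000, n_pairs=300, n_probes=20, n_responsive_probes=4,
        n_discriminating_probes=4, seed=51,
    )
    matrix, sheet, truth = simulate_population(cfg)
    cc = draw_nested_case_control(sheet, cfg.n_pairs, seed=52)
    ccm = matrix.subset_samples(list(cc["sample_id"]))
    pi = float(sheet["case"].mean())
    return cfg, ccm, cc, truth, pi


def _manual_models(
    gamma, theta, sigma, n=400, mediator="m1", seed=0, corr=None
) -> tuple[MediatorModel, OutcomeModel, pd.DataFrame]:
    """Hand-built single-mediator models plus a constant-age population sheet."""
    coef = pd.DataFrame(
        {mediator: [gamma["g0"], gamma["g1"], gamma.get("g2", 0.0), gamma.get("g3", 0.0)]},
        index=MEDIATOR_DESIGN,
    )
    med_model = MediatorModel(
        coefficients=coef,
        sigma=pd.Series([sigma], index=[mediator]),
        residual_corr=pd.DataFrame([[1.0]], index=[mediator], columns=[mediator]),
        prevalence=None,
        n_obs=n,
    )
    names = ["intercept", "exposure", mediator, "age", f"exposure:{mediator}", "exposure:age"]
    params = np.array(
        [theta.get("t0", -6.0), theta["t1"], theta["t2"], theta.get("t4", 0.0),
         theta.get("t3", 0.0), 0.0]
    )
    fit = LogisticFit(names=names, params=params, cov=np.eye(6), loglik=0.0, n_iter=1, converged=True)
    out_model = OutcomeModel(fit=fit, mediators=[mediator], interactions=("exposure:mediator", "exposure:age"),
                             n_cases=1, n_controls=1)
    sheet = pd.DataFrame(
        {"sample_id": [f"s{i}" for i in range(n)], "case": 0, "age": 0.0,
         "smoking_status": "never"}
    )
    return med_model, out_model, sheet


class TestMediatorModels:
    def test_uniform_weights_equal_unweighted_least_squares(self, cc_data):
        import statsmodels.api as sm

        cfg, ccm, cc, _, _ = cc_data
        probes = mediator_probe_ids(cfg)
        balanced = cc  # 1:1 design: equal case/control counts
        model = fit_mediator_models(balanced, ccm, probes, prevalence=0.5)
        ever = (balanced["smoking_status"] != "never").astype(float).to_numpy()
        age = balanced["age"].to_numpy()
        X = np.column_stack([np.ones(len(balanced)), ever, age, ever * age])
        for probe in probes:
            y = ccm.values.loc[probe, balanced["sample_id"]].to_numpy()
            ols = sm.OLS(y, X).fit()
            np.testing.assert_allclose(model.coefficients[probe].to_numpy(), ols.params, atol=1e-10)

    def test_weighted_solution_matches_normal_equations_oracle(self, cc_data):
        cfg, ccm, cc, _, pi = cc_data
        probes = mediator_probe_ids(cfg)
        model = fit_mediator_models(cc, ccm, probes, prevalence=pi)
        ever = (cc["smoking_status"] != "never").astype(float).to_numpy()
        age = cc["age"].to_numpy()
        w = np.where(cc["case"].to_numpy() == 1, pi, 1 - pi)
        X = np.column_stack([np.ones(len(cc)), ever, age, ever * age])
        sw = np.sqrt(w)
        for probe in probes:
            y = ccm.values.loc[probe, cc["sample_id"]].to_numpy()
            beta = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)[0]
            np.testing.assert_allclose(model.coefficients[probe].to_numpy(), beta, atol=1e-8)

    def test_exposure_coefficient_recovery(self):
        """Weighted mediator regression on a population sample recovers the
        true exposure->mediator shift within sampling error at n=2000."""
        cfg = SimulationConfig(
            n_population=2_000, n_pairs=10, n_probes=10, n_responsive_probes=2,
            n_discriminating_probes=0, seed=53,
        )
        matrix, sheet, _ = simulate_population(cfg)
        probes = mediator_probe_ids(cfg)
        pi = float(sheet["case"].mean())
        # on the full population, pi-weighting is immaterial; use truth shift
        model = fit_mediator_models(sheet, matrix, probes, prevalence=pi)
        probe = probes[0]
        s = sheet.set_index("sample_id")
        v = matrix.values.loc[probe]
        true_shift = (
            v[(s.smoking_status != "never").to_numpy()].mean()
            - v[(s.smoking_status == "never").to_numpy()].mean()
        )
        g1 = model.coefficients.loc["exposure", probe]
        g3 = model.coefficients.loc["exposure:age", probe]
        mean_age = s["age"].mean()
        assert g1 + g3 * mean_age == pytest.approx(true_shift, abs=0.01)

    def test_invalid_prevalence_rejected(self, cc_data):
        cfg, ccm, cc, _, _ = cc_data
        with pytest.raises(Exception):
            fit_mediator_models(cc, ccm, mediator_probe_ids(cfg), prevalence=1.5)


class TestOutcomeModel:
    def test_empty_interaction_spec_reduces_to_main_effects(self, cc_data):
        cfg, ccm, cc, _, _ = cc_data
        probes = mediator_probe_ids(cfg)
        model = fit_outcome_model(cc, ccm, probes, interactions=())
        assert model.fit.names == ["intercept", "exposure", *probes, "age"]

    def test_null_interaction_estimated_near_zero(self, cc_data):
        cfg, ccm, cc, _, _ = cc_data
        probes = mediator_probe_ids(cfg)
        model = fit_outcome_model(cc, ccm, probes)
        for m in probes:  # generative interaction coefficients are zero
            name = f"exposure:{m}"
            assert abs(model.fit.coef(name)) < 2.5 * model.fit.se_of(name)

    def test_permuted_mediator_has_no_association(self, cc_data):
        cfg, ccm, cc, _, _ = cc_data
        probe = mediator_probe_ids(cfg)[0]
        rng = np.random.default_rng(5)
        values = ccm.values.copy()
        values.loc[probe] = rng.permutation(values.loc[probe].to_numpy())
        permuted = MethylationMatrix(values, ccm.annotations)
        model = fit_outcome_model(cc, permuted, [probe], interactions=())
        assert abs(model.fit.coef(probe)) < 2.5 * model.fit.se_of(probe)


class TestGComputation:
    def test_blocked_outcome_pathway_gives_zero_nie(self):
        med, out, sheet = _manual_models(
            {"g0": 0.5, "g1": -0.2}, {"t1": 0.8, "t2": 0.0, "t3": 0.0}, sigma=0.1
        )
        res = gcompute_mediation(med, out, sheet, n_mc=2_000, seed=1)
        assert res.nie == pytest.approx(0.0, abs=1e-6)
        assert res.nde == pytest.approx(res.tce, abs=1e-9)
        assert res.proportion_mediated == pytest.approx(0.0, abs=1e-6)

    def test_no_exposure_mediator_link_gives_zero_nie(self):
        med, out, sheet = _manual_models(
            {"g0": 0.5, "g1": 0.0}, {"t1": 0.8, "t2": -2.0, "t3": 0.0}, sigma=0.1
        )
        res = gcompute_mediation(med, out, sheet, n_mc=2_000, seed=2)
        assert res.nie == pytest.approx(0.0, abs=0.01)

    def test_decomposition_identity_holds_by_construction(self, cc_data):
        cfg, ccm, cc, _, pi = cc_data
        probes = mediator_probe_ids(cfg)
        med = fit_mediator_models(cc, ccm, probes, prevalence=pi)
        out = fit_outcome_model(cc, ccm, probes)
        res = gcompute_mediation(med, out, cc, prevalence=pi, n_mc=200, seed=3)
        assert res.tce == pytest.approx(res.nde + res.nie, abs=1e-12)
        assert res.proportion_mediated == pytest.approx(res.nie / res.tce, abs=1e-12)

    def test_mediator_order_invariance(self, cc_data):
        cfg, ccm, cc, _, pi = cc_data
        probes = mediator_probe_ids(cfg)
        rev = list(reversed(probes))
        res1 = gcompute_mediation(
            fit_mediator_models(cc, ccm, probes, prevalence=pi),
            fit_outcome_model(cc, ccm, probes),
            cc, prevalence=pi, n_mc=4_000, seed=4,
        )
        res2 = gcompute_mediation(
            fit_mediator_models(cc, ccm, rev, prevalence=pi),
            fit_outcome_model(cc, ccm, rev),
            cc, prevalence=pi, n_mc=4_000, seed=5,
        )
        assert res1.nie == pytest.approx(res2.nie, abs=0.02)
        assert res1.nde == pytest.approx(res2.nde, abs=0.02)


class TestClosedForm:
    def test_no_interaction_reduction(self):
        out = closed_form_nde_nie({"g0": 1.0, "g1": -0.4}, {"t1": 0.7, "t2": -1.2, "t3": 0.0}, sigma=0.3)
        assert out["nie"] == pytest.approx(-1.2 * -0.4)
        assert out["nde"] == pytest.approx(0.7)

    def test_zero_exposure_mediator_effect(self):
        out = closed_form_nde_nie({"g0": 1.0, "g1": 0.0}, {"t1": 0.7, "t2": -1.2, "t3": 0.5}, sigma=0.3)
        assert out["nie"] == 0.0

    def test_matches_brute_force_rare_outcome_simulation(self):
        """Generic parameters: closed form vs direct Monte Carlo of the same
        mediator and outcome models in the rare-outcome regime."""
        rng = np.random.default_rng(9)
        gamma = {"g0": 0.6, "g1": -0.25, "g2": 0.0}
        theta = {"t0": -7.5, "t1": 0.6, "t2": -1.1, "t3": 0.4}
        sigma = 0.35
        n = 4_000_000
        m0 = gamma["g0"] + sigma * rng.standard_normal(n)
        m1 = m0 + gamma["g1"]  # shared noise: common random numbers

        def p(a, m):
            return expit(theta["t0"] + theta["t1"] * a + theta["t2"] * m + theta["t3"] * a * m).mean()

        p11, p10, p00 = p(1, m1), p(1, m0), p(0, m0)
        sim_nde = np.log(p10 / (1 - p10)) - np.log(p00 / (1 - p00))
        sim_nie = np.log(p11 / (1 - p11)) - np.log(p10 / (1 - p10))
        mc_se = np.sqrt((1 - p00) / (p00 * n)) + np.sqrt((1 - p10) / (p10 * n))
        out = closed_form_nde_nie(gamma, theta, sigma)
        assert abs(out["nde"] - sim_nde) < 3 * mc_se + 0.02 * abs(sim_nde)
        assert abs(out["nie"] - sim_nie) < 3 * mc_se + 0.02 * abs(sim_nie)


class TestBootstrap:
    def test_degenerate_two_resamples_return_finite_se(self, cc_data):
        cfg, ccm, cc, _, pi = cc_data
        probes = mediator_probe_ids(cfg)
        res = bootstrap_mediation(
            cc, ccm, probes, prevalence=pi, n_bootstrap=2, n_mc=50, seed=1
        )
        assert np.isfinite(res.se["tce"])
        assert res.n_bootstrap == 2

    def test_null_pathway_proportion_ci_covers_zero(self):
        cfg = SimulationConfig(
            n_population=4_000, n_pairs=200, n_probes=10, n_responsive_probes=2,
            n_discriminating_probes=0, seed=61,
            outcome_coeffs=SimulationConfig().outcome_coeffs.__class__(
                intercept=-2.5, direct_smoking_log_or=0.9,
                mediator_log_or_per_sd=(0.0, 0.0),
                exposure_mediator_interaction=(0.0, 0.0),
            ),
        )
        matrix, sheet, _ = simulate_population(cfg)
        cc = draw_nested_case_control(sheet, cfg.n_pairs, seed=62)
        ccm = matrix.subset_samples(list(cc["sample_id"]))
        pi = float(sheet["case"].mean())
        res = bootstrap_mediation(
            cc, ccm, mediator_probe_ids(cfg), prevalence=pi,
            n_bootstrap=200, n_mc=100, n_mc_bootstrap=50, seed=63,
        )
        lo, hi = res.ci["proportion_mediated"]
        assert lo <= 0.0 <= hi

    def test_resampling_stability_when_doubling_b(self, cc_data):
        cfg, ccm, cc, _, pi = cc_data
        probes = mediator_probe_ids(cfg)
        r1 = bootstrap_mediation(cc, ccm, probes, prevalence=pi,
                                 n_bootstrap=100, n_mc=100, n_mc_bootstrap=50, seed=9)
        r2 = bootstrap_mediation(cc, ccm, probes, prevalence=pi,
                                 n_bootstrap=200, n_mc=100, n_mc_bootstrap=50, seed=9)
        assert abs(r1.se["nie"] - r2.se["nie"]) < 0.25 * r2.se["nie"]

    def test_pair_resampling_is_deterministic_given_seed(self, cc_data):
        cfg, ccm, cc, _, pi = cc_data
        probes = mediator_probe_ids(cfg)
        a = bootstrap_mediation(cc, ccm, probes, prevalence=pi, n_bootstrap=20, n_mc=50, seed=4)
        b = bootstrap_mediation(cc, ccm, probes, prevalence=pi, n_bootstrap=20, n_mc=50, seed=4)
        assert a.to_dict() == b.to_dict()

    def test_aggregate_mean_mediator(self, cc_data):
        cfg, ccm, cc, _, pi = cc_data
        probes = mediator_probe_ids(cfg)
        res = bootstrap_mediation(
            cc, ccm, probes, prevalence=pi, aggregate="mean",
            n_bootstrap=10, n_mc=50, seed=6,
        )
        assert len(res.mediators) == 1 and res.mediators[0].startswith("mean(")
        assert np.isfinite(res.tce)


class TestReportBlock:
    def test_blocks_satisfy_decomposition_identity(self, cc_data):
        cfg, ccm, cc, _, pi = cc_data
        probes = mediator_probe_ids(cfg)
        results = {}
        for label, pset in ((probes[0], [probes[0]]), ("joint", probes)):
            med = fit_mediator_models(cc, ccm, pset, prevalence=pi)
            out = fit_outcome_model(cc, ccm, pset)
            results[label] = gcompute_mediation(med, out, cc, prevalence=pi, n_mc=200, seed=8)
        table = report_mediation_block(results)
        for _, block in table.groupby("block"):
            q = block.set_index("quantity")["log_or"]
            assert q["TCE"] == pytest.approx(q["NDE"] + q["NIE"], abs=1e-9)

    def test_published_block_arithmetic(self):
        arith = published_arithmetic()
        # proportion mediated = NIE/TCE on the published values
        assert round(arith["AHRR-cg05575921"]["nie_over_tce"], 2) == 0.31
        assert round(arith["F2RL3-cg03636183"]["nie_over_tce"], 2) == 0.32
        assert round(arith["joint"]["nie_over_tce"], 2) == 0.37
        # printed NDE + NIE reconstructs the printed TCE where it is exact
        assert arith["F2RL3-cg03636183"]["nde_plus_nie"] == pytest.approx(1.82)
        assert arith["joint"]["nde_plus_nie"] == pytest.approx(1.79)
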