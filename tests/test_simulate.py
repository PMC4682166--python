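import numpy as np
import pandas as pd
import pytest

from methmediate import (
    ConfigurationError,
    MatchingError,
    SimulationConfig,
    apply_technical_layer,
    draw_nested_case_control,
    mediator_probe_ids,
    responsive_probe_ids,
    simulate_population,
    simulate_reference_panel,
    true_effects_oracle,
)
from methmediate.config import OutcomeCoeffs
from methmediate.simulate import _architecture, _calibration, _smoking_factor


def _group_means(matrix, sheet, probes):
    s = sheet.set_index("sample_id")
    vals = matrix.values.loc[probes]
    out = {}
    for g in ("never", "former", "current"):
        cols = s.index[s["smoking_status"] == g]
        out[g] = float(vals[cols].to_numpy().mean())
    return out


class TestSimulatePopulation:
    def test_zero_effect_means_equal_across_smoking_groups(self):
        cfg = SimulationConfig(
            n_population=6_000, n_probes=30, n_responsive_probes=6,
            n_discriminating_probes=0, relative_hypomethylation=0.0, seed=2,
        )
        matrix, sheet, _ = simulate_population(cfg)
        means = _group_means(matrix, sheet, responsive_probe_ids(cfg))
        assert means["current"] == pytest.approx(means["never"], rel=0.01)
        assert means["former"] == pytest.approx(means["never"], rel=0.01)

    def test_nineteen_percent_hypomethylation_in_current_smokers(self):
        """Current-smoker mean at responsive probes is 0.81x the never mean."""
        cfg = SimulationConfig(
            n_population=20_000, n_probes=30, n_responsive_probes=6,
            n_discriminating_probes=0, seed=3,
        )
        matrix, sheet, _ = simulate_population(cfg)
        means = _group_means(matrix, sheet, responsive_probe_ids(cfg))
        assert means["current"] / means["never"] == pytest.approx(0.81, abs=0.01)

    def test_direct_effect_recovered_when_mediator_terms_are_zero(self):
        """With no methylation pathway, a logistic refit on the population
        recovers the configured direct smoking log-OR (refit oracle)."""
        import statsmodels.api as sm

        cfg = SimulationConfig(
            n_population=20_000, n_probes=10, n_responsive_probes=2,
            n_discriminating_probes=0,
            outcome_coeffs=OutcomeCoeffs(
                intercept=-2.5, direct_smoking_log_or=0.8,
                mediator_log_or_per_sd=(0.0, 0.0),
                exposure_mediator_interaction=(0.0, 0.0),
                age_log_or_per_sd=0.3,
            ),
            seed=4,
        )
        _, sheet, _ = simulate_population(cfg)
        ever = (sheet["smoking_status"] != "never").astype(float)
        z_age = (sheet["age"] - sheet["age"].mean()) / sheet["age"].std()
        X = sm.add_constant(np.column_stack([ever, z_age]))
        res = sm.Logit(sheet["case"].to_numpy(), X).fit(disp=0)
        assert abs(res.params[1] - 0.8) < 2 * res.bse[1]

    def test_determinism_and_seed_sensitivity(self, small_config):
        m1, s1, _ = simulate_population(small_config)
        m2, s2, _ = simulate_population(small_config)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(s1, s2)
        m3, _, _ = simulate_population(small_config.with_(seed=99))
        assert not m1.values.equals(m3.values)

    def test_betas_strictly_inside_unit_interval(self, small_cohort):
        matrix, _, _ = small_cohort
        arr = matrix.values.to_numpy()
        assert np.all((arr > 0) & (arr < 1))

    def test_monotone_reversal_with_time_since_quitting(self):
        cfg = SimulationConfig(
            n_population=12_000, n_probes=20, n_responsive_probes=4,
            n_discriminating_probes=0, seed=6,
        )
        matrix, sheet, _ = simulate_population(cfg)
        s = sheet.set_index("sample_id")
        probe = mediator_probe_ids(cfg)[0]
        v = matrix.values.loc[probe]
        never = v[(s.smoking_status == "never").to_numpy()].mean()
        current = v[(s.smoking_status == "current").to_numpy()].mean()
        recent = v[((s.smoking_status == "former") & (s.years_since_quit < 5)).to_numpy()].mean()
        longq = v[((s.smoking_status == "former") & (s.years_since_quit > 15)).to_numpy()].mean()
        assert never > longq > recent > current

    def test_cell_proportions_in_truth_are_compositional(self, small_cohort):
        _, _, truth = small_cohort
        props = truth.cell_proportions.to_numpy()
        assert np.all(props >= 0)
        np.testing.assert_allclose(props.sum(axis=1), 1.0, atol=1e-9)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(relative_hypomethylation=1.2)
        with pytest.raises(ConfigurationError):
            SimulationConfig(smoking_prevalence=(0.5, 0.5, 0.5))
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_probes=10, n_responsive_probes=20)
        with pytest.raises(ConfigurationError):
            SimulationConfig(noise_sd=float("nan"))


class TestNestedCaseControl:
    def test_matching_on_smoking_gives_identical_status_within_pairs(self, small_cohort):
        _, sheet, _ = small_cohort
        cc = draw_nested_case_control(sheet, 30, matching_vars=("smoking_status",), seed=1)
        by_pair = cc.groupby("pair_id")["smoking_status"].nunique()
        assert (by_pair == 1).all()

    def test_unmatched_sampling_shows_crude_smoking_odds_ratio(self):
        cfg = SimulationConfig(
            n_population=15_000, n_pairs=400, n_probes=10, n_responsive_probes=2,
            n_discriminating_probes=0, seed=8,
        )
        _, sheet, _ = simulate_population(cfg)
        cc = draw_nested_case_control(sheet, cfg.n_pairs, seed=9)
        ever = cc["smoking_status"] != "never"
        a = ((cc["case"] == 1) & ever).sum()
        b = ((cc["case"] == 1) & ~ever).sum()
        c = ((cc["case"] == 0) & ever).sum()
        d = ((cc["case"] == 0) & ~ever).sum()
        crude_or = (a * d) / (b * c)  # 2x2 cross-product oracle
        assert crude_or > 1.5
        # and the case/control smoking distributions genuinely differ
        assert ever[cc["case"] == 1].mean() > ever[cc["case"] == 0].mean()

    def test_same_seed_reproduces_byte_identical_sheet(self, small_cohort):
        _, sheet, _ = small_cohort
        cc1 = draw_nested_case_control(sheet, 25, matching_vars=("age",), seed=5)
        cc2 = draw_nested_case_control(sheet, 25, matching_vars=("age",), seed=5)
        assert cc1.to_csv(index=False) == cc2.to_csv(index=False)

    def test_each_subject_in_at_most_one_pair(self, small_cohort):
        _, sheet, _ = small_cohort
        cc = draw_nested_case_control(sheet, 40, seed=2)
        assert not cc["sample_id"].duplicated().any()
        assert len(cc) == 80

    def test_controls_at_risk_at_case_event_time(self, small_cohort):
        _, sheet, _ = small_cohort
        cc = draw_nested_case_control(sheet, 30, seed=3)
        pop = sheet.set_index("sample_id")
        for pair, grp in cc.groupby("pair_id"):
            case = grp[grp["case"] == 1].iloc[0]
            ctrl = grp[grp["case"] == 0].iloc[0]
            assert pop.loc[ctrl["sample_id"], "event_time"] > case["event_time"]

    def test_age_caliper_matching(self, small_cohort):
        _, sheet, _ = small_cohort
        cc = draw_nested_case_control(sheet, 25, matching_vars=("age",), seed=4)
        diffs = cc.groupby("pair_id")["age"].agg(lambda x: abs(x.iloc[0] - x.iloc[1]))
        assert (diffs <= 2.0).all()

    def test_insufficient_cases_raise_matching_error(self, small_cohort):
        _, sheet, _ = small_cohort
        with pytest.raises(MatchingError):
            draw_nested_case_control(sheet, 10_000, seed=1)


class TestReferencePanel:
    def test_discriminating_probes_spread_exceeds_noise(self, small_config):
        profiles, purified, labels = simulate_reference_panel(small_config, seed=1)
        from methmediate import discriminating_probe_ids

        disc = discriminating_probe_ids(small_config)
        between = profiles.profiles.loc[disc].var(axis=1)
        within = purified.values.loc[disc].T.groupby(labels).var().mean()
        assert (between.mean() / within.mean().mean()) > 10

    def test_replicate_means_converge_to_profiles(self, small_config):
        profiles, purified, labels = simulate_reference_panel(
            small_config, seed=2, n_replicates=200
        )
        ct = small_config.cell_types[0]
        cols = labels.index[labels == ct]
        emp = purified.values[cols].mean(axis=1)
        np.testing.assert_allclose(
            emp.to_numpy(), profiles.profiles[ct].to_numpy(), atol=0.01
        )

    def test_fewer_than_two_cell_types_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(cell_types=("Gran",), dirichlet_concentration=(1.0,))


class TestTechnicalLayer:
    def test_identity_when_all_effects_off(self, small_cohort, small_config):
        matrix, sheet, _ = small_cohort
        cfg = small_config.with_(
            detection_missing_rate=0.0,
            batch=small_config.batch.__class__(chip_sd=0.0, position_sd=0.0),
        )
        out = apply_technical_layer(matrix, sheet, cfg, seed=1)
        pd.testing.assert_frame_equal(out.values, matrix.values)

    def test_detection_missingness_rate(self, small_cohort, small_config):
        matrix, sheet, _ = small_cohort
        cfg = small_config.with_(detection_missing_rate=0.05)
        out = apply_technical_layer(matrix, sheet, cfg, seed=2)
        frac = out.mask.to_numpy().mean()
        n = matrix.n_probes * matrix.n_samples
        tol = 4 * np.sqrt(0.05 * 0.95 / n)  # binomial oracle
        assert abs(frac - 0.05) < tol

    def test_samples_on_same_chip_share_the_chip_shift(self, small_cohort, small_config):
        from scipy.special import logit

        matrix, sheet, _ = small_cohort
        # position effects off: any residual shift is purely the chip effect
        cfg = small_config.with_(
            detection_missing_rate=0.0,
            batch=small_config.batch.__class__(position_sd=0.0),
        )
        out = apply_technical_layer(matrix, sheet, cfg, seed=3)
        shift = logit(out.values.to_numpy()) - logit(matrix.values.to_numpy())
        s = sheet.set_index("sample_id").loc[list(matrix.sample_ids)]
        chips = s["chip"]
        dup_chip = chips[chips.duplicated(keep=False)].iloc[0]
        cols = [matrix.sample_ids.get_loc(x) for x in chips.index[chips == dup_chip]]
        assert len(cols) >= 2
        np.testing.assert_allclose(shift[:, cols[0]], shift[:, cols[1]], atol=1e-9)
        assert np.abs(shift[:, cols[0]]).mean() > 0.0

    def test_contaminated_samples_get_elevated_missingness(self, small_cohort, small_config):
        matrix, sheet, _ = small_cohort
        bad = matrix.sample_ids[0]
        out = apply_technical_layer(
            matrix, sheet, small_config, seed=4,
            contaminated_samples=[bad], contaminated_rate=0.5,
        )
        assert out.mask[bad].mean() > 0.3


class TestTruthOracle:
    def test_no_mediator_terms_means_no_indirect_effect(self):
        cfg = SimulationConfig(
            n_probes=10, n_responsive_probes=2, n_discriminating_probes=0,
            outcome_coeffs=OutcomeCoeffs(
                mediator_log_or_per_sd=(0.0, 0.0),
                exposure_mediator_interaction=(0.0, 0.0),
            ),
        )
        truth = true_effects_oracle(cfg)
        assert truth["nie"] == pytest.approx(0.0, abs=0.01)
        assert truth["nde"] == pytest.approx(truth["tce"], abs=0.01)
        assert truth["proportion_mediated"] == pytest.approx(0.0, abs=0.01)

    def test_no_exposure_effect_on_mediator_means_no_indirect_effect(self):
        cfg = SimulationConfig(
            n_probes=10, n_responsive_probes=2, n_discriminating_probes=0,
            relative_hypomethylation=0.0,
        )
        truth = true_effects_oracle(cfg)
        assert truth["nie"] == pytest.approx(0.0, abs=0.01)

    def test_decomposition_identity(self):
        truth = true_effects_oracle(SimulationConfig())
        assert truth["tce"] == pytest.approx(truth["nde"] + truth["nie"], abs=1e-12)

    def test_oracle_matches_independent_numerical_integration(self):
        """Cross-check the Monte Carlo truth oracle against deterministic
        quadrature (Gauss-Legendre over age and quit time, Gauss-Hermite over
        the mediator noise) of the same generative law."""
        from numpy.polynomial.hermite_e import hermegauss
        from numpy.polynomial.legendre import leggauss
        from scipy.special import expit, logit

        cfg = SimulationConfig(n_probes=10, n_responsive_probes=2, n_discriminating_probes=0)
        arch = _architecture(cfg)
        mu_cal, sd_cal = _calibration(cfg)
        oc = cfg.outcome_coeffs
        base = arch["means"][0, arch["mediator_idx"]]
        lo, hi = cfg.age_range
        age_x, age_w = leggauss(24)
        ages = (age_x + 1) / 2 * (hi - lo) + lo
        age_w = age_w / 2
        ysq_x, ysq_w = leggauss(24)
        ysqs = (ysq_x + 1) / 2 * (cfg.max_years_since_quit - 0.5) + 0.5
        ysq_w = ysq_w / 2
        eps_x, eps_w = hermegauss(24)
        eps_w = eps_w / np.sqrt(2 * np.pi)
        p_nev, p_for, p_cur = cfg.smoking_prevalence
        w_cur = p_cur / (p_for + p_cur)

        def mediator_grid(factor):
            # betas for each (eps1, eps2) node pair at a given smoking factor
            m = np.clip(factor * base, 1e-4, 1 - 1e-4)
            sd_l = cfg.noise_sd / (m * (1 - m))
            return [expit(logit(m[j]) + eps_x * sd_l[j]) for j in range(2)]

        def p_cond(a1, factor):
            g = mediator_grid(factor)
            z1 = (g[0] - mu_cal[0]) / sd_cal[0]
            z2 = (g[1] - mu_cal[1]) / sd_cal[1]
            age_mean, age_sd = (lo + hi) / 2, (hi - lo) / np.sqrt(12)
            za = (ages - age_mean) / age_sd
            th = np.asarray(oc.mediator_log_or_per_sd)
            lp = (
                oc.intercept + oc.direct_smoking_log_or * a1
                + oc.age_log_or_per_sd * za[:, None, None]
                + th[0] * z1[None, :, None] + th[1] * z2[None, None, :]
            )
            w = age_w[:, None, None] * eps_w[None, :, None] * eps_w[None, None, :]
            return float((expit(lp) * w).sum())

        def p_marginal(a1, regime):
            if regime == "never":
                return p_cond(a1, 1.0)
            cur = p_cond(a1, 1.0 - cfg.relative_hypomethylation)
            form = sum(
                wq * p_cond(a1, 1.0 - cfg.relative_hypomethylation
                            * np.exp2(-yq / cfg.reversal_halflife))
                for yq, wq in zip(ysqs, ysq_w)
            )
            return w_cur * cur + (1 - w_cur) * form

        p11 = p_marginal(1.0, "ever")
        p10 = p_marginal(1.0, "never")
        p00 = p_marginal(0.0, "never")
        nde_q = logit(p10) - logit(p00)
        nie_q = logit(p11) - logit(p10)

        truth = true_effects_oracle(cfg)
        n = truth["n_draws"]
        mc_se = np.sqrt((1 - p11) / (p11 * n)) + np.sqrt((1 - p00) / (p00 * n))
        assert abs(truth["nde"] - nde_q) < 3 * mc_se
        assert abs(truth["nie"] - nie_q) < 3 * mc_se

    def test_undefined_proportion_signalled(self):
        cfg = SimulationConfig(
            n_probes=10, n_responsive_probes=2, n_discriminating_probes=0,
            relative_hypomethylation=0.0,
            outcome_coeffs=OutcomeCoeffs(
                direct_smoking_log_or=0.0,
                mediator_log_or_per_sd=(0.0, 0.0),
                exposure_mediator_interaction=(0.0, 0.0),
            ),
        )
        truth = true_effects_oracle(cfg)
        assert not truth["proportion_defined"]
        assert np.isnan(truth["proportion_mediated"])


def test_smoking_factor_boundaries():
    cfg = SimulationConfig()
    status = np.array([0, 2, 1, 1])
    ysq = np.array([np.nan, np.nan, 0.0, 1e9])
    f = _smoking_factor(cfg, status, ysq)
    assert f[0] == 1.0
    assert f[1] == pytest.approx(1.0 - cfg.relative_hypomethylation)
    assert f[2] == pytest.approx(1.0 - cfg.relative_hypomethylation)
    assert f[3] == pytest.approx(1.0)
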