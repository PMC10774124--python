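"""Choice GLM, psychometrics, model comparison, selection, stimulation."""

import numpy as np
import pandas as pd
import pytest

import infoval as iv
from infoval.behavior import (
    ChoiceModel,
    RankDeficientError,
    compare_uncertainty_forms,
    select_attributes_cv,
    shuffle_corrected_loglik,
)
from infoval.task import ModelSpec, core_spec, timing_spec


class TestChoiceGlm:
    def test_recovers_generating_weights(self, rng):
        from infoval.studies import human_wtp_study

        cfg, params = human_wtp_study(n_trials=10_000)
        t = iv.simulate_choices(iv.generate_offers(cfg, rng), params, rng)
        fit = ChoiceModel(t, params.spec).fit()
        assert fit.converged
        for name, truth in zip(params.spec.attributes, params.beta):
            assert abs(fit.params[name] - truth) < 3 * fit.bse[name]

    def test_null_chooser_gives_null_weights(self, rng):
        cfg = iv.SessionConfig.human_coins(n_trials=5000)
        params = iv.BehavioralParams(core_spec(), (0.0,) * 5)
        t = iv.simulate_choices(iv.generate_offers(cfg, rng), params, rng)
        fit = ChoiceModel(t, core_spec()).fit()
        assert (fit.params.abs() < 4 * fit.bse).all()

    def test_per_weight_type_i_error_calibrated(self):
        """Wald tests on a null chooser reject at ~ the nominal 5% rate."""
        rng = np.random.default_rng(77)
        cfg = iv.SessionConfig.human_coins(n_trials=400)
        params = iv.BehavioralParams(core_spec(), (0.0,) * 5)
        hits, total = 0, 0
        for _ in range(120):
            t = iv.simulate_choices(iv.generate_offers(cfg, rng), params, rng)
            fit = ChoiceModel(t, core_spec()).fit()
            if not fit.converged:
                continue
            hits += int((fit.pvalues < 0.05).sum())
            total += len(fit.pvalues)
        assert 0.02 < hits / total < 0.09

    def test_deterministic_chooser_flagged_not_converged(self, rng):
        cfg = iv.SessionConfig.human_coins(n_trials=500, matched_fraction=0.0)
        t = iv.generate_offers(cfg, rng)
        e1 = t[[f"r_1_{j}" for j in (1, 2, 3, 4)]].mean(axis=1)
        e2 = t[[f"r_2_{j}" for j in (1, 2, 3, 4)]].mean(axis=1)
        t = t.loc[(e1 - e2).abs() > 1e-9].copy()
        e1, e2 = e1.loc[t.index], e2.loc[t.index]
        t["choice"] = np.where(e2 > e1, 2, 1)
        t["outcome"] = t["r_1_1"]
        t.loc[t["choice"] == 2, "outcome"] = t["r_2_1"]
        spec = ModelSpec("e-only", ("E[r]",), "none")
        fit = ChoiceModel(t, spec).fit()
        assert not fit.converged

    def test_rank_deficient_design_names_attributes(self, coin_session):
        t, _params = coin_session
        # fixed-timing session: every timing attribute difference is zero
        with pytest.raises(RankDeficientError, match="t_out"):
            ChoiceModel(t, timing_spec()).fit()

    def test_antisymmetry_under_offer_relabeling(self, coin_session):
        t, params = coin_session
        swapped = t.copy()
        offer_cols = [f"r_KK_{j}" for j in (1, 2, 3, 4)] + [
            "info_KK", "t_cue_KK", "t_rev_KK", "pos_KK"
        ]
        for tmpl in offer_cols:
            c1, c2 = tmpl.replace("KK", "1"), tmpl.replace("KK", "2")
            swapped[c1], swapped[c2] = t[c2], t[c1]
        swapped["choice"] = 3 - t["choice"]
        a = ChoiceModel(t, params.spec).fit()
        b = ChoiceModel(swapped, params.spec).fit()
        np.testing.assert_allclose(a.params, b.params, atol=1e-6)

    def test_translation_invariance_of_difference_model(self, rng):
        spec = ModelSpec("no-interaction", ("E[r]", "Unc[r]", "Info"), "sd")
        cfg = iv.SessionConfig.human_coins(n_trials=4000)
        params = iv.BehavioralParams(spec, (0.8, -0.05, 0.4))
        t = iv.simulate_choices(iv.generate_offers(cfg, rng), params, rng)
        shifted = t.copy()
        for k in (1, 2):
            for j in (1, 2, 3, 4):
                shifted[f"r_{k}_{j}"] = t[f"r_{k}_{j}"] + 3.0
        a = ChoiceModel(t, spec).fit()
        b = ChoiceModel(shifted, spec).fit()
        np.testing.assert_allclose(a.params, b.params, atol=1e-8)

    def test_reward_unit_conversion(self, coin_session):
        t, params = coin_session
        fit = ChoiceModel(t, params.spec).fit()
        scaled = fit.to_reward_units()
        assert scaled["E[r]"] == pytest.approx(1.0)
        assert scaled["Info"] == pytest.approx(
            fit.params["Info"] / fit.params["E[r]"]
        )

    def test_reward_unit_conversion_requires_positive_e_weight(self, rng):
        cfg = iv.SessionConfig.human_coins(n_trials=2000)
        params = iv.BehavioralParams(core_spec(), (-0.5, 0.0, 0.0, 0.0, 0.0))
        t = iv.simulate_choices(iv.generate_offers(cfg, rng), params, rng)
        fit = ChoiceModel(t, core_spec()).fit()
        with pytest.raises(ValueError, match="meaningless"):
            fit.to_reward_units()


class TestShuffleCorrectedLoglik:
    def test_uninformative_model_corrects_to_zero(self):
        """A model of attributes the chooser ignores gains nothing after
        shuffle correction."""
        rng = np.random.default_rng(4)
        spec_e = ModelSpec("e-only", ("E[r]",), "none")
        spec_junk = ModelSpec("junk", ("Info", "Unc[r]"), "sd")
        vals = []
        for _ in range(20):
            cfg = iv.SessionConfig.human_coins(n_trials=500)
            params = iv.BehavioralParams(spec_e, (0.8,))
            t = iv.simulate_choices(iv.generate_offers(cfg, rng), params, rng)
            vals.append(
                shuffle_corrected_loglik(t, spec_junk, n_shuffles=30, rng=rng)
            )
        vals = np.array(vals)
        assert abs(vals.mean()) < 2 * vals.std(ddof=1) / np.sqrt(len(vals))

    def test_true_model_beats_reduction(self, coin_session):
        rng = np.random.default_rng(5)
        t, params = coin_session
        full = shuffle_corrected_loglik(t, core_spec("sd"), 30, rng)
        reduced = shuffle_corrected_loglik(t, core_spec("none"), 30, rng)
        assert full > reduced

    def test_irrelevant_attributes_add_nothing(self, clock_session):
        """Extra attributes with zero generating weight leave the corrected
        LL unchanged up to noise (the correction removes the chance gain)."""
        rng = np.random.default_rng(6)
        cfg = iv.SessionConfig.monkey_v2(n_trials=3000)
        spec_small = ModelSpec("small", ("E[r]", "Unc[r]", "Info"), "sd")
        params = iv.BehavioralParams(spec_small, (8.0, 2.0, 0.5))
        t = iv.simulate_choices(iv.generate_offers(cfg, rng), params, rng)
        base = shuffle_corrected_loglik(t, spec_small, 40, rng)
        ext = shuffle_corrected_loglik(t, timing_spec("sd"), 40, rng)
        # 7 extra irrelevant attributes: corrected LLs agree within a few units
        assert abs(ext - base) < 6.0

    def test_cross_validated_mode_runs(self, coin_session):
        t, _params = coin_session
        rng = np.random.default_rng(7)
        v = shuffle_corrected_loglik(
            t.iloc[:1000], core_spec(), n_shuffles=10, rng=rng, cv_folds=4
        )
        assert np.isfinite(v)


class TestCompareUncertaintyForms:
    def test_zero_uncertainty_weight_keeps_none_in_contention(self, rng):
        cfg = iv.SessionConfig.human_coins(n_trials=5000)
        params = iv.BehavioralParams(core_spec(), (0.8, 0.0, 0.5, 0.0, 0.0))
        t = iv.simulate_choices(iv.generate_offers(cfg, rng), params, rng)
        res = compare_uncertainty_forms(t, n_shuffles=20, n_boot=200, rng=rng)
        assert res.table.loc["none", "ci_high"] >= res.table["rel_ll"].max() - 3.0

    def test_underpowered_design_flagged(self, rng):
        cfg = iv.SessionConfig.human_coins(n_trials=1000, dist_types=("safe", "50_50"))
        params = iv.BehavioralParams(core_spec(), (0.8, 0.0, 0.5, 0.0, 0.1))
        t = iv.simulate_choices(iv.generate_offers(cfg, rng), params, rng)
        with pytest.warns(UserWarning, match="underpowered"):
            res = compare_uncertainty_forms(t, n_shuffles=10, n_boot=50, rng=rng)
        assert res.underpowered


class TestPsychometric:
    def test_flat_info_value_recovered_as_wtp(self, rng):
        cfg = iv.SessionConfig.human_coins(n_trials=8000)
        params = iv.BehavioralParams(core_spec(), (1.0, 0.0, 1.0, 0.0, 0.0))
        t = iv.simulate_choices(iv.generate_offers(cfg, rng), params, rng)
        res = iv.psychometric_wtp(t, n_boot=100, rng=rng)
        # info worth exactly 1 coin by construction
        assert abs(res.wtp - 1.0) < 2.6 * res.wtp_se

    def test_zero_info_value_gives_zero_wtp(self, rng):
        cfg = iv.SessionConfig.human_coins(n_trials=8000)
        params = iv.BehavioralParams(core_spec(), (1.0, 0.0, 0.0, 0.0, 0.0))
        t = iv.simulate_choices(iv.generate_offers(cfg, rng), params, rng)
        res = iv.psychometric_wtp(t, n_boot=100, rng=rng)
        assert abs(res.wtp) < 3 * res.wtp_se

    def test_uncertainty_split_orders_wtp(self, rng):
        """With Info x Unc > 0, information is worth more on uncertain trials."""
        cfg = iv.SessionConfig.human_coins(n_trials=20_000)
        params = iv.BehavioralParams(core_spec(), (0.8, -0.05, 0.3, 0.0, 0.2))
        t = iv.simulate_choices(iv.generate_offers(cfg, rng), params, rng)
        sds = {
            k: t[[f"r_{k}_{j}" for j in (1, 2, 3, 4)]].to_numpy().std(axis=1)
            for k in (1, 2)
        }
        both_unc = (sds[1] > 0) & (sds[2] > 0)
        both_cert = (sds[1] == 0) & (sds[2] == 0)
        w_unc = iv.psychometric_wtp(t.loc[both_unc], n_boot=60, rng=rng)
        w_cert = iv.psychometric_wtp(t.loc[both_cert], n_boot=60, rng=rng)
        assert w_unc.wtp > w_cert.wtp

    def test_population_level_fit(self, rng):
        cfg = iv.SessionConfig.human_coins(n_trials=150)
        params = iv.BehavioralParams(core_spec(), (1.0, 0.0, 1.0, 0.0, 0.0))
        parts = []
        for i in range(30):
            s = iv.generate_offers(cfg, rng)
            s["session_id"] = f"p{i:02d}"
            parts.append(iv.simulate_choices(s, params, rng))
        t = pd.concat(parts, ignore_index=True)
        res = iv.psychometric_wtp(t, level="population", n_boot=60, rng=rng)
        assert abs(res.wtp - 1.0) < max(3 * res.wtp_se, 0.3)


class TestAttributeSelection:
    def test_recovers_generating_attributes(self, rng):
        cfg = iv.SessionConfig.monkey_v2(n_trials=10_000)
        spec = ModelSpec("gen", ("E[r]", "Info", "Info:Unc[r]"), "sd")
        params = iv.BehavioralParams(spec, (8.0, 0.8, 6.0))
        t = iv.simulate_choices(iv.generate_offers(cfg, rng), params, rng)
        selected = select_attributes_cv(
            t, list(timing_spec().attributes), coverage=0.99, rng=rng
        )
        assert {"E[r]", "Info:Unc[r]"} <= set(selected)
        assert len(selected) <= 6

    def test_pure_noise_selects_nothing(self, rng):
        cfg = iv.SessionConfig.monkey_v2(n_trials=2000)
        params = iv.BehavioralParams(core_spec(), (0.0,) * 5)
        t = iv.simulate_choices(iv.generate_offers(cfg, rng), params, rng)
        with pytest.warns(UserWarning, match="chance"):
            selected = select_attributes_cv(
                t, list(timing_spec().attributes), rng=rng
            )
        assert selected == []


class TestStimulationModel:
    def test_requires_stim_trials(self, coin_session):
        t, params = coin_session
        fit = ChoiceModel(t, params.spec).fit()
        with pytest.raises(ValueError, match="stimulation"):
            iv.fit_stimulation_model(t, fit.subjective_values(t))

    def test_per_session_fits(self, rng):
        from infoval.studies import stimulation_study

        cfg, params = stimulation_study(n_trials=4000)
        parts = []
        for i in range(2):
            s = iv.generate_offers(cfg, rng)
            s["session_id"] = f"s{i}"
            parts.append(iv.simulate_stimulation(
                s, params, rng, stim_prob=(0.25, 0.25), value_subtraction=1.0
            ))
        t = pd.concat(parts, ignore_index=True)
        base = iv.ChoiceModel(t.loc[t["stim"] == "none"], params.spec).fit()
        vals = base.subjective_values(t)
        by_session = iv.fit_stimulation_model(t, vals, by_session=True)
        assert set(by_session) == {"s0", "s1"}
        for res in by_session.values():
            assert abs(res.params["Stim1"] - 1.0) < 4 * res.bse["Stim1"]
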