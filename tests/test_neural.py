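"""Neural encoding models: normalization, fits, shuffle-corrected R^2,
value coding index, cross-validated peristimulus effects."""

import numpy as np
import pandas as pd
import pytest

import infoval as iv
from infoval.neural import (
    ConstantRateError,
    NeuronEncodingModel,
    classify_attribute_responsive,
    crossval_effect_timecourse,
    normalize_rates,
    shuffle_corrected_r2,
    value_coding_index,
)
from infoval.task import ModelSpec, core_spec


class TestNormalization:
    def test_z_score_against_session_bins(self):
        windows = pd.DataFrame({"rate_offer1": [4.0, 2.0, 3.0]})
        out = normalize_rates(windows, np.array([2.0, 4.0] * 50))
        np.testing.assert_allclose(out["rate_offer1"], [1.0, -1.0, 0.0])

    def test_constant_neuron_excluded(self):
        with pytest.raises(ConstantRateError):
            normalize_rates(pd.DataFrame({"r": [1.0]}), np.full(100, 7.0))

    def test_affine_invariance(self):
        windows = pd.DataFrame({"r": [1.0, 5.0, 9.0]})
        bins = np.array([1.0, 3.0, 5.0, 7.0] * 25)
        a = normalize_rates(windows, bins)
        b = normalize_rates(windows * 2, bins * 2)
        pd.testing.assert_frame_equal(a, b)


class TestEncodingModel:
    def test_noiseless_weights_recovered_exactly(self, clock_session):
        t, params, _nu = clock_session
        rng = np.random.default_rng(1)
        scheme = iv.CodingScheme(noise_sd=0.0, gain=1.0, baseline=0.25)
        resp = iv.simulate_neuron(t, scheme, params, rng)
        fit = NeuronEncodingModel(
            resp["rate_offer1"].to_numpy(), t, params.spec, 1
        ).fit()
        np.testing.assert_allclose(
            fit.params[list(params.spec.attributes)], params.beta, atol=1e-8
        )
        assert fit.params["const"] == pytest.approx(0.25, abs=1e-8)

    def test_minimum_trial_floor(self, clock_session):
        t, params, _nu = clock_session
        with pytest.raises(ValueError, match="20"):
            NeuronEncodingModel(np.zeros(10), t.iloc[:10], params.spec, 1)

    def test_null_neuron_false_positive_rate(self, clock_session):
        t, params, _nu = clock_session
        rng = np.random.default_rng(2)
        sub = t.iloc[:150]
        hits = total = 0
        for _ in range(150):
            y = rng.normal(size=len(sub))
            fit = NeuronEncodingModel(y, sub, params.spec, 1).fit()
            hits += int((fit.attribute_pvalues() < 0.05).sum())
            total += len(fit.attribute_pvalues())
        assert 0.03 < hits / total < 0.075

    def test_full_integration_weights_align_with_value(self, clock_session):
        t, params, _nu = clock_session
        rng = np.random.default_rng(3)
        scheme = iv.CodingScheme(noise_sd=0.1, gain=1.0)
        resp = iv.simulate_neuron(t, scheme, params, rng)
        fit = NeuronEncodingModel(
            resp["rate_offer2"].to_numpy()[:300], t.iloc[:300], params.spec, 2
        ).fit()
        w = fit.params[list(params.spec.attributes)].to_numpy()
        b = np.asarray(params.beta)
        cos = w @ b / np.linalg.norm(w) / np.linalg.norm(b)
        assert cos > 0.99


class TestShuffleCorrectedR2:
    def test_pure_noise_corrects_to_zero(self, clock_session):
        t, params, _nu = clock_session
        rng = np.random.default_rng(4)
        x = iv.attribute_matrix(t.iloc[:300], params.spec, 1)
        vals = [
            shuffle_corrected_r2(rng.normal(size=300), x, 100, rng)
            for _ in range(40)
        ]
        vals = np.asarray(vals)
        assert abs(vals.mean()) < max(
            2 * vals.std(ddof=1) / np.sqrt(len(vals)), 0.01
        )

    def test_noiseless_neuron_near_one(self, clock_session):
        t, params, _nu = clock_session
        rng = np.random.default_rng(5)
        resp = iv.simulate_neuron(
            t, iv.CodingScheme(noise_sd=0.0), params, rng
        )
        x = iv.attribute_matrix(t, params.spec, 1)
        assert shuffle_corrected_r2(
            resp["rate_offer1"].to_numpy(), x, 50, rng
        ) > 0.9

    def test_attribute_model_nests_value_model(self, clock_session, clock_fit):
        """Corrected R^2 of the full attribute model is never meaningfully
        below the one-regressor value model's."""
        t, params, _nu = clock_session
        fit, values = clock_fit
        rng = np.random.default_rng(6)
        x_attr = iv.attribute_matrix(t, params.spec, 1)
        for hyp in ("full_integration", "random_mixture", "single_attribute"):
            for _ in range(5):
                scheme = iv.CodingScheme(hypothesis=hyp, noise_sd=0.8)
                resp = iv.simulate_neuron(t, scheme, params, rng)
                y = resp["rate_offer1"].to_numpy()
                r2a = shuffle_corrected_r2(y, x_attr, 60, rng)
                r2v = shuffle_corrected_r2(
                    y, values[["V1"]].to_numpy(), 60, rng
                )
                assert r2a >= r2v - 0.02


class TestValueCodingIndex:
    def test_noiseless_full_integration_scores_one(self, clock_session):
        t, params, _nu = clock_session
        rng = np.random.default_rng(7)
        resp = iv.simulate_neuron(
            t, iv.CodingScheme(noise_sd=0.0), params, rng
        )
        # the neuron encodes the generating V, so use the ground-truth values
        v1, v2 = iv.simulate.offer_values(t, params)
        values = pd.DataFrame({"V1": v1, "V2": v2}, index=t.index)
        res = value_coding_index(
            {1: resp["rate_offer1"].to_numpy(), 2: resp["rate_offer2"].to_numpy()},
            t, params.spec, values, n_shuffles=40, rng=rng,
        )
        assert res.strong_attribute
        assert res.index == pytest.approx(1.0)  # clamped ratio
        assert res.value_sign == 1

    def test_negative_coder_sign(self, clock_session, clock_fit):
        t, params, _nu = clock_session
        _fit, values = clock_fit
        rng = np.random.default_rng(8)
        resp = iv.simulate_neuron(
            t, iv.CodingScheme(noise_sd=0.2, sign=-1), params, rng
        )
        res = value_coding_index(
            {1: resp["rate_offer1"].to_numpy(), 2: resp["rate_offer2"].to_numpy()},
            t, params.spec, values, n_shuffles=40, rng=rng,
        )
        assert res.value_sign == -1
        assert res.index > 0.9

    def test_gate_failure_leaves_index_undefined(self, clock_session, clock_fit):
        t, params, _nu = clock_session
        _fit, values = clock_fit
        rng = np.random.default_rng(9)
        noise = {k: rng.normal(size=len(t)) for k in (1, 2)}
        res = value_coding_index(
            noise, t, params.spec, values, n_shuffles=40, rng=rng
        )
        assert res.index is None
        assert not res.strong_attribute

    def test_index_bounded(self, clock_session, clock_fit):
        t, params, _nu = clock_session
        _fit, values = clock_fit
        rng = np.random.default_rng(10)
        for hyp in ("random_mixture", "partial_integration"):
            resp = iv.simulate_neuron(
                t, iv.CodingScheme(hypothesis=hyp, noise_sd=0.5), params, rng
            )
            res = value_coding_index(
                {1: resp["rate_offer1"].to_numpy(),
                 2: resp["rate_offer2"].to_numpy()},
                t, params.spec, values, n_shuffles=40, rng=rng,
            )
            if res.index is not None:
                assert 0.0 <= res.index <= 1.0


def test_attribute_responsive_null_rate(clock_session):
    """Pure-noise neurons are 'responsive' at ~ 1 - 0.95^(2m)."""
    t, params, _nu = clock_session
    rng = np.random.default_rng(11)
    sub = t.iloc[:150]
    m = len(params.spec.attributes)
    expected = 1 - 0.95 ** (2 * m)
    flags = []
    for _ in range(250):
        fits = [
            NeuronEncodingModel(rng.normal(size=len(sub)), sub, params.spec, k).fit()
            for k in (1, 2)
        ]
        flags.append(classify_attribute_responsive(*fits))
    rate = np.mean(flags)
    # correlated attribute tests push the any-attribute rate slightly off the
    # independence approximation; require agreement to ~0.12
    assert abs(rate - expected) < 0.12


class TestCrossvalTimecourse:
    @staticmethod
    def _population(trials, spec, rng, n_neurons, info_unc_gain, T=10):
        pop = []
        for _ in range(n_neurons):
            sign = rng.choice([-1.0, 1.0])
            rec = {"trials": trials, "traces": {}, "fits": {}}
            for k in (1, 2):
                outs = trials[[f"r_{k}_{j}" for j in (1, 2, 3, 4)]].to_numpy(float)
                info = trials[f"info_{k}"].to_numpy()
                signal = sign * info_unc_gain * info * outs.std(axis=1)
                traces = signal[:, None] + rng.normal(0, 1, (len(trials), T))
                rec["traces"][k] = traces
                main = traces[:, 3:7].mean(axis=1)
                rec["fits"][k] = NeuronEncodingModel(main, trials, spec, k).fit()
            pop.append(rec)
        return pop

    def test_true_mixed_sign_coding_rectifies_positive(self, clock_session):
        t, params, _nu = clock_session
        rng = np.random.default_rng(12)
        pop = self._population(t, params.spec, rng, 30, info_unc_gain=8.0)
        eff = crossval_effect_timecourse(pop, "InfoxUnc")
        assert eff.n_responses > 30
        assert (eff.mean > 0).all()

    def test_single_offer_neurons_excluded(self, clock_session):
        t, params, _nu = clock_session
        rng = np.random.default_rng(13)
        pop = self._population(t, params.spec, rng, 3, info_unc_gain=8.0)
        for rec in pop:
            del rec["traces"][1]
            del rec["fits"][1]
        with pytest.warns(UserWarning, match="no responses"):
            eff = crossval_effect_timecourse(pop, "InfoxUnc")
        assert eff.n_responses == 0

    def test_unc_type_effect_dissociates_5050_from_255025(self, clock_session):
        t, params, _nu = clock_session
        rng = np.random.default_rng(14)
        pop = self._population(t, params.spec, rng, 30, info_unc_gain=8.0)
        eff = crossval_effect_timecourse(pop, "InfoxUncType")
        # SD-coded signal is larger for 50/50 than 25/50/25, so positive
        assert eff.n_responses > 0
        assert eff.mean.mean() > 0
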