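"""Risk network forward pass, partial-likelihood loss, and training loop."""

import numpy as np
import pytest

from conftest import finite_difference_gradient
from ttsurv.data import SurvivalDataset
from ttsurv.embedding import EncoderConfig
from ttsurv.model import (LinearCoxModel, LinearRiskNetwork, TrainingConfig,
                          TTSurvModel, TTSurvNetwork, forward_risk,
                          full_risk_set_loss, partial_likelihood_loss, train)
from ttsurv.schema import Feature, FeatureSchema
from ttsurv.simulate import linear_ph_scenario, simulate_cohort

SCHEMA = FeatureSchema((Feature("x", "continuous"),
                        Feature("grp", "categorical", ("a", "b", "c"))))


def make_data(n, seed=0, all_events=False):
    rng = np.random.default_rng(seed)
    d = np.ones(n, int) if all_events else rng.integers(0, 2, n)
    if d.sum() == 0:
        d[0] = 1
    return SurvivalDataset(SCHEMA, rng.normal(size=(n, 1)),
                           rng.integers(0, 3, (n, 1)), rng.uniform(1, 100, n),
                           d, np.arange(n))


def direct_loss_oracle(g_fn, data):
    """Exact partial likelihood by explicit double summation."""
    total = 0.0
    n_events = 0
    for i in range(data.n):
        if data.d[i] != 1:
            continue
        n_events += 1
        gi = g_fn(data.t[i], i)
        s = sum(np.exp(g_fn(data.t[i], j) - gi)
                for j in range(data.n) if data.t[j] >= data.t[i])
        total += np.log(s)
    return total / n_events


class TestForwardRisk:
    def setup_method(self):
        self.net = TTSurvNetwork(
            SCHEMA, encoder=EncoderConfig(d_embed=4, n_layers=1, n_heads=2,
                                          mlp_hidden=8), hidden=8, seed=0)

    def test_deterministic_given_parameters(self):
        a = forward_risk(self.net, 50.0, [0.3], [1])
        b = forward_risk(self.net, 50.0, [0.3], [1])
        np.testing.assert_array_equal(a, b)

    def test_batched_call_matches_single_calls(self):
        t = np.array([10.0, 20.0, 30.0])
        xc = np.array([[0.1], [0.2], [0.3]])
        xk = np.array([[0], [1], [2]])
        batched = forward_risk(self.net, t, xc, xk)
        singles = [forward_risk(self.net, t[i], xc[i], xk[i])[0]
                   for i in range(3)]
        np.testing.assert_allclose(batched, singles, rtol=1e-12)

    def test_zeroed_head_gives_constant_bias(self):
        self.net.dense["Wh"].data[:] = 0.0
        self.net.dense["bh"].data[:] = 1.75
        out = forward_risk(self.net, [5.0, 500.0], [[0.0], [2.0]], [[0], [2]])
        np.testing.assert_allclose(out, [1.75, 1.75], rtol=1e-12)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            forward_risk(self.net, np.nan, [0.0], [0])

    def test_risk_matrix_agrees_with_autodiff_path(self):
        data = make_data(7, seed=3)
        times = np.array([5.0, 50.0])
        M = self.net.risk_matrix(times, data)
        for r, t in enumerate(times):
            via_tensor = self.net.risk_tensor(
                data, np.arange(7), np.full(7, t)).data
            np.testing.assert_allclose(M[r], via_tensor, rtol=1e-10)


class TestPartialLikelihoodLoss:
    def test_two_subject_hand_computation(self):
        # both events, constant risk: log(2)/2
        data = SurvivalDataset(SCHEMA, np.zeros((2, 1)), np.zeros((2, 1), int),
                               [1.0, 2.0], [1, 1], np.arange(2))
        net = LinearRiskNetwork(SCHEMA)
        net.beta.data[:] = 0.0
        loss = partial_likelihood_loss(net, data)
        assert loss == pytest.approx(np.log(2) / 2, rel=1e-12)

    def test_single_event_alone_in_risk_set_gives_zero(self):
        data = SurvivalDataset(SCHEMA, np.zeros((1, 1)), np.zeros((1, 1), int),
                               [3.0], [1], np.arange(1))
        net = LinearRiskNetwork(SCHEMA)
        assert partial_likelihood_loss(net, data) == pytest.approx(0.0, abs=1e-12)

    def test_full_risk_sets_match_direct_summation_oracle(self):
        net = TTSurvNetwork(SCHEMA, encoder=EncoderConfig(
            d_embed=4, n_layers=1, n_heads=2, mlp_hidden=8), hidden=8, seed=1)
        for seed in range(5):
            data = make_data(6, seed=seed)
            expected = direct_loss_oracle(
                lambda t, j: net.risk_matrix(np.array([t]),
                                             data.subset([j]))[0, 0], data)
            assert full_risk_set_loss(net, data) == pytest.approx(
                expected, abs=1e-10)

    def test_loss_invariant_to_constant_risk_shift(self):
        net = TTSurvNetwork(SCHEMA, encoder=EncoderConfig(
            d_embed=4, n_layers=1, n_heads=2, mlp_hidden=8), hidden=8, seed=2)
        data = make_data(10, seed=4)
        base = full_risk_set_loss(net, data)
        net.dense["bh"].data += 13.7
        assert full_risk_set_loss(net, data) == pytest.approx(base, rel=1e-12)
        # sampled variant with fixed seed is shift-invariant too
        a = partial_likelihood_loss(net, data, sampled_controls=3, seed=5)
        net.dense["bh"].data -= 13.7
        b = partial_likelihood_loss(net, data, sampled_controls=3, seed=5)
        assert a == pytest.approx(b, rel=1e-12)

    def test_loss_is_non_negative(self):
        net = LinearRiskNetwork(SCHEMA, seed=3)
        for seed in range(5):
            data = make_data(8, seed=seed)
            assert partial_likelihood_loss(net, data) >= 0.0
            assert partial_likelihood_loss(net, data, sampled_controls=2,
                                           seed=seed) >= 0.0

    def test_no_events_is_an_error(self):
        data = SurvivalDataset(SCHEMA, np.zeros((2, 1)), np.zeros((2, 1), int),
                               [1.0, 2.0], [0, 0], np.arange(2))
        with pytest.raises(ValueError, match="event"):
            partial_likelihood_loss(LinearRiskNetwork(SCHEMA), data)

    def test_gradient_matches_central_finite_differences(self):
        # tiny model (2 parameters), 6-subject batch, fixed risk sets
        from ttsurv.model import _pair_loss
        net = LinearRiskNetwork(SCHEMA, seed=7)
        net.beta.data[:] = np.random.default_rng(0).normal(0, 0.5, (2, 1))
        data = make_data(6, seed=11)
        ev = np.flatnonzero(data.d == 1)
        ctrl = [np.flatnonzero(data.t >= data.t[i]) for i in ev]
        width = max(len(c) for c in ctrl)
        padded = np.stack([np.resize(c, width) for c in ctrl])
        loss = _pair_loss(net, data, ev, padded)
        loss.backward()
        analytic = net.beta.grad.copy()
        numeric = finite_difference_gradient(
            lambda: _pair_loss(net, data, ev, padded).item(), net.beta.data)
        np.testing.assert_allclose(analytic, numeric, rtol=1e-4)

    def test_ttsurv_network_gradient_matches_finite_differences(self):
        # same check through the transformer branch on a pocket-size network
        from ttsurv.model import _pair_loss
        net = TTSurvNetwork(SCHEMA, encoder=EncoderConfig(
            d_embed=2, n_layers=1, n_heads=1, mlp_hidden=2), hidden=2, seed=5)
        data = make_data(6, seed=13)
        ev = np.flatnonzero(data.d == 1)
        padded = np.stack([np.resize(np.flatnonzero(data.t >= data.t[i]), 6)
                           for i in ev])
        loss = _pair_loss(net, data, ev, padded)
        loss.backward()
        for p in [net.dense["W1"], net.table.per_level,
                  net.encoder_params[0]["Wq"]]:
            analytic = p.grad.copy()
            numeric = finite_difference_gradient(
                lambda: _pair_loss(net, data, ev, padded).item(), p.data)
            np.testing.assert_allclose(analytic, numeric, rtol=1e-4, atol=1e-8)


class TestTraining:
    def small_config(self, **kw):
        base = dict(learning_rate=5e-3, batch_size=16, max_epochs=12,
                    patience=4, sampled_controls=4, seed=0)
        base.update(kw)
        return TrainingConfig(**base)

    def test_identical_seeds_give_identical_histories(self):
        data = make_data(40, seed=1)
        valid = make_data(20, seed=2)
        h1 = train(LinearRiskNetwork(SCHEMA, seed=0), data, valid,
                   self.small_config())
        h2 = train(LinearRiskNetwork(SCHEMA, seed=0), data, valid,
                   self.small_config())
        assert h1 == h2

    def test_early_stopping_on_unimprovable_validation(self):
        # constant-risk validation data: loss cannot improve, stop fast
        rng = np.random.default_rng(5)
        valid = SurvivalDataset(SCHEMA, np.zeros((10, 1)),
                                np.zeros((10, 1), int), rng.uniform(1, 50, 10),
                                np.ones(10, int), np.arange(10))
        data = make_data(30, seed=3)
        net = LinearRiskNetwork(SCHEMA, seed=0)
        net.beta.data[:] = 0.0
        history = train(net, data, valid,
                        self.small_config(patience=1, learning_rate=1e-9))
        assert len(history["train_loss"]) <= 2

    def test_training_reduces_validation_loss_on_informative_data(self):
        scn = linear_ph_scenario(n=700, seed=5)
        data = simulate_cohort(scn)
        res = LinearCoxModel(data).fit(TrainingConfig(
            learning_rate=0.01, batch_size=64, max_epochs=40, patience=10,
            sampled_controls=8, seed=0))
        h = res.history["valid_loss"]
        assert min(h) < h[0]

    def test_best_epoch_parameters_are_restored(self):
        data = make_data(40, seed=6)
        valid = make_data(25, seed=7)
        net = LinearRiskNetwork(SCHEMA, seed=1)
        history = train(net, data, valid, self.small_config(max_epochs=8))
        assert full_risk_set_loss(net, valid) == pytest.approx(
            min(history["valid_loss"]), rel=1e-12)

    def test_monotone_severity_effect_learned(self):
        # hazard dominated by an ordinal covariate: mean learned risk at the
        # top level must exceed the bottom level
        scn = linear_ph_scenario(n=600, seed=9)
        data = simulate_cohort(scn)
        res = LinearCoxModel(data).fit(TrainingConfig(
            learning_rate=0.02, batch_size=64, max_epochs=60, patience=15,
            sampled_controls=8, seed=0))
        dv = data.x_cat[:, [f.name for f in data.schema.categorical
                            ].index("deauville")]
        g = res.network.risk_matrix([1.0], res._prep(data))[0]
        assert g[dv == 4].mean() > g[dv == 0].mean()


class TestResultsObject:
    def test_summary_and_predictions_round_trip(self, tmp_path):
        scn = linear_ph_scenario(n=300, seed=4)
        data = simulate_cohort(scn)
        res = TTSurvModel(data, encoder=EncoderConfig(
            d_embed=4, n_layers=1, n_heads=2, mlp_hidden=8), hidden=8).fit(
            TrainingConfig(learning_rate=5e-3, batch_size=32, max_epochs=4,
                           patience=2, sampled_controls=4, seed=0))
        text = res.summary()
        assert "events (train)" in text and "best epoch" in text
        sub = data.subset(np.arange(6))
        days, crossed = res.predict_median(sub)
        assert days.shape == (6,) and crossed.dtype == bool
        res.save(tmp_path / "model.npz")
        from ttsurv.model import SurvivalResults
        back = SurvivalResults.load(tmp_path / "model.npz")
        np.testing.assert_allclose(back.risk_score(sub), res.risk_score(sub),
                                   rtol=1e-12)
        np.testing.assert_allclose(back.predict_median(sub)[0], days)


def test_linear_baseline_helper_trains_with_shared_machinery():
    scn = linear_ph_scenario(n=300, seed=8)
    data = simulate_cohort(scn)
    from ttsurv.data import stratified_kfold
    tr, va = stratified_kfold(data, 5, seed=0)[0]
    from ttsurv.model import linear_baseline
    net, history = linear_baseline(
        data.subset(tr), data.subset(va),
        TrainingConfig(learning_rate=0.02, batch_size=64, max_epochs=20,
                       patience=5, sampled_controls=8, seed=0))
    assert net.coefficients.shape == (10,)
    assert len(history["valid_loss"]) == len(history["train_loss"])
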