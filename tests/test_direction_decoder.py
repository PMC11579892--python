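"""GMM training, per-sample likelihoods, evidence accumulation, decoding."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, qmc

from synid.direction_decoder import (
    DIRECTION_NAMES,
    DIRECTIONS,
    DecoderModel,
    DirectionGmm,
    DirectionLabel,
    accumulate,
    decode_trial,
    direction_likelihoods,
    estimate_direction,
    train_gmms,
)
from synid.errors import DataError, TrainingError, TrialExcludedError
from synid.signal_processing import EnvelopeSeries, OnsetEvent
from synid.synergy_model import ActivationSeries, SynergyModel


def _labeled_activations(rng, per_dir=60, n_syn=4, separation=0.0):
    H, labels = [], []
    for i, d in enumerate(DIRECTION_NAMES):
        X = np.abs(rng.normal(1.0 + separation * i, 0.3, size=(per_dir, n_syn)))
        H.append(X)
        labels += [d] * per_dir
    return ActivationSeries(
        H=np.concatenate(H).T, fs=100.0, labels=np.array(labels)
    )


def _uniform_model(gmm, n_syn=4, t_acc=0.6):
    W = np.eye(6)[:, :n_syn] + 0.01
    W /= np.linalg.norm(W, axis=0)
    return DecoderModel(
        synergy=SynergyModel(W=W, n_syn=n_syn),
        gmms={d: gmm for d in DIRECTION_NAMES},
        t_acc_s=t_acc,
    )


@pytest.fixture()
def simple_gmm(rng):
    return DirectionGmm(
        weights=np.array([0.5, 0.3, 0.2]),
        means=rng.normal(size=(3, 4)),
        covariances=np.stack([np.eye(4)] * 3) * 0.5,
    )


class TestDirectionLabel:
    def test_name_angle_index_bijection(self):
        for i, (name, angle) in enumerate(
            zip(DIRECTION_NAMES, (0, 45, 90, 135, 180, 225, 270, 315))
        ):
            d = DirectionLabel.from_name(name)
            assert (d.index, d.angle_deg) == (i, angle)
            assert DirectionLabel.from_index(i) is d


class TestTrainGmms:
    def test_weights_sum_to_one(self, rng):
        gmms = train_gmms(_labeled_activations(rng), seed=0)
        for g in gmms.values():
            assert g.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_mixture_mean_equals_sample_mean(self, rng):
        # at any EM fixed point the mixture mean matches the data mean
        acts = _labeled_activations(rng, per_dir=200)
        gmms = train_gmms(acts, seed=1)
        X = acts.H.T[acts.labels == "N"]
        g = gmms["N"]
        mix_mean = g.weights @ g.means
        np.testing.assert_allclose(mix_mean, X.mean(axis=0), atol=1e-6)

    def test_too_few_samples_names_direction(self, rng):
        acts = _labeled_activations(rng, per_dir=5)
        with pytest.raises(TrainingError, match="direction E: 5 samples"):
            train_gmms(acts)

    def test_fitted_density_integrates_to_one(self, rng):
        # quasi-random integration oracle over a generous bounding box
        acts = _labeled_activations(rng, per_dir=300, n_syn=2)
        g = train_gmms(acts, seed=2)["E"]
        X = acts.H.T[acts.labels == "E"]
        lo = X.min(axis=0) - 5 * X.std(axis=0)
        hi = X.max(axis=0) + 5 * X.std(axis=0)
        pts = qmc.Sobol(d=2, seed=0).random_base2(20)  # ~1e6 points
        pts = lo + pts * (hi - lo)
        dens = sum(
            w * multivariate_normal.pdf(pts, mean=m, cov=c)
            for w, m, c in zip(g.weights, g.means, g.covariances)
        )
        integral = dens.mean() * np.prod(hi - lo)
        assert integral == pytest.approx(1.0, rel=0.02)


class TestLikelihoods:
    def test_identical_mixtures_give_uniform(self, simple_gmm):
        p = direction_likelihoods(np.zeros(4), _uniform_model(simple_gmm))
        np.testing.assert_allclose(p, 0.125, atol=1e-12)

    def test_well_separated_mixture_wins(self):
        gmms = {}
        for i, d in enumerate(DIRECTION_NAMES):
            mean = np.zeros(4)
            mean[0] = 10.0 * i     # 10-sigma spacing
            gmms[d] = DirectionGmm(
                weights=np.array([1.0, 0.0, 0.0]) + np.array([0, 1e-15, 1e-15]),
                means=np.stack([mean] * 3),
                covariances=np.stack([np.eye(4)] * 3),
            )
        model = _uniform_model(next(iter(gmms.values())))
        model.gmms = gmms
        p = direction_likelihoods(gmms["N"].means[0], model)
        assert p[DirectionLabel.from_name("N").index] > 0.99

    def test_normalization_contract(self, simple_gmm, rng):
        model = _uniform_model(simple_gmm)
        for _ in range(20):
            p = direction_likelihoods(rng.uniform(0, 2, 4), model)
            assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_permutation_equivariance(self, rng):
        gmms = train_gmms(_labeled_activations(rng, separation=0.3), seed=3)
        model = _uniform_model(gmms["E"])
        model.gmms = gmms
        c = rng.uniform(0, 2, 4)
        p = direction_likelihoods(c, model)
        rolled = {DIRECTION_NAMES[(i + 1) % 8]: gmms[DIRECTION_NAMES[i]]
                  for i in range(8)}
        model.gmms = rolled
        p2 = direction_likelihoods(c, model)
        np.testing.assert_allclose(np.roll(p, 1), p2, atol=1e-12)


class TestAccumulate:
    def test_uniform_is_fixed_point(self):
        u = np.full(8, 0.125)
        np.testing.assert_allclose(accumulate(u, u), u, atol=1e-15)

    def test_closed_form_ratio(self):
        # constant likelihoods 0.3 vs 0.1 -> P(d*) after k steps = 3^k/(3^k+7)
        lik = np.full(8, 0.1)
        lik[2] = 0.3
        P = np.full(8, 0.125)
        for k in range(1, 61):
            P = accumulate(P, lik)
            expected = 3.0**k / (3.0**k + 7.0)
            assert P[2] == pytest.approx(expected, abs=1e-12)
        assert P.sum() == pytest.approx(1.0, abs=1e-12)

    def test_vanishing_product_keeps_previous(self):
        prev = np.full(8, 0.125)
        out = accumulate(prev, np.zeros(8))
        np.testing.assert_array_equal(out, prev)


class TestEstimateDirection:
    @pytest.mark.parametrize(
        "vec,expected",
        [
            ([1, 0, 0, 0, 0, 0, 0, 0], "E"),
            ([0, 0, 0.5, 0, 0, 0, 0.5, 0], "N"),   # N/S tie -> lower index
            ([0.125] * 8, "E"),
        ],
    )
    def test_argmax_with_tie_rule(self, vec, expected):
        assert estimate_direction(np.array(vec)).name == expected


class TestDecodeTrial:
    def test_iteration_count_at_defaults(self, trained_model, small_session):
        from synid.pipeline import PipelineConfig, control_envelope
        from synid.signal_processing import detect_onset

        trial = small_session.test_trials[0]
        env = control_envelope(trial.emg, PipelineConfig())
        onset = detect_onset(env)
        trace = decode_trial(env, onset, trained_model)
        assert trace.n_iterations == 60
        assert trace.cumulative.shape == (60, 8)
        np.testing.assert_allclose(trace.cumulative.sum(axis=1), 1.0, atol=1e-9)
        # running estimate is the argmax of each cumulative vector
        np.testing.assert_array_equal(
            trace.estimates, trace.cumulative.argmax(axis=1)
        )

    def test_all_zero_envelope_is_deterministic(self, trained_model):
        env = EnvelopeSeries(np.zeros((6, 200)), fs=100.0)
        onset = OnsetEvent(index=50, time_s=0.5,
                           threshold_trace=np.zeros(200), sum_trace=np.zeros(200))
        trace = decode_trial(env, onset, trained_model)
        np.testing.assert_array_equal(
            trace.likelihoods, np.tile(trace.likelihoods[0], (60, 1))
        )
        assert len(set(trace.estimates.tolist())) == 1

    def test_too_short_trial_excluded(self, trained_model):
        env = EnvelopeSeries(np.ones((6, 80)), fs=100.0)
        onset = OnsetEvent(index=50, time_s=0.5,
                           threshold_trace=np.zeros(80), sum_trace=np.zeros(80))
        with pytest.raises(TrialExcludedError):
            decode_trial(env, onset, trained_model)


def test_decoder_model_roundtrip(tmp_path, trained_model):
    from synid.io import load_decoder, save_decoder

    path = tmp_path / "model.json"
    save_decoder(trained_model, path)
    loaded = load_decoder(path)
    np.testing.assert_array_equal(loaded.synergy.W, trained_model.synergy.W)
    for d in DIRECTION_NAMES:
        np.testing.assert_array_equal(
            loaded.gmms[d].covariances, trained_model.gmms[d].covariances
        )
    assert loaded.t_acc_s == trained_model.t_acc_s
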