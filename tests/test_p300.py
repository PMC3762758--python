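"""xDAWN spatial filtering, Bayesian LDA and per-object P300 decisions."""

import numpy as np
import pytest

from hybridbci.p300 import (NONTARGET, TARGET, P300Pipeline, decide_objects,
                            fit_blda, fit_xdawn, score_epoch)
from hybridbci.signals import (EMOTIV_CHANNELS, TrialSet, Window, bandpass,
                               downsample, extract_epochs)
from hybridbci.synth import ERPTemplate, SynthConfig, gen_p300_stream


def labelled_epochs(seed=41, snr=4.0, n_flashes=30, favorite=0):
    """Preprocessed, target/non-target-labelled epoch set from a stream."""
    rec, _ = gen_p300_stream(SynthConfig(seed=seed, snr=snr), 2, n_flashes,
                             favorite)
    filtered = bandpass(rec, 1.0, 20.0)
    ep = extract_epochs(filtered, {0, 1}, 0.6)
    ep = downsample(ep, rec.rate, 32.0)
    labels = [TARGET if w.label == favorite else NONTARGET
              for w in ep.windows]
    return TrialSet(ep.windows, "P300", labels)


def xdawn_oracle(ts, n_components=3):
    """Independent route: whiten by the pooled covariance, then
    eigendecompose the whitened evoked covariance."""
    targets = [w.data for w, lab in zip(ts.windows, ts.y) if lab == TARGET]
    evoked = np.mean(targets, axis=0)
    n_t = evoked.shape[1]
    Cs = evoked @ evoked.T / n_t
    X = ts.X
    Cx = np.einsum("kct,kdt->cd", X, X) / (X.shape[0] * n_t)
    Cx += 1e-12 * np.trace(Cx) / len(Cx) * np.eye(len(Cx))
    evals, evecs = np.linalg.eigh(Cx)
    Wh = evecs @ np.diag(1.0 / np.sqrt(evals)) @ evecs.T
    s_vals, s_vecs = np.linalg.eigh(Wh @ Cs @ Wh)
    full = Wh @ s_vecs
    order = np.argsort(s_vals)[::-1][:n_components]
    return full[:, order], s_vals[order]


class TestXdawn:
    def test_single_channel_projection_is_scalar_multiple(self):
        ts = labelled_epochs()
        one = TrialSet([Window(w.data[:1], w.start_time, w.duration,
                               w.label, w.rate, ("P7",))
                        for w in ts.windows], "P300", list(ts.class_labels))
        model = fit_xdawn(one, n_components=1)
        assert model.spatial_filters.shape == (1, 1)
        epoch = one.windows[0].data
        np.testing.assert_allclose(
            model.project(epoch),
            model.spatial_filters[0, 0] * epoch, rtol=1e-12)

    def test_recovers_planted_spatial_pattern(self):
        ts = labelled_epochs(seed=41, snr=4.0)
        model = fit_xdawn(ts)
        planted = ERPTemplate().pattern(EMOTIV_CHANNELS)
        r = np.corrcoef(model.forward_patterns[:, 0], planted)[0, 1]
        assert abs(r) > 0.95

    def test_matches_whitening_oracle(self):
        rng = np.random.default_rng(6)
        windows = []
        for k in range(30):
            data = rng.standard_normal((4, 19))
            lab = TARGET if k % 3 == 0 else NONTARGET
            if lab == TARGET:
                data[1] += np.linspace(0, 1, 19)  # weak structured evoked
            windows.append(Window(data, 0.0, 0.6, label=lab, rate=32.0,
                                  channel_names=("a", "b", "c", "d")))
        ts = TrialSet(windows, "P300")
        model = fit_xdawn(ts, n_components=3)
        W_ref, vals_ref = xdawn_oracle(ts, 3)
        np.testing.assert_allclose(model.eigenvalues, vals_ref, atol=1e-8)
        for got, ref in zip(model.spatial_filters, W_ref.T):
            sign = np.sign(got @ ref)
            np.testing.assert_allclose(got, sign * ref, atol=1e-6)

    def test_null_amplitude_not_above_permutation_distribution(self):
        ts = labelled_epochs(seed=43, snr=0.0)
        observed = fit_xdawn(ts).eigenvalues[0]
        rng = np.random.default_rng(0)
        null = []
        labels = np.array(ts.class_labels)
        for _ in range(50):
            perm = TrialSet(ts.windows, "P300",
                            list(rng.permutation(labels)))
            null.append(fit_xdawn(perm).eigenvalues[0])
        # empirical p-value of the observed leading eigenvalue
        p = np.mean(np.asarray(null) >= observed)
        assert p > 0.05

    def test_too_few_targets_rejected(self):
        ts = labelled_epochs()
        two = TrialSet(ts.windows[:5], "P300",
                       [TARGET, TARGET, NONTARGET, NONTARGET, NONTARGET])
        with pytest.raises(ValueError):
            fit_xdawn(two, n_components=3)


class TestBLDA:
    @staticmethod
    def clusters(sep=4.0, n=40, d=6, seed=7):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 1, (n, d)),
                       rng.normal(sep, 1, (n, d))])
        y = np.array([NONTARGET] * n + [TARGET] * n)
        return X, y

    def test_fixed_hyperparameters_equal_ridge_solution(self):
        X, y = self.clusters()
        alpha, beta = 2.5, 4.0
        model = fit_blda(X, y, alpha=alpha, beta=beta)
        phi = np.hstack([X, np.ones((len(X), 1))])
        ridge = np.linalg.solve(phi.T @ phi + alpha / beta * np.eye(7),
                                phi.T @ y)
        np.testing.assert_allclose(model.weights, ridge, atol=1e-8)

    def test_separated_clusters_classified_perfectly(self):
        X, y = self.clusters()
        model = fit_blda(X, y)
        assert (np.sign(model.score(X)) == y).all()

    def test_pure_noise_dimension_shrinks(self):
        # n large enough that chance correlation of the noise dimension is
        # well below the informative-weight scale
        X, y = self.clusters(sep=4.0, n=2000)
        rng = np.random.default_rng(8)
        X_aug = np.hstack([X, rng.standard_normal((len(X), 1))])
        model = fit_blda(X_aug, y)
        w = model.weights[:-1]  # drop bias
        assert abs(w[-1]) < 0.10 * np.mean(np.abs(w[:-1]))

    def test_evidence_non_decreasing(self):
        X, y = self.clusters(sep=1.0)
        model = fit_blda(X, y)
        path = np.asarray(model.evidence_path)
        assert np.all(np.diff(path) > -1e-6)
        assert model.alpha > 0 and model.beta > 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_blda(np.zeros((4, 2)), [TARGET] * 4)

    def test_non_finite_features_rejected(self):
        X, y = self.clusters()
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_blda(X, y)


@pytest.fixture(scope="module")
def fitted():
    ts = labelled_epochs(seed=44, snr=3.0)
    xd = fit_xdawn(ts)
    feats = np.stack([xd.project(w.data).ravel() for w in ts.windows])
    bl = fit_blda(feats, ts.y)
    return ts, xd, bl


class TestScoring:

    def test_mean_target_epoch_scores_positive(self, fitted):
        ts, xd, bl = fitted
        mean_target = np.mean([w.data for w, lab in zip(ts.windows, ts.y)
                               if lab == TARGET], axis=0)
        assert score_epoch(xd, bl, mean_target) > 0

    def test_zero_epoch_scores_the_bias(self, fitted):
        ts, xd, bl = fitted
        zero = np.zeros_like(ts.windows[0].data)
        assert score_epoch(xd, bl, zero) == pytest.approx(bl.weights[-1])

    def test_score_is_affine(self, fitted):
        ts, xd, bl = fitted
        a, b = ts.windows[0].data, ts.windows[1].data
        zero = np.zeros_like(a)
        lhs = (score_epoch(xd, bl, a + b) - score_epoch(xd, bl, a)
               - score_epoch(xd, bl, b) + score_epoch(xd, bl, zero))
        assert lhs == pytest.approx(0.0, abs=1e-9)

    def test_shape_mismatch_rejected(self, fitted):
        _, xd, bl = fitted
        with pytest.raises(ValueError):
            score_epoch(xd, bl, np.zeros((14, 76)))


class TestDecisions:
    def test_equal_scores_below_threshold_flag_nothing(self):
        flags, _ = decide_objects({0: [1.0] * 5, 1: [1.0] * 5},
                                  threshold=2.0)
        assert not any(flags.values())

    def test_unequal_flash_counts_rejected(self):
        with pytest.raises(ValueError):
            decide_objects({0: [1.0] * 5, 1: [1.0] * 4})

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            decide_objects({0: [], 1: [1.0]})
        with pytest.raises(ValueError):
            decide_objects({})

    def test_argmax_object_reported(self):
        flags, best = decide_objects({0: [0.1, 0.2], 1: [1.0, 1.2]},
                                     threshold=0.0)
        assert best == 1 and flags[1]


class TestPipeline:
    def test_more_flashes_do_not_hurt(self):
        """Recognition accuracy with 10 flashes per object is at least
        that with a single flash, on the same synthetic family."""
        train, _ = gen_p300_stream(SynthConfig(seed=50, snr=1.0), 2, 30, 0)
        pipe = P300Pipeline().fit(train, favorite=0)
        acc = {}
        for flashes in (1, 10):
            ok = 0
            for r in range(20):
                fav = r % 2
                rec, _ = gen_p300_stream(
                    SynthConfig(seed=600 + r, snr=1.0), 2, flashes, fav)
                _, best = pipe.recognize(rec)
                ok += best == fav
            acc[flashes] = ok / 20
        assert acc[10] >= acc[1]

    def test_threshold_calibrated_between_class_means(self):
        train, _ = gen_p300_stream(SynthConfig(seed=51, snr=3.0), 2, 30, 0)
        pipe = P300Pipeline().fit(train, favorite=0)
        scores = pipe.scores_by_object(train)
        m_target = np.mean(scores[0])
        m_non = np.mean(scores[1])
        assert m_non < pipe.threshold < m_target
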