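"""TRCA: eigenproblem correctness, prediction logic, cross-validation."""

import numpy as np
import pandas as pd
import pytest

from realness_ssvep import io_preproc as iop
from realness_ssvep import synthetic_data as sd
from realness_ssvep import trca
from realness_ssvep.synthetic_data import GenerativeParams


def epochs_from_arrays(data, realness, sessions, srate=250.0, names=None):
    data = np.asarray(data, dtype=float)
    labels = pd.DataFrame({
        "subject": 1, "session": sessions,
        "trial": np.arange(1, data.shape[0] + 1),
        "realness": realness, "gender": "male", "emotion": "happy",
    })
    names = names or [f"ch{i}" for i in range(data.shape[1])]
    return iop.Epochs(data, srate, names, labels, tmin=1.0)


def two_channel_session_data(n_sessions=4, L=500, seed=0):
    """Channel 0: identical waveform each session; channel 1: fresh noise."""
    rng = np.random.default_rng(seed)
    shared = rng.normal(size=L)
    data = np.stack([
        np.stack([shared, rng.normal(size=L)]) for _ in range(n_sessions)
    ])
    return epochs_from_arrays(data, realness=[1] * n_sessions,
                              sessions=list(range(1, n_sessions + 1)))


def rayleigh(w, s_mat, q_mat):
    return (w @ s_mat @ w) / (w @ q_mat @ w)


class TestFit:
    def test_reproducible_channel_dominates_filter(self):
        ep = two_channel_session_data()
        model = trca.fit_trca(ep, channels=None)
        w = model.filters[0]
        assert abs(w[0]) > 10 * abs(w[1])

    def test_filter_matches_brute_force_grid(self):
        ep = two_channel_session_data(seed=3)
        model = trca.fit_trca(ep, channels=None)
        # independent oracle: maximize w'Sw/w'Qw over a fine angular grid
        data = ep.data - ep.data.mean(axis=2, keepdims=True)
        n_s, L = data.shape[0], data.shape[2]
        total = data.sum(axis=0)
        s_mat = (total @ total.T
                 - np.einsum("hcl,hdl->cd", data, data)) / L
        tmpl = data.mean(axis=0)
        q_mat = tmpl @ tmpl.T / L
        angles = np.linspace(0, np.pi, 100_000, endpoint=False)
        vecs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
        ratios = np.einsum("ki,ij,kj->k", vecs, s_mat, vecs) / np.einsum(
            "ki,ij,kj->k", vecs, q_mat, vecs)
        best = vecs[np.argmax(ratios)]
        w = model.filters[0] / np.linalg.norm(model.filters[0])
        angle = np.degrees(np.arccos(np.clip(abs(best @ w), -1, 1)))
        assert angle < 1.0
        assert rayleigh(w, s_mat, q_mat) >= ratios.max() * 0.99

    def test_single_channel_reduces_to_template_correlation(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(4, 1, 200))
        ep = epochs_from_arrays(data, [1, 1, 2, 2], [1, 2, 1, 2])
        model = trca.fit_trca(ep, channels=None)
        assert model.filters.shape == (2, 1)
        np.testing.assert_allclose(np.abs(model.filters), 1.0)

    def test_s_identity_for_identical_sessions(self):
        # perfectly session-reproducible data: S = N_s(N_s-1) Cov(x)
        rng = np.random.default_rng(5)
        x = rng.normal(size=(2, 300))
        n_s = 4
        data = np.tile(x, (n_s, 1, 1))
        xc = x - x.mean(axis=1, keepdims=True)
        cov = xc @ xc.T / x.shape[1]
        total = (data - data.mean(axis=2, keepdims=True)).sum(axis=0)
        s_mat = (total @ total.T - n_s * (xc @ xc.T)) / x.shape[1]
        np.testing.assert_allclose(s_mat, n_s * (n_s - 1) * cov, atol=1e-10)

    def test_q_variant_equivalence(self, default_epochs):
        ep, _ = default_epochs
        m1 = trca.fit_trca(ep, window_s=2.0, q_matrix="template")
        m2 = trca.fit_trca(ep, window_s=2.0, q_matrix="concatenated")
        for k in range(len(m1.classes)):
            cos = abs(m1.filters[k] @ m2.filters[k]) / (
                np.linalg.norm(m1.filters[k]) * np.linalg.norm(m2.filters[k]))
            assert cos > 0.999

    def test_single_session_rejected(self):
        rng = np.random.default_rng(0)
        ep = epochs_from_arrays(rng.normal(size=(2, 2, 100)), [1, 2], [1, 1])
        with pytest.raises(ValueError, match="session"):
            trca.fit_trca(ep, channels=None)

    def test_model_serialization_roundtrip(self, tmp_path, default_epochs):
        ep, _ = default_epochs
        model = trca.fit_trca(ep, window_s=2.0)
        path = model.save(tmp_path / "model")
        back = trca.TRCAModel.load(path)
        np.testing.assert_array_equal(back.filters, model.filters)
        np.testing.assert_array_equal(back.templates, model.templates)
        assert back.classes == model.classes


class TestPredict:
    def _model(self):
        rng = np.random.default_rng(7)
        templates = rng.normal(size=(2, 3, 100))
        filters = np.ones((2, 3))
        return trca.TRCAModel([1, 2], filters, templates,
                              ["a", "b", "c"], 250.0)

    def test_template_self_correlation(self):
        model = self._model()
        pred, rho = trca.predict_trca(model, model.templates[0])
        assert pred == 1
        assert rho[0] == pytest.approx(1.0)

    def test_anticorrelated_template(self):
        model = self._model()
        pred, rho = trca.predict_trca(model, -model.templates[0])
        assert rho[0] == pytest.approx(-1.0)
        assert pred == 2

    def test_filter_scale_and_sign_invariance(self):
        model = self._model()
        rng = np.random.default_rng(8)
        x = rng.normal(size=(3, 100))
        _, rho_ref = trca.predict_trca(model, x)
        model.filters[0] *= -3.7
        model.filters[1] *= 0.01
        _, rho = trca.predict_trca(model, x)
        np.testing.assert_allclose(np.abs(rho), np.abs(rho_ref), atol=1e-12)

    def test_tie_breaks_to_lowest_class(self):
        model = self._model()
        model.templates[1] = model.templates[0]
        with pytest.warns(RuntimeWarning, match="tie"):
            pred, _ = trca.predict_trca(model, model.templates[0])
        assert pred == 1

    def test_shape_mismatch_rejected(self):
        model = self._model()
        with pytest.raises(ValueError, match="shape"):
            trca.predict_trca(model, np.zeros((3, 50)))


class TestCrossValidate:
    def test_noise_free_data_fully_separable(self, noisefree_epochs):
        ep, _ = noisefree_epochs
        for classes in ([1, 6], [5, 6], [1, 2, 3, 4, 5, 6]):
            res = trca.cross_validate(ep, classes=classes, window_s=2.0,
                                      ridge=1e-8)
            assert res.accuracy == 1.0

    def test_confusion_rows_sum_to_one(self, default_epochs):
        ep, _ = default_epochs
        res = trca.cross_validate(ep, window_s=2.0)
        np.testing.assert_allclose(res.confusion.sum(axis=1), 1.0)

    def test_longer_window_does_not_hurt(self, default_epochs):
        ep, _ = default_epochs
        acc2 = trca.cross_validate(ep, window_s=2.0).accuracy
        acc8 = trca.cross_validate(ep, window_s=8.0).accuracy
        assert acc8 >= acc2 - 0.02

    def test_most_confused_pair_has_closest_templates(self):
        # generator ground truth defines the closest class pair: compute
        # the noise-free class templates and find the most-correlated pair,
        # then check that it is also the most-confused pair
        params = GenerativeParams(seed=21, beta=(0.5, 0.2, 0.0))
        p100, n170s = sd._component_trains(params, 250.0, 8.0)
        a = sd.amplitude_profile(params)
        templates = {r: p100 + a[r - 1] * n170s[r] for r in range(1, 7)}
        corrs = {(i, j): np.corrcoef(templates[i], templates[j])[0, 1]
                 for i in range(1, 7) for j in range(i + 1, 7)}
        closest = set(max(corrs, key=corrs.get))
        assert closest == {5, 6}  # smallest trough-latency gap

        design = sd.make_design(2, 8, seed=21)
        ep, _ = sd.simulate_epochs(design, params)
        res = trca.cross_validate(ep, window_s=8.0)
        conf = res.confusion.copy()
        np.fill_diagonal(conf, 0.0)
        sym = conf + conf.T
        i, j = np.unravel_index(np.argmax(sym), sym.shape)
        assert {res.classes[i], res.classes[j]} == closest

    def test_unbalanced_sessions_rejected(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(6, 2, 100))
        ep = epochs_from_arrays(data, [1, 1, 2, 1, 2, 2],
                                [1, 1, 1, 2, 2, 2])
        with pytest.raises(ValueError, match="balance|unbalanced"):
            trca.cross_validate(ep, channels=None)


class TestPermutation:
    def test_perfect_accuracy_gives_p_zero(self, noisefree_epochs):
        ep, _ = noisefree_epochs
        res = trca.permutation_test(ep, classes=[1, 6], n_perm=5, seed=0,
                                    window_s=2.0, ridge=1e-8)
        assert res.observed == 1.0
        assert res.p_value == 0.0

    def test_single_permutation_counting(self, default_epochs):
        ep, _ = default_epochs
        res = trca.permutation_test(ep, classes=[1, 6], n_perm=1, seed=3,
                                    window_s=2.0)
        expected = float(res.permuted[0] > res.observed)
        assert res.p_value == expected

    def test_add_one_estimator_never_zero(self, noisefree_epochs):
        ep, _ = noisefree_epochs
        res = trca.permutation_test(ep, classes=[1, 6], n_perm=5, seed=0,
                                    add_one=True, window_s=2.0, ridge=1e-8)
        assert res.p_value == pytest.approx(1.0 / 6.0)

    def test_zero_permutations_rejected(self, default_epochs):
        ep, _ = default_epochs
        with pytest.raises(ValueError, match="n_perm"):
            trca.permutation_test(ep, n_perm=0)
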