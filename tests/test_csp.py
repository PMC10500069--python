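import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mindeeg.csp import (CSP, FBCSP, FilterBank, OneVsRestCSP, bandpass_trials,
                         class_covariance, default_filter_bank, fit_csp)


def planted_trials(rng, n_trials=60, n_channels=4, n_samples=500, boost=3.0):
    """Class A has variance boost^2 on channel 0; class B is isotropic."""
    a = rng.standard_normal((n_trials, n_channels, n_samples))
    a[:, 0] *= boost
    b = rng.standard_normal((n_trials, n_channels, n_samples))
    return a, b


class TestClassCovariance:
    def test_iid_noise_approaches_scaled_identity(self, rng):
        trials = rng.standard_normal((400, 3, 400))
        cov = class_covariance(trials)
        np.testing.assert_allclose(cov, np.eye(3) / 3, atol=0.05 / 3 * 3)
        assert np.trace(cov) == pytest.approx(1.0, rel=1e-6)

    def test_single_trial_is_own_normalised_covariance(self, rng):
        trial = rng.standard_normal((1, 3, 200))
        cov = class_covariance(trial)
        x = trial[0] - trial[0].mean(axis=1, keepdims=True)
        expected = x @ x.T / 200
        expected /= np.trace(expected)
        np.testing.assert_allclose(cov, expected, atol=1e-8)

    def test_zero_variance_trial_rejected(self, rng):
        trials = rng.standard_normal((3, 2, 100))
        trials[1] = 0.0
        with pytest.raises(ValueError, match="trial 1"):
            class_covariance(trials)

    def test_symmetric_positive_semidefinite(self, rng):
        cov = class_covariance(rng.standard_normal((10, 5, 300)))
        np.testing.assert_allclose(cov, cov.T, atol=1e-14)
        assert np.linalg.eigvalsh(cov).min() > 0


class TestCSPFit:
    def test_identical_processes_give_half_eigenvalues(self, rng):
        a = rng.standard_normal((200, 4, 400))
        b = rng.standard_normal((200, 4, 400))
        model = fit_csp(a, b)
        np.testing.assert_allclose(model.eigenvalues_, 0.5, atol=0.05)

    def test_exactly_four_filters(self, rng):
        a, b = planted_trials(rng)
        model = fit_csp(a, b)
        assert model.filters_.shape == (4, 4)
        assert model.patterns_.shape == (4, 4)

    def test_eigenvalue_complementarity(self, rng):
        """Whitened class eigenvalue pairs sum to one."""
        from scipy.linalg import eigh

        a, b = planted_trials(rng)
        model = fit_csp(a, b)
        c1, c2 = model._c1, model._c2
        lam_c, u_c = eigh(c1 + c2)
        p = (u_c / np.sqrt(lam_c)).T
        l1 = np.sort(eigh(p @ c1 @ p.T, eigvals_only=True))
        l2 = np.sort(eigh(p @ c2 @ p.T, eigvals_only=True))[::-1]
        assert np.abs(l1 + l2 - 1).max() < 1e-8

    def test_simultaneous_diagonalisation(self, rng):
        a, b = planted_trials(rng)
        model = fit_csp(a, b)
        for cov in (model._c1, model._c2):
            d = model.filters_ @ cov @ model.filters_.T
            off = np.abs(d - np.diag(np.diag(d))).max()
            assert off < 1e-6 * np.abs(np.diag(d)).max()

    def test_top_filter_matches_rayleigh_oracle(self, rng):
        """The fitted top filter attains the brute-force maximum of
        w'C1w / w'(C1+C2)w over random unit vectors within 1%."""
        a, b = planted_trials(rng)
        model = fit_csp(a, b)
        c1, c = model._c1, model._c1 + model._c2
        v = rng.standard_normal((100_000, 4))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        brute = (np.einsum("ij,jk,ik->i", v, c1, v)
                 / np.einsum("ij,jk,ik->i", v, c, v)).max()
        w = model.filters_[0]
        achieved = (w @ c1 @ w) / (w @ c @ w)
        assert achieved >= brute * (1 - 0.01)

    def test_empty_class_rejected(self, rng):
        with pytest.raises(ValueError, match="non-empty"):
            fit_csp(np.empty((0, 3, 100)), rng.standard_normal((5, 3, 100)))

    def test_requires_two_classes(self, rng):
        X = rng.standard_normal((10, 4, 100))
        with pytest.raises(ValueError, match="two-class"):
            CSP().fit(X, np.zeros(10))


class TestCSPTransform:
    def test_feature_dimension_is_four(self, rng):
        a, b = planted_trials(rng)
        model = fit_csp(a, b)
        assert model.transform(a[:5]).shape == (5, 4)

    def test_scaling_shifts_log_features(self, rng):
        a, b = planted_trials(rng)
        model = fit_csp(a, b)
        f = model.transform(a[:3])
        f_scaled = model.transform(3.0 * a[:3])
        np.testing.assert_allclose(f_scaled - f, 2 * np.log(3.0), atol=1e-6)

    def test_zero_trial_yields_finite_epsilon_features(self, rng):
        a, b = planted_trials(rng)
        model = fit_csp(a, b)
        f = model.transform(np.zeros((1, 4, 500)))
        assert np.all(np.isfinite(f))
        np.testing.assert_allclose(f, np.log(1e-12))

    def test_channel_mismatch_rejected(self, rng):
        a, b = planted_trials(rng)
        model = fit_csp(a, b)
        with pytest.raises(ValueError, match="channels"):
            model.transform(rng.standard_normal((2, 5, 500)))

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=3))
    def test_filter_sign_indeterminacy(self, row):
        """Negating any filter row leaves the log-variance features unchanged."""
        rng = np.random.default_rng(42)
        a, b = planted_trials(rng)
        model = fit_csp(a, b)
        f = model.transform(a[:4])
        model.filters_[row] *= -1
        np.testing.assert_allclose(model.transform(a[:4]), f, atol=1e-10)

    def test_channel_permutation_leaves_features_unchanged(self, rng):
        a, b = planted_trials(rng)
        model = fit_csp(a, b)
        f = model.transform(a[:6])
        perm = rng.permutation(4)
        model_p = fit_csp(a[:, perm], b[:, perm])
        f_p = model_p.transform(a[:6, perm])
        np.testing.assert_allclose(np.sort(f_p, axis=1), np.sort(f, axis=1),
                                   atol=1e-6)


class TestFilterBank:
    def test_default_bank_structure(self):
        bank = default_filter_bank()
        assert len(bank) == 10
        for (lo, hi), expected_lo in zip(bank.bands, range(0, 40, 4)):
            assert lo == expected_lo and hi == expected_lo + 4

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            FilterBank(((8.0, 4.0),))

    def test_band_above_nyquist_rejected(self, rng):
        X = rng.standard_normal((4, 3, 300))
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_trials(X, 100.0, 130.0, 250.0)


class TestFBCSP:
    def test_default_feature_dimension_40(self, rng):
        a, b = planted_trials(rng, n_samples=400)
        X = np.concatenate([a, b])
        y = np.r_[np.zeros(len(a)), np.ones(len(b))]
        model = FBCSP(sfreq=250.0).fit(X, y)
        assert model.transform(X[:3]).shape == (3, 40)

    def test_fit_transform_matches_fit_then_transform(self, rng):
        a, b = planted_trials(rng, n_trials=20, n_samples=400)
        X = np.concatenate([a, b])
        y = np.r_[np.zeros(len(a)), np.ones(len(b))]
        f1 = FBCSP(sfreq=250.0).fit_transform(X, y)
        f2 = FBCSP(sfreq=250.0).fit(X, y).transform(X)
        np.testing.assert_allclose(f1, f2, atol=1e-10)

    def test_planted_band_has_largest_eigenvalue(self, compact_montage):
        """With a discriminative signal only in 8-12 Hz, that band's top CSP
        eigenvalue dominates the other bands' (averaged over seeds)."""
        from mindeeg.containers import State
        from mindeeg.preprocess import PreprocConfig, cohort_to_trialset, assemble_task
        from mindeeg.simulate import SimConfig, StateSpec, simulate_cohort

        specs = {
            State.REST1: StateSpec(State.REST1),
            State.MBSR1: StateSpec(State.MBSR1, {("alpha", "mid_frontal"): 2.0,
                                                 ("alpha", "occipital"): 2.0}),
            State.REST2: StateSpec(State.REST2, global_scale=1.2),
            State.MBSR2: StateSpec(State.MBSR2, {("alpha", "mid_frontal"): 2.0,
                                                 ("alpha", "occipital"): 2.0},
                                   global_scale=1.2),
        }
        wins = 0
        for seed in range(3):
            cfg = SimConfig(raw_rate=250.0, segment_duration=100.0, rng_seed=seed)
            recs = simulate_cohort(3, cfg, dispersion=0.0, state_specs=specs,
                                   montage=compact_montage)
            ts = cohort_to_trialset(recs, PreprocConfig(bad_channels=()))
            sub, y = assemble_task(ts, "MBSR1_REST1")
            model = FBCSP(sfreq=250.0).fit(sub.trials, y)
            tops = [max(m.eigenvalues_[0], 1 - m.eigenvalues_[-1])
                    for m in model.models_]
            if np.argmax(tops) == 2:  # the 8-12 Hz band
                wins += 1
        assert wins >= 2

    def test_single_band_reduces_to_plain_csp(self, rng):
        a, b = planted_trials(rng, n_trials=20, n_samples=400)
        X = np.concatenate([a, b])
        y = np.r_[np.zeros(len(a)), np.ones(len(b))]
        bank = FilterBank(((0.0, 40.0),))
        fb = FBCSP(sfreq=250.0, bank=bank).fit(X, y)
        xf = bandpass_trials(X, 0.0, 40.0, 250.0)
        plain = CSP().fit(xf, y)
        np.testing.assert_allclose(np.abs(fb.transform(X[:4])),
                                   np.abs(plain.transform(xf[:4])), atol=1e-8)


class TestOneVsRest:
    def _four_class(self, rng):
        X = rng.standard_normal((80, 4, 300))
        y = np.repeat(np.arange(4), 20)
        for c in range(4):
            X[y == c, c] *= 2.0 + c
        return X, y

    def test_csp_mode_dimensions(self, rng):
        X, y = self._four_class(rng)
        model = OneVsRestCSP("csp").fit(X, y)
        assert model.transform(X[:5]).shape == (5, 16)

    def test_fbcsp_mode_dimensions(self, rng):
        X, y = self._four_class(rng)
        model = OneVsRestCSP("fbcsp", sfreq=250.0).fit(X, y)
        assert model.transform(X[:2]).shape == (2, 160)

    def test_two_class_reduces_to_plain_csp(self, rng):
        a, b = planted_trials(rng)
        X = np.concatenate([a, b])
        y = np.r_[np.zeros(len(a), int), np.ones(len(b), int)]
        ovr = OneVsRestCSP("csp").fit(X, y)
        plain = CSP().fit(X, y)
        f_ovr = ovr.models_[0].transform(X[:6])
        f_plain = plain.transform(X[:6])
        np.testing.assert_allclose(f_ovr, f_plain, atol=1e-8)

    def test_empty_class_rejected(self, rng):
        X = rng.standard_normal((10, 3, 100))
        with pytest.raises(ValueError):
            OneVsRestCSP("csp").fit(X, np.zeros(10))
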