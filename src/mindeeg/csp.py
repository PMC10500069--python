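"""Common spatial patterns (CSP) and filter-bank CSP feature extraction.

CSP finds spatial filters w maximising the variance ratio
w' C1 w / w' (C1 + C2) w between two classes of multichannel trials:

1.  class covariances C1, C2 (per-trial covariances trace-normalised then
    averaged, plus a small diagonal shrinkage for rank safety),
2.  whitening P = L^{-1/2} U' from the eigendecomposition of C = C1 + C2,
3.  eigendecomposition of the whitened class-1 covariance S1 = P C1 P';
    the eigenvalue pairs of S1 and S2 sum to 1,
4.  the first two and last two eigenvectors (four filters) project trials
    to feature signals whose log-variances form a 4-dimensional feature.

FBCSP decomposes the signal with a bank of ten 4-Hz bandpass filters
(0-4, 4-8, ..., 36-40 Hz) and fits one CSP per band, concatenating the
per-band log-variance features (40 dimensions).  Multiclass problems use a
one-vs-rest reduction with one (FB)CSP per class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh, pinv
from scipy.signal import butter, sosfiltfilt
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "class_covariance",
    "CSP",
    "FilterBank",
    "default_filter_bank",
    "FBCSP",
    "OneVsRestCSP",
    "fit_csp",
    "csp_transform",
    "fit_fbcsp",
    "fbcsp_transform",
    "fit_ovr",
    "ovr_transform",
]

_SHRINKAGE = 1e-8
_LOG_EPS = 1e-12


def class_covariance(trials: np.ndarray) -> np.ndarray:
    """Average trace-normalised per-trial covariance of one class.

    Trace normalisation removes trial-amplitude differences; a shrinkage term
    ``1e-8 * mean(diag) * I`` keeps the result numerically full-rank.
    """
    trials = np.asarray(trials, dtype=np.float64)
    if trials.ndim != 3 or trials.shape[0] < 1:
        raise ValueError("need a non-empty (trials x channels x samples) array")
    n, c, s = trials.shape
    centred = trials - trials.mean(axis=2, keepdims=True)
    covs = centred @ centred.transpose(0, 2, 1) / s
    traces = np.trace(covs, axis1=1, axis2=2)
    bad = np.flatnonzero(traces <= 0)
    if bad.size:
        raise ValueError(f"trial {bad[0]} has zero variance; cannot normalise")
    cov = (covs / traces[:, None, None]).mean(axis=0)
    cov = (cov + cov.T) / 2.0
    cov += _SHRINKAGE * np.mean(np.diag(cov)) * np.eye(c)
    return cov


class CSP(TransformerMixin, BaseEstimator):
    """Two-class CSP spatial filtering with log-variance features.

    Parameters
    ----------
    n_components : int
        Number of spatial filters kept, half from each end of the eigenvalue
        spectrum (default 4: the first two and the last two eigenvectors).

    Attributes
    ----------
    filters_ : (n_components, n_channels) spatial filter matrix W (rows = filters).
    patterns_ : (n_channels, n_components) corresponding patterns (selected
        columns of the pseudo-inverse of the full filter matrix).
    eigenvalues_ : (n_channels,) eigenvalues of the whitened class-1
        covariance, sorted descending; each pairs with ``1 - eigenvalue`` for
        class 2.
    """

    def __init__(self, n_components: int = 4):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"CSP is a two-class method; got classes {classes}")
        self.classes_ = classes
        self._fit_two_class(X[y == classes[0]], X[y == classes[1]])
        return self

    def _fit_two_class(self, trials_a, trials_b):
        if len(trials_a) == 0 or len(trials_b) == 0:
            raise ValueError("both classes must be non-empty")
        if trials_a.shape[1] != trials_b.shape[1]:
            raise ValueError("classes have inconsistent channel counts")
        n_channels = trials_a.shape[1]
        if not (2 <= self.n_components <= n_channels):
            raise ValueError("n_components must be in [2, n_channels]")
        c1 = class_covariance(trials_a)
        c2 = class_covariance(trials_b)
        c = c1 + c2
        lam_c, u_c = eigh(c)
        if lam_c[-1] <= 0 or lam_c[0] / lam_c[-1] < 0:
            raise ValueError("composite covariance is not positive definite")
        rel = lam_c / lam_c[-1]
        if np.any(rel <= 1e-12):
            raise ValueError(
                "composite covariance is rank deficient beyond shrinkage repair"
            )
        whitener = (u_c / np.sqrt(lam_c)).T  # P = L^{-1/2} U'
        s1 = whitener @ c1 @ whitener.T
        s1 = (s1 + s1.T) / 2.0
        lam, u = eigh(s1)  # ascending
        order = np.argsort(lam)[::-1]
        lam = lam[order]
        u = u[:, order]
        w_full = u.T @ whitener  # rows = filters
        a_full = pinv(w_full)  # columns = patterns
        k = self.n_components
        sel = np.r_[np.arange(k // 2), np.arange(n_channels - (k - k // 2), n_channels)]
        self.filters_ = w_full[sel]
        self.patterns_ = a_full[:, sel]
        self.eigenvalues_ = lam
        self._c1, self._c2 = c1, c2
        self.n_channels_ = n_channels
        return self

    def transform(self, X) -> np.ndarray:
        """Log-variance of each spatially filtered trial component."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[None]
        if X.shape[1] != self.n_channels_:
            raise ValueError(
                f"trials have {X.shape[1]} channels, model expects {self.n_channels_}"
            )
        projected = np.einsum("fc,ncs->nfs", self.filters_, X)
        return np.log(projected.var(axis=-1) + _LOG_EPS)


@dataclass
class FilterBank:
    """Ordered list of (low, high) bandpass edges in Hz."""

    bands: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        for low, high in self.bands:
            if not (0 <= low < high):
                raise ValueError(f"invalid band ({low}, {high})")

    def __len__(self) -> int:
        return len(self.bands)


def default_filter_bank() -> FilterBank:
    """Ten contiguous 4-Hz bands covering 0-40 Hz (all five EEG rhythms)."""
    return FilterBank(tuple((4.0 * i, 4.0 * (i + 1)) for i in range(10)))


def bandpass_trials(X: np.ndarray, low: float, high: float, rate: float,
                    order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth bandpass of an epoched array along time.

    A band starting at 0 Hz becomes a lowpass at its upper edge.
    """
    nyq = rate / 2.0
    if high >= nyq:
        raise ValueError(f"band upper edge {high} Hz is at or above Nyquist ({nyq} Hz)")
    if low <= 0:
        sos = butter(order, high, btype="lowpass", fs=rate, output="sos")
    else:
        sos = butter(order, [low, high], btype="bandpass", fs=rate, output="sos")
    return sosfiltfilt(sos, np.asarray(X, dtype=np.float64), axis=-1)


class FBCSP(TransformerMixin, BaseEstimator):
    """Filter-bank CSP: one CSP per band, features concatenated in band order."""

    def __init__(self, sfreq: float = 250.0, bank: FilterBank | None = None,
                 n_components: int = 4):
        self.sfreq = sfreq
        self.bank = bank
        self.n_components = n_components

    def fit(self, X, y):
        self._fit(X, y, return_features=False)
        return self

    def fit_transform(self, X, y):
        # band-filters each trial once, shared between fitting and features
        return self._fit(X, y, return_features=True)

    def _fit(self, X, y, return_features: bool):
        X = np.asarray(X)
        bank = self.bank if self.bank is not None else default_filter_bank()
        self.bank_ = bank
        self.models_ = []
        feats = []
        for low, high in bank.bands:
            xf = bandpass_trials(X, low, high, self.sfreq)
            model = CSP(self.n_components).fit(xf, y)
            self.models_.append(model)
            if return_features:
                feats.append(model.transform(xf))
        self.n_channels_ = X.shape[1]
        if return_features:
            return np.concatenate(feats, axis=1)
        return None

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X)
        feats = []
        for (low, high), model in zip(self.bank_.bands, self.models_):
            xf = bandpass_trials(X, low, high, self.sfreq)
            feats.append(model.transform(xf))
        return np.concatenate(feats, axis=1)


class OneVsRestCSP(TransformerMixin, BaseEstimator):
    """One-vs-rest multiclass extension of CSP / FBCSP.

    One submodel is fitted per class (that class as "one", the rest pooled);
    features are concatenated in ascending class-label order, giving
    ``K * 4`` (CSP) or ``K * 4 * n_bands`` (FBCSP) dimensions.
    """

    def __init__(self, method: str = "csp", sfreq: float = 250.0,
                 bank: FilterBank | None = None, n_components: int = 4):
        self.method = method
        self.sfreq = sfreq
        self.bank = bank
        self.n_components = n_components

    def _make(self):
        if self.method == "csp":
            return CSP(self.n_components)
        if self.method == "fbcsp":
            return FBCSP(self.sfreq, self.bank, self.n_components)
        raise ValueError(f"unknown method {self.method!r}; expected 'csp' or 'fbcsp'")

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes")
        self.models_ = []
        for c in self.classes_:
            mask = y == c
            if mask.sum() == 0:
                raise ValueError(f"class {c!r} has no trials")
            model = self._make()
            y_bin = np.where(mask, 0, 1)  # class c first => its covariance is C1
            model.fit(X, y_bin)
            self.models_.append(model)
        return self

    def transform(self, X) -> np.ndarray:
        return np.concatenate([m.transform(X) for m in self.models_], axis=1)


# ---------------------------------------------------------------------------
# functional wrappers

def fit_csp(trials_a, trials_b, n_components: int = 4) -> CSP:
    model = CSP(n_components)
    model.classes_ = np.array([0, 1])
    model._fit_two_class(np.asarray(trials_a), np.asarray(trials_b))
    return model


def csp_transform(model: CSP, trial) -> np.ndarray:
    return model.transform(np.asarray(trial)[None] if np.asarray(trial).ndim == 2
                           else trial)


def fit_fbcsp(trials_a, trials_b, sfreq: float, bank: FilterBank | None = None) -> FBCSP:
    a, b = np.asarray(trials_a), np.asarray(trials_b)
    X = np.concatenate([a, b])
    y = np.r_[np.zeros(len(a), int), np.ones(len(b), int)]
    return FBCSP(sfreq, bank).fit(X, y)


def fbcsp_transform(model: FBCSP, trial) -> np.ndarray:
    t = np.asarray(trial)
    return model.transform(t[None] if t.ndim == 2 else t)


def fit_ovr(trials, labels, mode: str = "csp", sfreq: float = 250.0,
            bank: FilterBank | None = None) -> OneVsRestCSP:
    return OneVsRestCSP(mode, sfreq, bank).fit(trials, labels)


def ovr_transform(model: OneVsRestCSP, trials) -> np.ndarray:
    t = np.asarray(trials)
    return model.transform(t[None] if t.ndim == 2 else t)
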