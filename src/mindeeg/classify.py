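"""SVM classification on CSP/FBCSP features.

The classification contract is fixed: features are z-scored with training-set
statistics only, then fed to an SVM (RBF kernel, C = 1, kernel scale
1/(d * mean feature variance) -- sklearn's ``gamma='scale'``; one-vs-rest
for more than two classes).  A linear kernel is available by configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import accuracy_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .csp import CSP, FBCSP, FilterBank, OneVsRestCSP

__all__ = [
    "SVMConfig",
    "make_svm",
    "train_svm",
    "predict",
    "accuracy",
    "CSPFeatureExtractor",
    "make_csp_svm",
]


@dataclass
class SVMConfig:
    kernel: str = "rbf"  # 'rbf' or 'linear'
    C: float = 1.0

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "linear"):
            raise ValueError("kernel must be 'rbf' or 'linear'")
        if self.C <= 0:
            raise ValueError("C must be positive")


def make_svm(cfg: SVMConfig | None = None) -> Pipeline:
    """Standardiser + SVM pipeline (training statistics only leak-free by
    construction of sklearn pipelines)."""
    cfg = cfg or SVMConfig()
    return Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel=cfg.kernel, C=cfg.C, gamma="scale",
                    decision_function_shape="ovr", random_state=0)),
    ])


def train_svm(features, labels, cfg: SVMConfig | None = None) -> Pipeline:
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 training samples")
    return make_svm(cfg).fit(features, labels)


def predict(clf: Pipeline, features) -> np.ndarray:
    features = np.asarray(features, dtype=float)
    expected = clf.named_steps["scale"].mean_.shape[0]
    if features.shape[1] != expected:
        raise ValueError(
            f"feature dimension {features.shape[1]} does not match training ({expected})"
        )
    return clf.predict(features)


def accuracy(pred, truth) -> float:
    return float(accuracy_score(np.asarray(truth), np.asarray(pred)))


class CSPFeatureExtractor(BaseEstimator):
    """(FB)CSP front end that switches to one-vs-rest for multiclass labels."""

    def __init__(self, method: str = "csp", sfreq: float = 250.0,
                 bank: FilterBank | None = None, n_components: int = 4):
        self.method = method
        self.sfreq = sfreq
        self.bank = bank
        self.n_components = n_components

    def _make_model(self, n_classes: int):
        if n_classes == 2:
            if self.method == "csp":
                return CSP(self.n_components)
            if self.method == "fbcsp":
                return FBCSP(self.sfreq, self.bank, self.n_components)
            raise ValueError(f"unknown method {self.method!r}")
        return OneVsRestCSP(self.method, self.sfreq, self.bank, self.n_components)

    def fit(self, X, y):
        self.model_ = self._make_model(np.unique(y).size)
        self.model_.fit(X, y)
        return self

    def transform(self, X):
        return self.model_.transform(X)

    def fit_transform(self, X, y):
        self.model_ = self._make_model(np.unique(y).size)
        if isinstance(self.model_, FBCSP):
            # shares the band filtering between fitting and feature extraction
            return self.model_.fit_transform(X, y)
        self.model_.fit(X, y)
        return self.model_.transform(X)


class CSPSVMClassifier(ClassifierMixin, BaseEstimator):
    """End-to-end trial classifier: (FB)CSP features -> z-score -> SVM."""

    def __init__(self, method: str = "csp", sfreq: float = 250.0,
                 bank: FilterBank | None = None, n_components: int = 4,
                 kernel: str = "rbf", C: float = 1.0):
        self.method = method
        self.sfreq = sfreq
        self.bank = bank
        self.n_components = n_components
        self.kernel = kernel
        self.C = C

    def fit(self, X, y, X_val=None, y_val=None):  # val args accepted for API parity
        self.extractor_ = CSPFeatureExtractor(self.method, self.sfreq, self.bank,
                                              self.n_components)
        feats = self.extractor_.fit_transform(X, y)
        self.clf_ = train_svm(feats, y, SVMConfig(self.kernel, self.C))
        self.classes_ = np.unique(np.asarray(y))
        return self

    def predict(self, X):
        return predict(self.clf_, self.extractor_.transform(X))

    def score(self, X, y):
        return accuracy(self.predict(X), y)


def make_csp_svm(method: str = "csp", sfreq: float = 250.0,
                 bank: FilterBank | None = None, **svm_kwargs) -> CSPSVMClassifier:
    return CSPSVMClassifier(method=method, sfreq=sfreq, bank=bank, **svm_kwargs)
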