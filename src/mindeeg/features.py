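"""Spectral feature analysis and canonical correlation with network features.

Implements the interpretation pipeline: Welch power spectral densities per
trial, band power integrated over scalp regions of interest, handcrafted
delta/alpha and delta/beta power-ratio features, the first canonical
correlation (CCA) between a network's penultimate features and the
handcrafted features, and a white-noise chance level for that correlation.

Band definitions here follow the feature-analysis convention (beta =
12-30 Hz); the synthetic generator's rhythm bands use 13-30 Hz -- both are
kept explicit in their respective modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.signal import welch

from .containers import TrialSet
from .montage import MontageSpec

__all__ = [
    "ANALYSIS_BANDS",
    "HANDCRAFTED_COLUMNS",
    "welch_psd",
    "roi_band_power",
    "handcrafted_features",
    "cca_first_r",
    "ChanceLevel",
    "chance_level",
    "significance",
    "CCAResult",
    "cca_analysis",
]

#: Analysis band edges (Hz).
ANALYSIS_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (5.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (31.0, 80.0),
}

_ROI_ORDER = ("occipital", "mid_frontal", "mid_parietal")
_RATIOS = (("delta", "alpha"), ("delta", "beta"))

#: Fixed column order of the handcrafted feature matrix.
HANDCRAFTED_COLUMNS: tuple[str, ...] = tuple(
    f"{roi}_{num}_{den}" for roi in _ROI_ORDER for num, den in _RATIOS
)

_WINDOW_SECONDS = 2.0


def welch_psd(trial: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD per channel (2-s Hann windows, 50% overlap).

    Returns ``(freqs, psd)`` with ``psd`` of shape (n_channels, n_freqs) in
    power per Hz; the integrated density recovers the signal variance.
    """
    trial = np.atleast_2d(np.asarray(trial, dtype=np.float64))
    nperseg = int(round(_WINDOW_SECONDS * rate))
    if trial.shape[1] < nperseg:
        raise ValueError(
            f"trial of {trial.shape[1]} samples is shorter than one "
            f"{_WINDOW_SECONDS:.0f}-s window ({nperseg} samples)"
        )
    freqs, psd = welch(trial, fs=rate, window="hann", nperseg=nperseg,
                       noverlap=nperseg // 2, detrend="constant", axis=1)
    return freqs, psd


def roi_band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float],
                   roi: str, montage: MontageSpec) -> float:
    """Trapezoidal band-power integral averaged over the ROI's channels."""
    idx = montage.roi_indices(roi)
    if len(idx) == 0:
        raise ValueError(f"ROI {roi!r} has no channels in this montage")
    low, high = band
    mask = (freqs >= low) & (freqs <= high)
    if mask.sum() < 2:
        raise ValueError(f"band ({low}, {high}) Hz covers fewer than 2 frequency bins")
    per_channel = np.trapezoid(psd[idx][:, mask], freqs[mask], axis=1)
    return float(per_channel.mean())


def handcrafted_features(trialset: TrialSet, montage: MontageSpec | None = None):
    """Per-trial delta/alpha and delta/beta ROI power ratios (6 columns).

    Column order is fixed: occipital, mid-frontal, mid-parietal, each with
    the delta/alpha ratio then the delta/beta ratio.  Returns a pandas
    DataFrame with strictly positive entries.
    """
    import pandas as pd

    montage = montage if montage is not None else trialset.montage
    if montage is None:
        raise ValueError("a montage with ROI definitions is required")
    rows = np.empty((trialset.n_trials, len(HANDCRAFTED_COLUMNS)))
    for i in range(trialset.n_trials):
        freqs, psd = welch_psd(trialset.trials[i], trialset.rate)
        col = 0
        for roi in _ROI_ORDER:
            powers = {
                name: roi_band_power(freqs, psd, ANALYSIS_BANDS[name], roi, montage)
                for name in ("delta", "alpha", "beta")
            }
            for num, den in _RATIOS:
                if powers[den] <= 0:
                    raise ValueError(
                        f"trial {i}: zero {den} band power in ROI {roi!r}"
                    )
                rows[i, col] = powers[num] / powers[den]
                col += 1
    return pd.DataFrame(rows, columns=list(HANDCRAFTED_COLUMNS))


# ---------------------------------------------------------------------------
# canonical correlation

_CCA_RIDGE = 1e-8  # relative to the mean covariance diagonal


def _inv_sqrt(cov: np.ndarray) -> np.ndarray:
    lam, u = linalg.eigh(cov)
    lam = np.maximum(lam, np.finfo(float).tiny)
    return (u / np.sqrt(lam)) @ u.T


def cca_first_r(X, Y, ridge: float = _CCA_RIDGE) -> float:
    """First canonical correlation between two feature blocks, in [0, 1].

    Columns are centred internally; both covariance blocks receive a small
    ridge (``ridge`` times their mean diagonal), which keeps the result
    invariant under well-conditioned invertible linear transforms.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with the same number of rows")
    n = X.shape[0]
    if n < 10:
        raise ValueError("need at least 10 rows for a meaningful correlation")
    if n <= X.shape[1] + Y.shape[1]:
        warnings.warn(
            f"only {n} rows for {X.shape[1]}+{Y.shape[1]} feature columns; "
            "the canonical correlation may be degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sxx = Xc.T @ Xc / (n - 1)
    syy = Yc.T @ Yc / (n - 1)
    sxy = Xc.T @ Yc / (n - 1)
    for s in (sxx, syy):
        scale = np.mean(np.diag(s))
        s[np.diag_indices_from(s)] += ridge * (scale if scale > 0 else 1.0)
    k = _inv_sqrt(sxx) @ sxy @ _inv_sqrt(syy)
    r = linalg.svdvals(k)[0]
    return float(np.clip(r, 0.0, 1.0))


@dataclass
class ChanceLevel:
    mean: float
    sd: float
    draws: np.ndarray

    def threshold(self, alpha: float = 0.05) -> float:
        return float(np.percentile(self.draws, 100 * (1 - alpha)))


def chance_level(X, y_dims: int, n_rep: int = 100, seed: int = 0) -> ChanceLevel:
    """Null distribution of the first canonical correlation against white noise.

    Correlates ``X`` with ``n_rep`` independent standard-normal matrices of
    matching row count and ``y_dims`` columns.
    """
    if n_rep < 20:
        raise ValueError("need at least 20 repetitions for a usable null")
    X = np.asarray(X, dtype=np.float64)
    rng = np.random.default_rng(seed)
    draws = np.array([
        cca_first_r(X, rng.standard_normal((X.shape[0], y_dims)))
        for _ in range(n_rep)
    ])
    return ChanceLevel(float(draws.mean()), float(draws.std(ddof=1)), draws)


def significance(r: float, chance: ChanceLevel, alpha: float = 0.05) -> bool:
    """True when ``r`` exceeds the (1 - alpha) quantile of the chance draws."""
    return bool(r > chance.threshold(alpha))


@dataclass
class CCAResult:
    r: float
    chance_mean: float
    chance_sd: float
    significant: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.r <= 1.0):
            raise ValueError("r must lie in [0, 1]")
        if self.chance_sd < 0:
            raise ValueError("chance_sd must be >= 0")


def cca_analysis(network_features, handcrafted, n_rep: int = 100,
                 seed: int = 0) -> CCAResult:
    """First canonical correlation of network vs handcrafted features, with
    its white-noise chance level and a significance flag at alpha = 0.05."""
    Y = np.asarray(handcrafted, dtype=np.float64)
    r = cca_first_r(network_features, Y)
    chance = chance_level(network_features, Y.shape[1], n_rep=n_rep, seed=seed)
    return CCAResult(r, chance.mean, chance.sd, significance(r, chance))
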