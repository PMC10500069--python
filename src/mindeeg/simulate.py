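"""Synthetic EEG cohorts with controlled spectral and spatial structure.

The generator emulates the study conditions the analysis pipeline assumes:
a 128-channel montage, four conditions (REST1, MBSR1, REST2, MBSR2) per
subject, 10-minute eyes-closed segments at 1 kHz, and meditation effects
expressed as band-power changes in scalp regions of interest:

* alpha (8-12 Hz) power increased frontally and occipitally during meditation,
* beta (13-30 Hz) power increased frontally,
* delta (1-4 Hz) power decreased mid-parietally,
* a multiplicative stage-2 "trait" shift plus a small stage-specific
  rotation of the spatial mixing patterns,
* optional inter-subject heterogeneity (random orthogonal perturbation of
  the mixing patterns and lognormal per-band amplitude jitter).

Each band source is white Gaussian noise passed through a zero-phase FIR
bandpass filter and mixed onto the scalp through Gaussian spatial bumps
centred on the ROIs plus a diffuse background pattern; sensor noise,
50 Hz line interference and slow drift are added on top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.signal import fftconvolve, firwin

from .containers import Recording, State
from .montage import MontageSpec, make_montage

__all__ = [
    "BANDS",
    "SimConfig",
    "StateSpec",
    "SubjectProfile",
    "default_state_specs",
    "simulate_sources",
    "simulate_recording",
    "simulate_cohort",
    "iter_cohort",
    "draw_subjects",
]

#: Canonical EEG rhythm bands (Hz) used by the generator.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (5.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (31.0, 80.0),
}

#: Baseline RMS amplitude per band (µV); roughly realistic resting EEG.
DEFAULT_BAND_AMPLITUDES: dict[str, float] = {
    "delta": 8.0,
    "theta": 4.0,
    "alpha": 10.0,
    "beta": 3.0,
    "gamma": 1.5,
}

_SOURCE_ROIS: tuple[str, ...] = ("diffuse", "occipital", "mid_frontal", "mid_parietal")


def n_samples_for(duration: float, rate: float) -> int:
    """Inclusive-endpoint sample count: both endpoints of the interval kept."""
    return int(round(duration * rate)) + 1


@dataclass
class SimConfig:
    """Global generator settings (sampling, noise, seeds)."""

    raw_rate: float = 1000.0  # Hz
    segment_duration: float = 600.0  # s (10-minute conditions)
    sensor_noise_sd: float = 2.0  # µV
    line_noise_amplitude: float = 1.0  # µV at 50 Hz
    drift_amplitude: float = 5.0  # µV, slow (< 0.1 Hz) drift
    drift_freq: float = 0.05  # Hz
    rng_seed: int = 0
    bands: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(BANDS))
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES)
    )
    diffuse_scale: float = 0.2  # background pattern amplitude relative to ROI bumps
    bump_sigma: float = 0.35  # Gaussian ROI bump width in unit-disc coordinates
    stage_rotation: float = 0.08  # rad, stage-2 pattern rotation (trait effect)

    def __post_init__(self) -> None:
        top = max(high for _, high in self.bands.values())
        if self.raw_rate <= 2.0 * top:
            raise ValueError(
                f"raw_rate={self.raw_rate} must exceed twice the highest band edge ({top} Hz)"
            )
        for name, value in (
            ("sensor_noise_sd", self.sensor_noise_sd),
            ("line_noise_amplitude", self.line_noise_amplitude),
            ("drift_amplitude", self.drift_amplitude),
        ):
            if value < 0:
                raise ValueError(f"{name} must be >= 0")
        for band, amp in self.band_amplitudes.items():
            if amp < 0:
                raise ValueError(f"amplitude for band {band!r} must be >= 0")


@dataclass
class StateSpec:
    """Condition-specific source gains.

    ``band_gain`` maps ``(band, roi)`` to a positive multiplier applied to the
    corresponding localised source amplitude; unlisted pairs default to 1.
    ``global_scale`` multiplies every source and carries the stage-2 trait
    shift (all gains scaled up at the late training stage).
    """

    state: State
    band_gain: dict[tuple[str, str], float] = field(default_factory=dict)
    global_scale: float = 1.0

    def __post_init__(self) -> None:
        self.state = State(self.state)
        if self.global_scale <= 0:
            raise ValueError("global_scale must be positive")
        for key, gain in self.band_gain.items():
            if gain <= 0:
                raise ValueError(f"gain for {key} must be positive")

    def gain(self, band: str, roi: str) -> float:
        return self.band_gain.get((band, roi), 1.0)


def default_state_specs(
    alpha_gain: float = 1.5,
    beta_gain: float = 1.3,
    delta_gain: float = 0.7,
    trait_scale: float = 1.2,
) -> dict[State, StateSpec]:
    """Default condition specs implementing the meditation effect directions.

    Relative to the matching rest condition, meditation raises alpha power in
    the frontal and occipital ROIs, raises beta power frontally, and lowers
    delta power mid-parietally.  Stage-2 conditions carry a global trait
    multiplier, which makes the stage contrast (REST1 vs REST2) decodable.
    """
    if not (alpha_gain > 1 and beta_gain > 1 and 0 < delta_gain < 1 and trait_scale > 0):
        raise ValueError(
            "need alpha_gain > 1, beta_gain > 1, 0 < delta_gain < 1, trait_scale > 0"
        )
    meditation = {
        ("alpha", "mid_frontal"): alpha_gain,
        ("alpha", "occipital"): alpha_gain,
        ("beta", "mid_frontal"): beta_gain,
        ("delta", "mid_parietal"): delta_gain,
    }
    return {
        State.REST1: StateSpec(State.REST1, {}, 1.0),
        State.MBSR1: StateSpec(State.MBSR1, dict(meditation), 1.0),
        State.REST2: StateSpec(State.REST2, {}, trait_scale),
        State.MBSR2: StateSpec(State.MBSR2, dict(meditation), trait_scale),
    }


@dataclass
class SubjectProfile:
    """Per-subject deviation from the population template."""

    subject_id: str
    band_scale: dict[str, float] = field(default_factory=dict)  # >0, default 1
    pattern_seed: int = 0
    dispersion: float = 0.0  # 0 => homogeneous population

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for band, scale in self.band_scale.items():
            if scale <= 0:
                raise ValueError(f"band scale for {band!r} must be positive")

    def scale(self, band: str) -> float:
        return self.band_scale.get(band, 1.0)


def _band_filter(low: float, high: float, rate: float) -> np.ndarray:
    """Odd-length linear-phase FIR bandpass applied with 'same' convolution
    (zero phase).  Transition width is a fraction of the band width so that
    >= 90% of the output power lands inside the nominal band."""
    nyq = rate / 2.0
    width = high - low
    trans = max(0.15 * width, 0.05)
    numtaps = int(math.ceil(3.3 * rate / trans))
    numtaps = min(numtaps | 1, 2 ** 15 - 1)
    if low <= 0:
        return firwin(numtaps, high / nyq)
    return firwin(numtaps, [low / nyq, high / nyq], pass_zero=False)


def simulate_sources(
    bands: dict[str, tuple[float, float]],
    duration: float,
    rate: float,
    seed,
    amplitudes: dict[str, float] | None = None,
) -> dict[str, np.ndarray]:
    """One zero-mean band-limited noise source per band.

    Each source is unit-RMS white Gaussian noise filtered to its band and
    rescaled so its RMS equals the requested amplitude (default 1).  At least
    90% of each source's spectral power lies inside its nominal band.
    """
    nyq = rate / 2.0
    for name, (low, high) in bands.items():
        if not (0 <= low < high):
            raise ValueError(f"band {name!r}: need 0 <= low < high, got ({low}, {high})")
        if high >= nyq:
            raise ValueError(
                f"band {name!r} upper edge {high} Hz is at or above Nyquist ({nyq} Hz)"
            )
    amplitudes = amplitudes or {}
    n = n_samples_for(duration, rate)
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for name in sorted(bands):
        low, high = bands[name]
        amp = amplitudes.get(name, 1.0)
        white = rng.standard_normal(n)
        if amp == 0.0:
            out[name] = np.zeros(n)
            continue
        taps = _band_filter(low, high, rate)
        sig = fftconvolve(white, taps, mode="same")
        sig -= sig.mean()
        rms = sig.std()
        out[name] = sig * (amp / rms) if rms > 0 else sig
    return out


def _roi_patterns(montage: MontageSpec, config: SimConfig) -> np.ndarray:
    """(n_channels, 4) mixing patterns: diffuse background + one Gaussian bump
    per ROI, in ``_SOURCE_ROIS`` order."""
    pos = montage.positions
    cols = [np.full(montage.n_channels, config.diffuse_scale)]
    for roi in _SOURCE_ROIS[1:]:
        idx = montage.roi_indices(roi)
        if len(idx) == 0:
            raise ValueError(f"montage ROI {roi!r} is empty")
        centre = pos[idx].mean(axis=0)
        d2 = ((pos - centre) ** 2).sum(axis=1)
        cols.append(np.exp(-d2 / (2.0 * config.bump_sigma ** 2)))
    return np.column_stack(cols)


def _random_rotation(n: int, angle: float, seed) -> np.ndarray:
    """Orthogonal perturbation exp(angle * K) with K random skew-symmetric,
    normalised to unit spectral norm."""
    if angle == 0.0:
        return np.eye(n)
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n, n))
    k = (a - a.T) / 2.0
    k /= np.linalg.norm(k, 2)
    return expm(angle * k)


def subject_mixing(
    subject: SubjectProfile, montage: MontageSpec, config: SimConfig
) -> np.ndarray:
    """Subject-specific mixing patterns: population template rotated by an
    angle proportional to the subject's dispersion."""
    base = _roi_patterns(montage, config)
    rot = _random_rotation(montage.n_channels, subject.dispersion, subject.pattern_seed)
    return rot @ base


def simulate_recording(
    subject: SubjectProfile,
    state: StateSpec,
    montage: MontageSpec,
    config: SimConfig,
    seed=None,
) -> Recording:
    """Synthesise one continuous condition recording for one subject.

    ROI band power scales with the squared condition gain; with the default
    gains, frontal alpha power during meditation exceeds the rest condition
    for the same subject.
    """
    if seed is None:
        seed = config.rng_seed
    n = n_samples_for(config.segment_duration, config.raw_rate)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    src_seed, noise_seed, line_seed = ss.spawn(3)

    patterns = subject_mixing(subject, montage, config)
    if state.state.stage == 2 and config.stage_rotation:
        rot = _random_rotation(montage.n_channels, config.stage_rotation, 987654321)
        patterns = rot @ patterns

    # independent source realisations per source location (diffuse + 3 ROIs);
    # bands are summed per location first, so mixing is one matmul
    src_children = src_seed.spawn(len(_SOURCE_ROIS))
    located = np.zeros((len(_SOURCE_ROIS), n))
    for s_idx, roi in enumerate(_SOURCE_ROIS):
        roi_sources = simulate_sources(
            config.bands, config.segment_duration, config.raw_rate, src_children[s_idx],
        )
        for band in sorted(config.bands):
            amp = (
                config.band_amplitudes.get(band, 1.0)
                * subject.scale(band)
                * state.global_scale
                * (1.0 if roi == "diffuse" else state.gain(band, roi))
            )
            if amp != 0.0:
                located[s_idx] += amp * roi_sources[band]
    data = patterns @ located

    rng_noise = np.random.default_rng(noise_seed)
    if config.sensor_noise_sd > 0:
        data += rng_noise.normal(0.0, config.sensor_noise_sd, size=data.shape)
    t = np.arange(n) / config.raw_rate
    if config.line_noise_amplitude > 0:
        rng_line = np.random.default_rng(line_seed)
        ch_gain = 0.8 + 0.4 * rng_line.random(montage.n_channels)
        data += (
            config.line_noise_amplitude
            * ch_gain[:, None]
            * np.sin(2 * np.pi * 50.0 * t)[None, :]
        )
    if config.drift_amplitude > 0:
        # slow drift is mostly common-mode (reference/amplifier), with a
        # small electrode-specific gain spread
        rng_drift = np.random.default_rng(ss.spawn(1)[0])
        phase = rng_drift.uniform(0, 2 * np.pi)
        ch_gain = 1.0 + 0.1 * rng_drift.standard_normal(montage.n_channels)
        data += (
            config.drift_amplitude
            * ch_gain[:, None]
            * np.sin(2 * np.pi * config.drift_freq * t + phase)[None, :]
        )

    return Recording(
        data.astype(np.float32),
        config.raw_rate,
        montage,
        subject_id=subject.subject_id,
        state=state.state,
    )


def draw_subjects(
    n_subjects: int, config: SimConfig, dispersion: float = 0.3
) -> list[SubjectProfile]:
    """Deterministically draw subject profiles at the given dispersion."""
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng(np.random.SeedSequence((config.rng_seed, 0x5EED)))
    subjects = []
    for i in range(n_subjects):
        if dispersion > 0:
            band_scale = {
                band: float(np.exp(rng.normal(0.0, 0.25 * dispersion)))
                for band in sorted(config.bands)
            }
        else:
            band_scale = {}
            rng.normal(size=len(config.bands))  # keep the stream aligned
        pattern_seed = int(rng.integers(0, 2 ** 31 - 1))
        subjects.append(
            SubjectProfile(f"S{i + 1:02d}", band_scale, pattern_seed, dispersion)
        )
    return subjects


def iter_cohort(
    n_subjects: int,
    config: SimConfig,
    dispersion: float = 0.3,
    state_specs: dict[State, StateSpec] | None = None,
    montage: MontageSpec | None = None,
):
    """Yield one Recording per (subject, condition), fully reproducible.

    Memory-friendly generator form of :func:`simulate_cohort`.
    """
    montage = montage if montage is not None else make_montage()
    specs = state_specs if state_specs is not None else default_state_specs()
    subjects = draw_subjects(n_subjects, config, dispersion)
    ss = np.random.SeedSequence((config.rng_seed, 0xC0F0))
    seeds = ss.spawn(n_subjects * len(specs))
    k = 0
    for subject in subjects:
        for state in sorted(specs, key=lambda s: s.value):
            yield simulate_recording(subject, specs[state], montage, config, seeds[k])
            k += 1


def simulate_cohort(
    n_subjects: int,
    config: SimConfig,
    dispersion: float = 0.3,
    state_specs: dict[State, StateSpec] | None = None,
    montage: MontageSpec | None = None,
) -> list[Recording]:
    """All recordings of a cohort: 4 conditions x ``n_subjects`` subjects."""
    return list(iter_cohort(n_subjects, config, dispersion, state_specs, montage))
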