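"""Preprocessing chain and epoching.

Fixed stage order: drop bad channels -> resample to 250 Hz -> average
re-reference -> notch (50, 100 Hz) -> bandpass (0.1-120 Hz) -> segment into
5-s trials.  Ocular/muscle artifact removal is a logged no-op here: the
synthetic recordings are generated without such artifacts.

Sample-count convention: a segment of duration d at rate r holds
``round(d*r) + 1`` samples (both interval endpoints kept), and consecutive
5-s trials share exactly one boundary sample (window 1251, hop 1250 at
250 Hz).  This is the unique convention under which a 10-minute segment
yields both 120 trials and 1,251 samples per trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy.signal import butter, filtfilt, iirnotch, resample_poly, sosfiltfilt

from .containers import Recording, TrialSet
from .montage import DEFAULT_BAD_CHANNELS

__all__ = [
    "PreprocConfig",
    "drop_bad_channels",
    "resample",
    "rereference_average",
    "notch_and_bandpass",
    "remove_artifacts",
    "segment",
    "preprocess_recording",
    "cohort_to_trialset",
    "assemble_task",
    "TASKS",
    "STATE_TASKS",
    "task_classes",
]

logger = logging.getLogger(__name__)


@dataclass
class PreprocConfig:
    bad_channels: tuple[str, ...] = DEFAULT_BAD_CHANNELS
    target_rate: float = 250.0
    notch_freqs: tuple[float, ...] = (50.0, 100.0)
    notch_q: float = 30.0
    bandpass: tuple[float, float] = (0.1, 120.0)
    bandpass_order: int = 4
    trial_len: int = 1251  # samples
    trial_hop: int = 1250  # samples

    def __post_init__(self) -> None:
        low, high = self.bandpass
        if not (0 < low < high):
            raise ValueError("bandpass edges must satisfy 0 < low < high")
        if high >= self.target_rate / 2:
            raise ValueError("bandpass upper edge must stay below the target Nyquist")
        if self.trial_hop > self.trial_len:
            raise ValueError("trial_hop must not exceed trial_len")
        if self.trial_len < 2 or self.trial_hop < 1:
            raise ValueError("trial_len/trial_hop out of range")


def drop_bad_channels(rec: Recording, bad_list=None) -> Recording:
    """Remove the listed channels, preserving survivor order and updating ROIs."""
    bad = list(DEFAULT_BAD_CHANNELS if bad_list is None else bad_list)
    unknown = set(bad) - set(rec.montage.channel_labels)
    if unknown:
        raise KeyError(f"bad channels not present in montage: {sorted(unknown)}")
    if not bad:
        return replace(rec, data=rec.data.copy())
    keep = [lab for lab in rec.montage.channel_labels if lab not in set(bad)]
    idx = rec.montage.indices(keep)
    montage = rec.montage.subset(keep)
    montage.bad_channels = []
    return Recording(rec.data[idx], rec.rate, montage, rec.subject_id, rec.state)


def resample(rec: Recording, target_rate: float) -> Recording:
    """Polyphase FIR resampling to ``target_rate`` (downsampling only).

    Output length follows the inclusive-endpoint convention:
    ``round((n_in - 1) * target/orig) + 1``.
    """
    if target_rate > rec.rate:
        raise ValueError(
            f"upsampling from {rec.rate} to {target_rate} Hz is not supported"
        )
    if target_rate == rec.rate:
        return replace(rec, data=rec.data.copy())
    ratio = Fraction(target_rate / rec.rate).limit_denominator(10_000)
    n_out = int(round((rec.n_samples - 1) * target_rate / rec.rate)) + 1
    out = resample_poly(rec.data.astype(np.float64), ratio.numerator, ratio.denominator, axis=1)
    if out.shape[1] < n_out:  # pad with the edge value on rare length mismatch
        pad = np.repeat(out[:, -1:], n_out - out.shape[1], axis=1)
        out = np.concatenate([out, pad], axis=1)
    out = out[:, :n_out]
    return Recording(out.astype(rec.data.dtype), target_rate, rec.montage,
                     rec.subject_id, rec.state)


def rereference_average(rec: Recording) -> Recording:
    """Re-reference to the whole-brain average (per-sample channel mean = 0)."""
    if rec.n_channels < 2:
        raise ValueError("average re-referencing needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return replace(rec, data=data)


def notch_and_bandpass(rec: Recording, cfg: PreprocConfig | None = None) -> Recording:
    """Zero-phase powerline notches followed by a Butterworth bandpass.

    Notches are 2nd-order IIR (quality factor ``cfg.notch_q``); the bandpass
    is a 4th-order Butterworth applied as second-order sections.  Everything
    is applied forward-backward, so there is no group delay.
    """
    cfg = cfg or PreprocConfig()
    nyq = rec.rate / 2.0
    for f0 in cfg.notch_freqs:
        if f0 >= nyq:
            raise ValueError(f"notch frequency {f0} Hz is at or above Nyquist ({nyq} Hz)")
    data = rec.data.astype(np.float64)
    for f0 in cfg.notch_freqs:
        b, a = iirnotch(f0, cfg.notch_q, fs=rec.rate)
        data = filtfilt(b, a, data, axis=1)
    sos = butter(cfg.bandpass_order, cfg.bandpass, btype="bandpass", fs=rec.rate,
                 output="sos")
    data = sosfiltfilt(sos, data, axis=1)
    return replace(rec, data=data.astype(rec.data.dtype))


def remove_artifacts(rec: Recording) -> Recording:
    """Placeholder for ocular/muscle artifact removal (no-op with a warning).

    The synthetic generator produces artifact-free data, so this stage passes
    the recording through unchanged; on real data a dedicated method would be
    slotted in here.
    """
    logger.warning(
        "artifact removal stage is a no-op (recordings are treated as artifact-free)"
    )
    return rec


def segment(rec: Recording, cfg: PreprocConfig | None = None) -> TrialSet:
    """Cut a recording into fixed-length trials.

    Windows of ``trial_len`` samples are placed every ``trial_hop`` samples,
    so consecutive trials share exactly ``trial_len - trial_hop`` samples
    (one boundary sample with the defaults).  Trial count is
    ``floor((n - trial_len) / trial_hop) + 1``.
    """
    cfg = cfg or PreprocConfig()
    n = rec.n_samples
    if n < cfg.trial_len:
        raise ValueError(
            f"recording has {n} samples, shorter than one trial ({cfg.trial_len})"
        )
    n_trials = (n - cfg.trial_len) // cfg.trial_hop + 1
    starts = np.arange(n_trials) * cfg.trial_hop
    trials = np.stack([rec.data[:, s:s + cfg.trial_len] for s in starts])
    return TrialSet(
        trials,
        np.array([rec.state.value] * n_trials, dtype=object),
        np.array([rec.subject_id] * n_trials, dtype=object),
        rec.rate,
        rec.montage,
    )


def preprocess_recording(rec: Recording, cfg: PreprocConfig | None = None) -> Recording:
    """Full continuous-data chain (everything before epoching), in fixed order."""
    cfg = cfg or PreprocConfig()
    bad = [lab for lab in cfg.bad_channels if lab in set(rec.montage.channel_labels)]
    rec = drop_bad_channels(rec, bad)
    rec = resample(rec, cfg.target_rate)
    rec = rereference_average(rec)
    rec = notch_and_bandpass(rec, cfg)
    rec = remove_artifacts(rec)
    return rec


def cohort_to_trialset(recordings, cfg: PreprocConfig | None = None) -> TrialSet:
    """Preprocess and epoch every recording, concatenated into one TrialSet."""
    cfg = cfg or PreprocConfig()
    parts = [segment(preprocess_recording(rec, cfg), cfg) for rec in recordings]
    return TrialSet.concatenate(parts)


#: Classification tasks: class label -> constituent conditions.
TASKS: dict[str, tuple[tuple[str, ...], ...]] = {
    "4CLASS": (("REST1",), ("MBSR1",), ("REST2",), ("MBSR2",)),
    "MBSR1_REST1": (("MBSR1",), ("REST1",)),
    "MBSR2_REST2": (("MBSR2",), ("REST2",)),
    "MBSR_REST": (("MBSR1", "MBSR2"), ("REST1", "REST2")),
    "MBSR1_MBSR2": (("MBSR1",), ("MBSR2",)),
    "REST1_REST2": (("REST1",), ("REST2",)),
}

#: Tasks that contrast meditation with rest (the "state" tasks); the
#: intra-subject and subject-transfer strategies are restricted to these.
STATE_TASKS: frozenset[str] = frozenset({"MBSR1_REST1", "MBSR2_REST2", "MBSR_REST"})


def task_classes(task: str) -> tuple[tuple[str, ...], ...]:
    try:
        return TASKS[task]
    except KeyError:
        raise ValueError(f"unknown task {task!r}; expected one of {sorted(TASKS)}") from None


def assemble_task(trialset: TrialSet, task: str) -> tuple[TrialSet, np.ndarray]:
    """Restrict a TrialSet to the conditions of ``task`` and build class labels.

    Returns the filtered TrialSet and an integer label vector (class k =
    k-th group in :data:`TASKS`, e.g. MBSR = MBSR1 u MBSR2 for the combined
    task).  Trials from conditions outside the task are excluded.
    """
    groups = task_classes(task)
    label_of: dict[str, int] = {}
    for k, states in enumerate(groups):
        for s in states:
            label_of[s] = k
    mask = np.array([s in label_of for s in trialset.states])
    subset = trialset.select(mask)
    y = np.array([label_of[s] for s in subset.states], dtype=int)
    return subset, y
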