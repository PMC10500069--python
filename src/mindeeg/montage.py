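"""Scalp montage description for the 128-channel recording system.

Channels are named ``N1`` .. ``N128``.  Three regions of interest (ROIs) are
used throughout the package for band-power features and for placing the
spatially localised sources of the synthetic generator:

* occipital lobe (20 channels),
* middle frontal lobe (14 channels),
* middle parietal lobe (9 channels).

Fifteen channels are flagged as bad (high impedance in the original
recordings) and are removed during preprocessing, leaving 113 channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MontageSpec",
    "make_montage",
    "make_compact_montage",
    "OCCIPITAL_CHANNELS",
    "MID_FRONTAL_CHANNELS",
    "MID_PARIETAL_CHANNELS",
    "DEFAULT_BAD_CHANNELS",
]

#: Occipital-lobe ROI channel labels (20 channels).
OCCIPITAL_CHANNELS: tuple[str, ...] = tuple(
    f"N{i}" for i in (19, 20, 21, 41, 42, 43, 44, 45, 46, 67, 68, 69, 70, 71, 72,
                      96, 97, 98, 99, 100)
)

#: Middle-frontal ROI channel labels (14 channels).
MID_FRONTAL_CHANNELS: tuple[str, ...] = tuple(
    f"N{i}" for i in (53, 54, 55, 56, 57, 58, 59, 60, 61, 79, 80, 81, 82, 83)
)

#: Middle-parietal ROI channel labels (9 channels).
MID_PARIETAL_CHANNELS: tuple[str, ...] = tuple(
    f"N{i}" for i in (48, 49, 50, 64, 65, 66, 74, 75, 76)
)

#: The 15 high-impedance channels excluded before analysis.
DEFAULT_BAD_CHANNELS: tuple[str, ...] = tuple(
    f"N{i}" for i in (10, 11, 17, 28, 59, 63, 64, 72, 74, 84, 85, 110, 111, 115, 118)
)

_MAX_ROI_INDEX = 100  # largest channel index referenced by any ROI


@dataclass
class MontageSpec:
    """Channel labels, 2-D scalp positions and ROI / bad-channel subsets.

    Positions live on the unit disc (a schematic top view of the scalp);
    they only need to be deterministic and spatially smooth, not an
    anatomically calibrated layout.
    """

    channel_labels: list[str]
    positions: np.ndarray  # (n_channels, 2), unit-disc coordinates
    rois: dict[str, list[str]] = field(default_factory=dict)
    bad_channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = list(self.channel_labels)
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(labels), 2):
            raise ValueError(
                f"positions must be ({len(labels)}, 2), got {self.positions.shape}"
            )
        known = set(labels)
        for name, roi in self.rois.items():
            missing = set(roi) - known
            if missing:
                raise ValueError(f"ROI {name!r} references unknown channels {sorted(missing)}")
        roi_lists = list(self.rois.values())
        for i in range(len(roi_lists)):
            for j in range(i + 1, len(roi_lists)):
                overlap = set(roi_lists[i]) & set(roi_lists[j])
                if overlap:
                    raise ValueError(f"ROIs overlap on channels {sorted(overlap)}")
        missing_bad = set(self.bad_channels) - known
        if missing_bad:
            raise ValueError(f"bad channels not in montage: {sorted(missing_bad)}")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def indices(self, labels) -> np.ndarray:
        """Integer indices of ``labels`` in montage order."""
        lookup = {lab: i for i, lab in enumerate(self.channel_labels)}
        try:
            return np.array([lookup[lab] for lab in labels], dtype=int)
        except KeyError as err:
            raise KeyError(f"channel {err.args[0]!r} not in montage") from None

    def roi_indices(self, name: str) -> np.ndarray:
        return self.indices(self.rois[name])

    def subset(self, keep_labels) -> "MontageSpec":
        """New montage restricted to ``keep_labels`` (montage order preserved)."""
        keep = set(keep_labels)
        unknown = keep - set(self.channel_labels)
        if unknown:
            raise KeyError(f"channels not in montage: {sorted(unknown)}")
        labels = [lab for lab in self.channel_labels if lab in keep]
        idx = self.indices(labels)
        rois = {
            name: [lab for lab in roi if lab in keep] for name, roi in self.rois.items()
        }
        bad = [lab for lab in self.bad_channels if lab in keep]
        return MontageSpec(labels, self.positions[idx], rois, bad)


def _disc_positions(n_channels: int) -> np.ndarray:
    """Deterministic sunflower (golden-angle) layout on the unit disc."""
    i = np.arange(n_channels)
    r = 0.95 * np.sqrt((i + 0.5) / n_channels)
    theta = i * (np.pi * (3.0 - np.sqrt(5.0)))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


#: Schematic anchor per ROI on the unit disc (nose up: +y is anterior).
_ROI_ANCHORS: dict[str, tuple[float, float]] = {
    "occipital": (0.0, -0.75),
    "mid_frontal": (0.0, 0.65),
    "mid_parietal": (0.0, -0.15),
}


def _cluster_positions(n: int, centre: tuple[float, float]) -> np.ndarray:
    radius = min(0.25, 0.06 * np.sqrt(n) + 0.08)
    local = _disc_positions(n) / 0.95 * radius
    return local + np.asarray(centre)


def _roi_layout(labels: list[str], rois: dict[str, list[str]]) -> np.ndarray:
    """Deterministic layout: ROI channels clustered around their anatomical
    anchors, remaining channels spread over the disc."""
    pos = _disc_positions(len(labels))
    index = {lab: i for i, lab in enumerate(labels)}
    for name, members in rois.items():
        cluster = _cluster_positions(len(members), _ROI_ANCHORS[name])
        for lab, p in zip(members, cluster):
            pos[index[lab]] = p
    return pos


def make_montage(n_channels: int = 128) -> MontageSpec:
    """Build the default montage with occipital / mid-frontal / mid-parietal ROIs.

    Parameters
    ----------
    n_channels : int
        Montage size; must cover every channel index referenced by the ROI
        definitions (i.e. ``n_channels >= 100``).
    """
    if n_channels < _MAX_ROI_INDEX:
        raise ValueError(
            f"n_channels={n_channels} is smaller than the largest ROI channel "
            f"index (N{_MAX_ROI_INDEX}); need at least {_MAX_ROI_INDEX} channels"
        )
    labels = [f"N{i + 1}" for i in range(n_channels)]
    available = set(labels)
    bad = [lab for lab in DEFAULT_BAD_CHANNELS if lab in available]
    rois = {
        "occipital": list(OCCIPITAL_CHANNELS),
        "mid_frontal": list(MID_FRONTAL_CHANNELS),
        "mid_parietal": list(MID_PARIETAL_CHANNELS),
    }
    return MontageSpec(labels, _roi_layout(labels, rois), rois, bad)


def make_compact_montage(n_channels: int = 16, n_bad: int = 0) -> MontageSpec:
    """Reduced-scale montage for quick experiments and simulations.

    ROIs are assigned proportionally (roughly the same coverage fractions as
    the full montage: occipital ~16%, mid-frontal ~11%, mid-parietal ~7%)
    and clustered around the same anatomical anchors as the full layout so
    the synthetic sources remain spatially localised.
    """
    if n_channels < 9:
        raise ValueError("compact montage needs at least 9 channels for three ROIs")
    labels = [f"N{i + 1}" for i in range(n_channels)]
    n_occ = max(2, round(0.16 * n_channels))
    n_fro = max(2, round(0.11 * n_channels))
    n_par = max(2, round(0.07 * n_channels))
    occ = labels[:n_occ]
    fro = labels[n_occ:n_occ + n_fro]
    par = labels[n_occ + n_fro:n_occ + n_fro + n_par]
    bad = labels[-n_bad:] if n_bad else []
    rois = {"occipital": occ, "mid_frontal": fro, "mid_parietal": par}
    return MontageSpec(labels, _roi_layout(labels, rois), rois, bad)
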